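"""Bayesian small-area estimation with spatial smoothing.

Fits the binomial logit model with structured (ICAR) + unstructured
district effects by MCMC on per-district counts for first births before
16, and prints posterior means with 95% credible intervals — including a
district with no observed clusters, whose estimate is driven entirely by
the intercept and its neighbours.
"""

import numpy as np

from prevmap import (McmcConfig, build_adjacency, fit_bym, outcome_counts,
                     simulate_survey, summarise_posterior, SyntheticConfig)

cfg = SyntheticConfig(seed=2024)
ds, truth = simulate_survey(cfg)

graph = build_adjacency(ds.districts)
counts = (outcome_counts(ds, admin_level=2, band="LT16")
          .set_index("unit_id").reindex(graph.ids))
# pretend one district's clusters were never surveyed, to show prediction
counts.loc[counts.index[-1], ["y", "n"]] = 0
fit = fit_bym(counts["y"].to_numpy(), counts["n"].to_numpy(), graph,
              mcmc=McmcConfig(n_iter=6000, n_burn=2000, thin=2, seed=7))
s = summarise_posterior(fit).set_index("unit_id")
s = s.join(truth.set_index("district_id")["p_lt16"]).join(counts)

cover = ((s["q2.5"] <= s["p_lt16"]) & (s["p_lt16"] <= s["q97.5"])).mean()
print(f"{len(s)} districts; 95% CI covers the true prevalence in "
      f"{100 * cover:.0f}% of them")
print(f"posterior SD: observed districts {s.loc[s['observed'], 'sd'].mean():.3f} "
      f"vs unobserved {s.loc[~s['observed'], 'sd'].mean():.3f} (mean)\n")

print("district   y/n     truth   mean    sd     95% CI")
show = list(s[~s["observed"]].index[:2]) + list(s[s["observed"]].index[:4])
for uid in show:
    r = s.loc[uid]
    yn = f"{int(r['y'])}/{int(r['n'])}" if r["n"] else "  -  "
    print(f"  {uid}  {yn:>7}  {r['p_lt16']:.3f}  {r['mean']:.3f}  "
          f"{r['sd']:.3f}  ({r['q2.5']:.3f}, {r['q97.5']:.3f})")
print("\nUnobserved districts (y/n = '-') get wider intervals: the model "
      "borrows strength from neighbours instead of reporting nothing.")
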