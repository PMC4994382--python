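"""Survey-weighted prevalence from the bundled published count table.

Expands the published unweighted counts (three East-African surveys of
women aged 20-29) to a respondent-level table with unit weights and
recomputes the headline percentages: the share of women with a first
birth in each adolescent age band, and conditional breakdowns among
those with a first birth before 16.
"""

from prevmap import conditional_share, weighted_prevalence
from prevmap.datasets import expand_to_respondents
from prevmap.survey_io import BANDS

r = expand_to_respondents()
print(f"{len(r)} respondents across {r['country'].nunique()} countries\n")

print("Population share with first birth in each band (%):")
for band in BANDS:
    pooled = weighted_prevalence(r, band).loc[0, "prevalence"]
    per = weighted_prevalence(r, band, "country").set_index("group")
    cells = "  ".join(f"{c}: {100 * per.loc[c, 'prevalence']:.1f}"
                      for c in ("Kenya", "Tanzania", "Uganda"))
    print(f"  {band:<7} pooled: {100 * pooled:.1f}   {cells}")

print("\nAmong women with a first birth before 16 (%):")
for ind in ("no_education", "bottom_wealth"):
    share = conditional_share(r, "LT16", ind).loc[0, "prevalence"]
    print(f"  {ind:<14} {100 * share:.1f}")

print("\nEach line is a weighted ratio sum(w*event)/sum(w); with unit "
      "weights it equals the plain proportion, so these match the "
      "published survey tables to one decimal place.")
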