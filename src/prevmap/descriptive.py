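"""Survey-weighted prevalence by administrative unit and choropleth export.

The descriptive stage answers "what share of women aged 20-29 in each area
had a first birth in each adolescent age band?" directly from the survey:

    prevalence = sum(w_i * 1[band_i = band]) / sum(w_i)

within each group, where w_i is the respondent's survey weight.  With unit
weights this is the plain proportion.  Respondents with no birth before 20
stay in the denominator — the estimand is a population proportion, not a
share among mothers.  A conditional mode restricts the denominator to one
band for breakdowns such as "share with no education among those with a
first birth before 16".

Estimates are exported as an attributed GeoJSON (one property per band,
plus any extra attributes for bivariate maps) and as a summary table with
bands as rows and groups as columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .survey_io import AdminUnit, BANDS, SurveyDataset, admin_units_to_geojson


def weighted_prevalence(respondents: pd.DataFrame, band: str | Sequence[str],
                        grouping: str | pd.Series | None = None,
                        ) -> pd.DataFrame:
    """Weighted prevalence of one band (or union of bands) per group.

    ``grouping`` is ``None`` for a pooled estimate, a column name in
    ``respondents``, or a Series of group labels aligned to the rows.
    Groups with zero weighted denominator are reported with NaN prevalence,
    never zero.  Returns columns ``group``, ``prevalence``, ``numerator``,
    ``denominator`` (the last two unweighted counts).
    """
    if len(respondents) == 0:
        raise ValueError("empty respondent set")
    w = respondents["weight"].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("all weights must be positive")
    bands = [band] if isinstance(band, str) else list(band)
    event = respondents["first_birth_band"].isin(bands).to_numpy()

    if grouping is None:
        labels = pd.Series("pooled", index=respondents.index)
    elif isinstance(grouping, str):
        labels = respondents[grouping]
    else:
        labels = grouping
    df = pd.DataFrame({"group": labels.to_numpy(), "w": w, "event": event})
    agg = df.groupby("group", dropna=False).agg(
        wsum=("w", "sum"),
        wev=("event", lambda s: float(np.sum(df.loc[s.index, "w"] * s))),
        numerator=("event", "sum"),
        denominator=("event", "size"))
    agg["prevalence"] = np.where(agg["wsum"] > 0, agg["wev"] / agg["wsum"],
                                 np.nan)
    out = agg.reset_index()[["group", "prevalence", "numerator",
                             "denominator"]]
    out["numerator"] = out["numerator"].astype(int)
    return out


def conditional_share(respondents: pd.DataFrame, band: str,
                      indicator: str,
                      grouping: str | pd.Series | None = None) -> pd.DataFrame:
    """Weighted share of an indicator among respondents in one band.

    Used for breakdowns like "no education among women with first birth
    before 16".  ``indicator`` names a boolean (or 0/1) column.
    """
    sub = respondents[respondents["first_birth_band"] == band]
    if len(sub) == 0:
        raise ValueError(f"no respondents in band {band!r}")
    if isinstance(grouping, pd.Series):
        grouping = grouping.loc[sub.index]
    event = sub[indicator].astype(bool)
    tmp = sub.assign(first_birth_band=np.where(event, "_EVT", "_NON"))
    return weighted_prevalence(tmp, "_EVT", grouping)


def prevalence_by_admin(ds: SurveyDataset, band: str,
                        admin_level: int = 2) -> pd.DataFrame:
    """Weighted band prevalence per admin unit; unit id in ``group``.

    Units with no respondents appear with NaN prevalence and zero counts.
    """
    r = ds.respondents.merge(
        ds.clusters[["cluster_id", "district_id"]], on="cluster_id")
    if admin_level == 1:
        parent = {u.unit_id: u.parent_id for u in ds.districts}
        labels = r["district_id"].map(parent)
        all_units = [u.unit_id for u in ds.regions]
    else:
        labels = r["district_id"]
        all_units = [u.unit_id for u in ds.districts]
    est = weighted_prevalence(r, band, labels)
    if all_units:
        est = (est.set_index("group")
               .reindex(all_units)
               .assign(numerator=lambda d: d["numerator"].fillna(0).astype(int),
                       denominator=lambda d: d["denominator"].fillna(0).astype(int))
               .reset_index())
    return est


def prevalence_table(ds: SurveyDataset, grouping: str | pd.Series | None,
                     percent: bool = True, decimals: int = 1) -> pd.DataFrame:
    """Summary table: rows = age bands, columns = groups, weighted prevalence.

    Values are percentages rounded at export time only; internal estimates
    keep full precision.
    """
    cols = {}
    for band in BANDS:
        est = weighted_prevalence(ds.respondents, band, grouping)
        for _, row in est.iterrows():
            cols.setdefault(row["group"], {})[band] = row["prevalence"]
    table = pd.DataFrame(cols).reindex(list(BANDS))
    if percent:
        table = (table * 100.0).round(decimals)
    return table


def wilson_interval(numerator: int, denominator: int,
                    alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval on unweighted counts — diagnostics only.

    The descriptive stage reports no design-based uncertainty; this plain
    binomial interval ignores weighting and clustering.
    """
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(numerator, denominator, alpha=alpha,
                                method="wilson")
    return float(lo), float(hi)


def choropleth_export(units: Sequence[AdminUnit],
                      estimates: pd.DataFrame,
                      path: str | Path,
                      extra_attributes: pd.DataFrame | None = None) -> dict:
    """Write polygons attributed with per-band prevalence to GeoJSON.

    ``estimates`` needs columns ``unit_id``, ``band``, ``prevalence``
    (long form, one row per unit x band).  Each feature carries one
    ``prev_<BAND>`` property per band; ``extra_attributes`` (indexed or
    keyed by ``unit_id``) adds further properties for bivariate maps, e.g.
    an education share.  Units lacking an estimate carry an explicit null.
    """
    ids = [u.unit_id for u in units]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate unit ids {dupes}")
    unknown = set(estimates["unit_id"].astype(str)) - set(ids)
    if unknown:
        raise ValueError(f"estimates reference unknown units {sorted(unknown)}")

    props: dict[str, dict] = {i: {} for i in ids}
    wide = estimates.pivot(index="unit_id", columns="band",
                           values="prevalence")
    for uid in ids:
        for band in BANDS:
            val = wide.at[uid, band] if (uid in wide.index
                                         and band in wide.columns) else np.nan
            props[uid][f"prev_{band}"] = None if pd.isna(val) else float(val)
    if extra_attributes is not None:
        ea = extra_attributes
        if "unit_id" in ea.columns:
            ea = ea.set_index("unit_id")
        for uid in ids:
            if uid in ea.index:
                for col, val in ea.loc[uid].items():
                    props[uid][str(col)] = (None if pd.isna(val)
                                            else float(val))
    doc = admin_units_to_geojson(units, props)
    Path(path).write_text(json.dumps(doc))
    return doc


def preview_choropleth(units: Sequence[AdminUnit], values: dict[str, float],
                       path: str | Path, title: str = "") -> None:
    """Minimal matplotlib shaded-polygon preview (convenience, no contract)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    fig, ax = plt.subplots(figsize=(6, 6))
    polys, vals = [], []
    for u in units:
        geoms = getattr(u.geometry, "geoms", [u.geometry])
        for g in geoms:
            polys.append(np.asarray(g.exterior.coords))
            vals.append(values.get(u.unit_id, np.nan))
    coll = PolyCollection(polys, array=np.asarray(vals), edgecolors="k",
                          linewidths=0.3, cmap="viridis")
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_title(title)
    fig.colorbar(coll, ax=ax, shrink=0.7)
    fig.savefig(path, dpi=120)
    plt.close(fig)
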