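"""Bundled example data: published unweighted sample counts from three
East-African DHS surveys (Kenya 2008, Tanzania 2010, Uganda 2010/11).

The counts describe women aged 20-29 at the time of survey, classified by
age at first birth (<16, 16-17, 18-19, or none before 20), with the
number in each band reporting no education and the number in the bottom
two wealth quintiles.  They serve as a worked example for the weighted-
prevalence estimator: expanding the counts to a respondent-level table
with unit weights reproduces the published percentages exactly.

The education/wealth flags within a band are assigned to disjoint leading
blocks of respondents; only their marginal shares are published, so any
joint arrangement with the correct margins is equivalent for the
estimators in this package.
"""

from __future__ import annotations

import pandas as pd

from .survey_io import BANDS, BASELINE, SurveyDataset

#: Unweighted counts per country: total sample, any birth by time of
#: survey, first births per adolescent band, and within-band counts with
#: no education / in the poorest two wealth quintiles.
PUBLISHED_COUNTS: dict[str, dict] = {
    "Kenya": {
        "n_total": 3167, "n_clusters": 397, "any_birth": 2403,
        "LT16": {"n": 324, "no_education": 105, "bottom_wealth": 166},
        "A16_17": {"n": 546, "no_education": 87, "bottom_wealth": 234},
        "A18_19": {"n": 676, "no_education": 99, "bottom_wealth": 263},
    },
    "Tanzania": {
        "n_total": 3347, "n_clusters": 457, "any_birth": 2641,
        "LT16": {"n": 212, "no_education": 85, "bottom_wealth": 97},
        "A16_17": {"n": 633, "no_education": 190, "bottom_wealth": 267},
        "A18_19": {"n": 855, "no_education": 174, "bottom_wealth": 353},
    },
    "Uganda": {
        "n_total": 3284, "n_clusters": 400, "any_birth": 2742,
        "LT16": {"n": 435, "no_education": 69, "bottom_wealth": 196},
        "A16_17": {"n": 700, "no_education": 110, "bottom_wealth": 320},
        "A18_19": {"n": 766, "no_education": 95, "bottom_wealth": 340},
    },
}


def published_counts_table() -> pd.DataFrame:
    """The published counts as a tidy DataFrame (one row per country/band)."""
    rows = []
    for country, d in PUBLISHED_COUNTS.items():
        for band in BANDS:
            rows.append({"country": country, "band": band,
                         "n": d[band]["n"],
                         "no_education": d[band]["no_education"],
                         "bottom_wealth": d[band]["bottom_wealth"],
                         "n_total": d["n_total"],
                         "any_birth": d["any_birth"]})
    return pd.DataFrame(rows)


def expand_to_respondents() -> pd.DataFrame:
    """Respondent-level table with unit weights reproducing the counts.

    One row per woman: ``country``, ``first_birth_band``, boolean
    ``no_education`` and ``bottom_wealth`` (within-band counts assigned to
    leading blocks), ``any_birth``, unit ``weight``, nominal age 25, and a
    synthetic country-level cluster id.
    """
    rows = []
    rid = 0
    for country, d in PUBLISHED_COUNTS.items():
        n_banded = sum(d[b]["n"] for b in BANDS)
        groups = [(b, d[b]["n"], d[b]["no_education"], d[b]["bottom_wealth"],
                   True) for b in BANDS]
        # first birth at >= 20, and never-mothers, share the baseline code
        groups.append((BASELINE, d["any_birth"] - n_banded, 0, 0, True))
        groups.append((BASELINE, d["n_total"] - d["any_birth"], 0, 0, False))
        for band, n, n_noed, n_poor, any_birth in groups:
            for k in range(n):
                rid += 1
                rows.append({
                    "respondent_id": f"P{rid:06d}",
                    "cluster_id": f"{country[:2].upper()}001",
                    "country": country,
                    "weight": 1.0,
                    "age_at_survey": 25,
                    "first_birth_band": band,
                    "no_education": k < n_noed,
                    "bottom_wealth": k < n_poor,
                    "any_birth": any_birth,
                })
    return pd.DataFrame(rows)


def example_dataset() -> SurveyDataset:
    """The expanded table wrapped as a dataset with one cluster per country."""
    respondents = expand_to_respondents()
    clusters = pd.DataFrame({
        "cluster_id": sorted(respondents["cluster_id"].unique()),
    })
    coords = {"KE001": (37.0, 0.0), "TA001": (35.0, -6.0),
              "UG001": (32.5, 1.0)}
    clusters["lon"] = clusters["cluster_id"].map(lambda c: coords[c][0])
    clusters["lat"] = clusters["cluster_id"].map(lambda c: coords[c][1])
    clusters["urban"] = False
    clusters["district_id"] = clusters["cluster_id"]
    return SurveyDataset(respondents=respondents, clusters=clusters)
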