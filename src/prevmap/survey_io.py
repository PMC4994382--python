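"""Reading, writing and validating the pipeline's tabular and geographic data.

The pipeline operates on three linked tables:

* **respondents** — one row per surveyed woman aged 20-29: ``respondent_id``,
  ``cluster_id``, ``weight`` (positive survey weight), ``age_at_survey``
  (integer years, 20-29) and ``first_birth_band``, one of the codes in
  :data:`BANDS`.
* **clusters** — one row per survey cluster (primary sampling unit):
  ``cluster_id``, published (displaced) ``lon``/``lat`` in WGS84 degrees,
  ``urban`` flag and ``district_id``.
* **admin units** — polygons at level 1 (region) and level 2 (district),
  exchanged as GeoJSON in WGS84 lon/lat.

District membership of a respondent is taken from the cluster's recorded
``district_id`` — the way region codes travel with published survey
clusters — never by point-in-polygon on displaced coordinates.  A utility
(:func:`assign_districts_by_point`) performs spatial assignment for
datasets lacking the field; because published coordinates are displaced by
up to 2 km (urban) / 5 km (rural), such assignment can misclassify
clusters near district borders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

#: Age-at-first-birth outcome codes: before 16, 16-17, 18-19, and the
#: baseline "no birth before age 20".
BANDS = ("LT16", "A16_17", "A18_19")
BASELINE = "NONE_BEFORE_20"
ALL_CODES = BANDS + (BASELINE,)

RESPONDENT_COLUMNS = ["respondent_id", "cluster_id", "weight",
                      "age_at_survey", "first_birth_band"]
CLUSTER_COLUMNS = ["cluster_id", "lon", "lat", "urban", "district_id"]


class IntegrityError(ValueError):
    """A foreign key or invariant of the linked survey tables is violated."""


class GeometryError(ValueError):
    """An administrative boundary geometry is invalid."""


@dataclass
class AdminUnit:
    """Administrative polygon at level 1 (region) or level 2 (district)."""

    unit_id: str
    level: int
    geometry: BaseGeometry
    name: str = ""
    parent_id: str | None = None

    def __post_init__(self):
        if self.level not in (1, 2):
            raise ValueError(f"admin level must be 1 or 2, got {self.level}")
        if self.level == 2 and self.parent_id is None:
            raise ValueError(f"level-2 unit {self.unit_id!r} needs a parent_id")
        if not self.geometry.is_valid:
            raise GeometryError(f"invalid geometry for unit {self.unit_id!r}")


@dataclass
class SurveyDataset:
    """The three linked tables plus the admin units they reference."""

    respondents: pd.DataFrame
    clusters: pd.DataFrame
    admin_units: list[AdminUnit] = field(default_factory=list)

    @property
    def districts(self) -> list[AdminUnit]:
        return [u for u in self.admin_units if u.level == 2]

    @property
    def regions(self) -> list[AdminUnit]:
        return [u for u in self.admin_units if u.level == 1]


def admin_units_to_geojson(units: Sequence[AdminUnit],
                           properties: dict[str, dict] | None = None) -> dict:
    """Build a GeoJSON FeatureCollection; optional extra properties per unit."""
    features = []
    for u in units:
        props = {"unit_id": u.unit_id, "level": u.level, "name": u.name,
                 "parent_id": u.parent_id}
        if properties is not None:
            props.update(properties.get(u.unit_id, {}))
        features.append({"type": "Feature",
                         "geometry": mapping(u.geometry),
                         "properties": props})
    return {"type": "FeatureCollection", "features": features}


def write_admin_units(units: Sequence[AdminUnit], path: str | Path,
                      properties: dict[str, dict] | None = None) -> None:
    Path(path).write_text(json.dumps(admin_units_to_geojson(units, properties)))


def read_admin_units(path: str | Path) -> list[AdminUnit]:
    """Load admin polygons from a GeoJSON FeatureCollection (WGS84 lon/lat)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise GeometryError(f"{path}: expected a GeoJSON FeatureCollection")
    units = []
    for feat in doc["features"]:
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise GeometryError(
                f"{path}: invalid geometry for unit "
                f"{feat['properties'].get('unit_id')!r}")
        p = feat["properties"]
        units.append(AdminUnit(unit_id=str(p["unit_id"]), level=int(p["level"]),
                               geometry=geom, name=p.get("name") or "",
                               parent_id=p.get("parent_id")))
    return units


def validate_dataset(ds: SurveyDataset) -> None:
    """Check invariants and referential integrity; raise naming offenders."""
    r, c = ds.respondents, ds.clusters
    missing = [col for col in RESPONDENT_COLUMNS if col not in r.columns]
    if missing:
        raise IntegrityError(f"respondent table missing columns {missing}")
    missing = [col for col in CLUSTER_COLUMNS if col not in c.columns]
    if missing:
        raise IntegrityError(f"cluster table missing columns {missing}")

    if (r["weight"] <= 0).any():
        bad = r.loc[r["weight"] <= 0, "respondent_id"].tolist()
        raise IntegrityError(f"non-positive weights for respondents {bad[:10]}")
    ages = r["age_at_survey"]
    if ((ages < 20) | (ages > 29)).any():
        bad = r.loc[(ages < 20) | (ages > 29), "respondent_id"].tolist()
        raise IntegrityError(f"age_at_survey outside [20, 29] for {bad[:10]}")
    bad_band = ~r["first_birth_band"].isin(ALL_CODES)
    if bad_band.any():
        raise IntegrityError(
            f"unknown first_birth_band codes "
            f"{sorted(r.loc[bad_band, 'first_birth_band'].unique())}")

    if c["cluster_id"].duplicated().any():
        dups = c.loc[c["cluster_id"].duplicated(), "cluster_id"].tolist()
        raise IntegrityError(f"duplicate cluster ids {dups}")
    if ((c["lon"] < -180) | (c["lon"] > 180) |
            (c["lat"] < -90) | (c["lat"] > 90)).any():
        raise IntegrityError("cluster coordinates outside WGS84 bounds")

    unknown = set(r["cluster_id"]) - set(c["cluster_id"])
    if unknown:
        offenders = r.loc[r["cluster_id"].isin(unknown), "respondent_id"]
        raise IntegrityError(
            f"respondents {offenders.tolist()[:10]} reference unknown "
            f"clusters {sorted(unknown)[:10]}")

    if ds.admin_units:
        district_ids = {u.unit_id for u in ds.districts}
        region_ids = {u.unit_id for u in ds.regions}
        unknown = set(c["district_id"].astype(str)) - district_ids
        if unknown:
            raise IntegrityError(
                f"clusters reference unknown districts {sorted(unknown)[:10]}")
        orphans = [u.unit_id for u in ds.districts
                   if u.parent_id not in region_ids]
        if orphans:
            raise IntegrityError(
                f"districts {orphans[:10]} reference unknown parent regions")


def load_survey(respondent_path: str | Path, cluster_path: str | Path,
                boundary_path: str | Path | None = None) -> SurveyDataset:
    """Load and validate the linked tables; unknown extra columns pass through."""
    respondents = pd.read_csv(respondent_path)
    clusters = pd.read_csv(cluster_path)
    clusters["cluster_id"] = clusters["cluster_id"].astype(str)
    respondents["cluster_id"] = respondents["cluster_id"].astype(str)
    if "district_id" in clusters.columns:
        clusters["district_id"] = clusters["district_id"].astype(str)
    units = read_admin_units(boundary_path) if boundary_path else []
    ds = SurveyDataset(respondents=respondents, clusters=clusters,
                       admin_units=units)
    validate_dataset(ds)
    return ds


def write_survey(ds: SurveyDataset, respondent_path: str | Path,
                 cluster_path: str | Path,
                 boundary_path: str | Path | None = None) -> None:
    ds.respondents.to_csv(respondent_path, index=False)
    ds.clusters.to_csv(cluster_path, index=False)
    if boundary_path and ds.admin_units:
        write_admin_units(ds.admin_units, boundary_path)


def assign_districts_by_point(clusters: pd.DataFrame,
                              districts: Iterable[AdminUnit]) -> pd.Series:
    """Assign each cluster to the district polygon containing its point.

    Intended for datasets lacking a recorded district code.  Displaced
    coordinates can land in a neighbouring district, so assignments near
    borders carry misclassification risk.  Points outside every polygon get
    the nearest district by boundary distance.
    """
    from shapely.geometry import Point

    districts = list(districts)
    out = []
    for lon, lat in zip(clusters["lon"], clusters["lat"]):
        pt = Point(lon, lat)
        hit = next((u.unit_id for u in districts if u.geometry.covers(pt)), None)
        if hit is None:
            hit = min(districts, key=lambda u: u.geometry.distance(pt)).unit_id
        out.append(hit)
    return pd.Series(out, index=clusters.index, name="district_id")


def outcome_counts(ds: SurveyDataset, admin_level: int, band: str,
                   cumulative: bool = False) -> pd.DataFrame:
    """Per-admin-unit event/trial counts (y_d, n_d) for one age band.

    ``y_d`` counts respondents in the unit's clusters whose first birth falls
    in ``band`` (or, with ``cumulative=True``, in that band or any younger
    band — "before age 20" when ``band="A18_19"``); ``n_d`` counts all
    respondents in the unit's clusters.  Units with no clusters appear with
    ``(0, 0)`` so that downstream small-area models can treat them as
    unobserved districts rather than silently dropping them.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {BANDS}")
    if admin_level not in (1, 2):
        raise ValueError("admin_level must be 1 or 2")

    r = ds.respondents.merge(
        ds.clusters[["cluster_id", "district_id"]], on="cluster_id", how="left")
    if admin_level == 1:
        parent = {u.unit_id: u.parent_id for u in ds.districts}
        r["unit_id"] = r["district_id"].map(parent)
        all_units = [u.unit_id for u in ds.regions]
    else:
        r["unit_id"] = r["district_id"]
        all_units = [u.unit_id for u in ds.districts]
    if not all_units:  # no boundaries supplied: use observed districts
        all_units = sorted(r["unit_id"].dropna().unique())

    if cumulative:
        event_codes = BANDS[:BANDS.index(band) + 1]
    else:
        event_codes = (band,)
    grouped = r.groupby("unit_id")
    n = grouped.size()
    y = grouped["first_birth_band"].apply(
        lambda s: int(s.isin(event_codes).sum()))
    out = pd.DataFrame({"unit_id": all_units})
    out["y"] = out["unit_id"].map(y).fillna(0).astype(int)
    out["n"] = out["unit_id"].map(n).fillna(0).astype(int)
    return out


def band_counts_wide(ds: SurveyDataset, admin_level: int) -> pd.DataFrame:
    """Events per band plus trials, one row per admin unit."""
    frames = {}
    for b in BANDS:
        t = outcome_counts(ds, admin_level, b).set_index("unit_id")
        frames[b] = t["y"]
        frames["n"] = t["n"]
    out = pd.DataFrame(frames).reset_index()
    return out
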