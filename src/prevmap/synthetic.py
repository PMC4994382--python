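"""DHS-like synthetic survey generator with known spatial structure.

Emulates the structure of a georeferenced cluster survey of women aged
20-29 in an East-African setting: nested admin polygons (regions tiled
into districts), survey clusters with GPS displacement (up to 2 km urban /
5 km rural), lognormal survey weights, and a four-category age-at-first-
birth outcome (<16, 16-17, 18-19, none before 20) driven by a
multinomial-logit model with district-level spatial structure.

Each outcome band k has its own pair of district random effects: a
spatially structured effect u drawn from the intrinsic conditional
autoregressive (ICAR) distribution over the district contiguity graph, and
an unstructured i.i.d. normal effect v.  Category probabilities are

    p_dk = softmax(beta0_k + u_dk + v_dk)   (baseline logit fixed at 0),

so the marginal model for any single band is exactly the binomial
logit-BYM model the small-area stage fits — parameter recovery is testable
against stored ground truth.

Default scale mirrors a single-country survey of the kind the pipeline
targets: 40 districts in 8 regions, ~420 clusters, ~3,300 respondents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon

from .adjacency import AdjacencyGraph, build_adjacency
from .geometry import KM_PER_DEG_LAT, km_offset_to_lonlat
from .survey_io import AdminUnit, BANDS, BASELINE, SurveyDataset

#: DHS confidentiality displacement radii, km.
URBAN_DISPLACEMENT_KM = 2.0
RURAL_DISPLACEMENT_KM = 5.0


class ConfigError(ValueError):
    """Invalid synthetic-survey configuration."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic survey.

    ``beta0`` holds the three multinomial-logit intercepts for the bands
    (<16, 16-17, 18-19) against the baseline "no birth before 20" (logit
    0).  Defaults reproduce pooled prevalences of roughly 10 / 20 / 25 %,
    the magnitudes typical of the East-African surveys this generator
    emulates.  ``sigma_u``/``sigma_v`` are the marginal SDs of the
    structured and unstructured district effects; ``weight_cv`` the
    coefficient of variation of the lognormal survey weights.
    """

    n_regions: int = 8
    districts_per_region: int = 5
    clusters_per_district_mean: float = 10.5
    cluster_size_mean: float = 8.0
    urban_fraction: float = 0.25
    beta0: tuple[float, float, float] = (-1.535, -0.832, -0.603)
    sigma_u: float = 0.3
    sigma_v: float = 0.15
    weight_cv: float = 0.3
    cell_size_km: float = 50.0
    origin_lonlat: tuple[float, float] = (32.0, -4.0)
    reassign_district_from_displaced: bool = False
    seed: int | None = None

    def validate(self) -> None:
        if self.n_regions < 1 or self.districts_per_region < 1:
            raise ConfigError("n_regions and districts_per_region must be >= 1")
        if self.clusters_per_district_mean <= 0 or self.cluster_size_mean <= 0:
            raise ConfigError("cluster count/size means must be positive")
        if not 0.0 <= self.urban_fraction <= 1.0:
            raise ConfigError("urban_fraction must be in [0, 1]")
        if self.sigma_u < 0 or self.sigma_v < 0 or self.weight_cv < 0:
            raise ConfigError("sigma_u, sigma_v, weight_cv must be >= 0")
        if self.cell_size_km <= 0:
            raise ConfigError("cell_size_km must be positive")
        if len(tuple(self.beta0)) != 3:
            raise ConfigError("beta0 must have one intercept per band")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(doc) - known
        if extra:
            raise ConfigError(f"unknown config keys {sorted(extra)}")
        cfg = cls(**doc)
        if isinstance(cfg.beta0, list):
            cfg.beta0 = tuple(cfg.beta0)
        if isinstance(cfg.origin_lonlat, list):
            cfg.origin_lonlat = tuple(cfg.origin_lonlat)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta0"] = list(self.beta0)
        d["origin_lonlat"] = list(self.origin_lonlat)
        return d


def _block_shape(n: int) -> tuple[int, int]:
    """Largest divisor pair (rows, cols), rows <= cols, rows*cols = n."""
    r = int(np.floor(np.sqrt(n)))
    while n % r:
        r -= 1
    return r, n // r


def make_admin_grid(n_regions: int, districts_per_region: int,
                    cell_size_km: float,
                    origin_lonlat: tuple[float, float] = (32.0, -4.0),
                    ) -> list[AdminUnit]:
    """Rectangular lattice of district cells tiled into contiguous regions.

    Each district is one square cell of edge ``cell_size_km``; each region
    is a near-square block of ``districts_per_region`` cells; region blocks
    are stacked northward from the origin (the lattice's south-west
    corner).  Cell edges are converted to degrees with a local flat-earth
    scaling anchored at the origin latitude, so planar areas in the local
    km frame are exact multiples of ``cell_size_km**2``.

    Returns level-1 region units followed by level-2 district units.
    """
    if n_regions < 1 or districts_per_region < 1:
        raise ConfigError("counts must be >= 1")
    if cell_size_km <= 0:
        raise ConfigError("cell_size_km must be positive")

    lon0, lat0 = origin_lonlat
    dlat = cell_size_km / KM_PER_DEG_LAT
    dlon = cell_size_km / (KM_PER_DEG_LAT * np.cos(np.radians(lat0)))
    block_rows, block_cols = _block_shape(districts_per_region)

    # shared lattice coordinates: neighbouring cells reference the exact
    # same floats, so shapely sees shared edges rather than hairline gaps
    lat_edges = lat0 + np.arange(n_regions * block_rows + 1) * dlat
    lon_edges = lon0 + np.arange(block_cols + 1) * dlon

    regions: list[AdminUnit] = []
    districts: list[AdminUnit] = []
    for g in range(n_regions):
        rid = f"R{g + 1:02d}"
        row_off = g * block_rows
        y_lo, y_hi = lat_edges[row_off], lat_edges[row_off + block_rows]
        regions.append(AdminUnit(
            unit_id=rid, level=1, name=f"Region {g + 1}",
            geometry=Polygon([(lon_edges[0], y_lo), (lon_edges[-1], y_lo),
                              (lon_edges[-1], y_hi), (lon_edges[0], y_hi)])))
        for k in range(districts_per_region):
            r, c = divmod(k, block_cols)
            x0, x1 = lon_edges[c], lon_edges[c + 1]
            y0, y1 = lat_edges[row_off + r], lat_edges[row_off + r + 1]
            districts.append(AdminUnit(
                unit_id=f"{rid}D{k + 1:02d}", level=2, parent_id=rid,
                name=f"District {g + 1}.{k + 1}",
                geometry=Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])))
    return regions + districts


def simulate_bym_effects(adjacency: AdjacencyGraph, sigma_u: float,
                         sigma_v: float,
                         seed: int | np.random.Generator,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Draw one structured (ICAR) and one unstructured district effect field.

    ``u`` is multivariate normal with covariance ``sigma_u**2 * Q^+`` where
    ``Q^+`` is the Moore-Penrose pseudo-inverse of the graph Laplacian —
    the proper distribution induced by the intrinsic autoregressive kernel
    under the sum-to-zero constraint.  ``v`` is i.i.d. normal(0,
    ``sigma_v**2``).  Returned arrays are ordered like ``adjacency.ids``.
    """
    if sigma_u < 0 or sigma_v < 0:
        raise ValueError("effect SDs must be >= 0")
    if adjacency.n_components() > 1:
        raise ValueError(
            "adjacency graph is disconnected; apply an island policy "
            "(build_adjacency(..., island_policy='join_nearest')) first")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = adjacency.n
    if sigma_u == 0 or n == 1:
        u = np.zeros(n)
    else:
        q = adjacency.laplacian()
        evals, evecs = np.linalg.eigh(q)
        keep = evals > 1e-10 * evals.max()
        z = rng.standard_normal(keep.sum())
        u = sigma_u * evecs[:, keep] @ (z / np.sqrt(evals[keep]))
        u -= u.mean()  # numerically exact sum-to-zero
    v = rng.normal(0.0, sigma_v, size=n) if sigma_v > 0 else np.zeros(n)
    return u, v


def displace_cluster(lonlat: tuple[float, float], urban: bool,
                     seed: int | np.random.Generator,
                     ) -> tuple[float, float]:
    """Random GPS displacement: uniform angle, distance uniform on
    [0, 2 km] (urban) or [0, 5 km] (rural), in a local flat-earth frame."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    max_km = URBAN_DISPLACEMENT_KM if urban else RURAL_DISPLACEMENT_KM
    theta = rng.uniform(0.0, 2.0 * np.pi)
    dist = rng.uniform(0.0, max_km)
    lon, lat = km_offset_to_lonlat(lonlat[0], lonlat[1],
                                   dist * np.cos(theta), dist * np.sin(theta))
    return float(lon), float(lat)


def _uniform_point_in(poly: Polygon, rng: np.random.Generator) -> Point:
    minx, miny, maxx, maxy = poly.bounds
    while True:
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if poly.covers(p):
            return p


def _truncated_poisson_ge1(mean: float, size: int,
                           rng: np.random.Generator) -> np.ndarray:
    out = rng.poisson(mean, size=size)
    while (zero := out == 0).any():
        out[zero] = rng.poisson(mean, size=int(zero.sum()))
    return out


def district_probabilities(beta0: Sequence[float], u: np.ndarray,
                           v: np.ndarray) -> np.ndarray:
    """Softmax category probabilities, baseline last; shape (n, 4).

    ``u``/``v`` have shape (3, n) — one effect field per band.
    """
    logits = np.asarray(beta0, dtype=float)[:, None] + u + v  # (3, n)
    full = np.vstack([logits, np.zeros((1, logits.shape[1]))])
    full -= full.max(axis=0, keepdims=True)
    p = np.exp(full)
    p /= p.sum(axis=0, keepdims=True)
    return p.T


def simulate_survey(config: SyntheticConfig,
                    admin_units: Sequence[AdminUnit] | None = None,
                    ) -> tuple[SurveyDataset, pd.DataFrame]:
    """Generate a full synthetic survey and its ground-truth record.

    Returns ``(dataset, truth)`` where ``truth`` has one row per district:
    the four true category probabilities and the true u/v effect per band.
    Cluster counts per district are Poisson (zero-cluster districts are
    kept — they exercise the unobserved-district path downstream); cluster
    sizes are Poisson truncated to >= 1; weights are lognormal normalised
    to mean 1.  All draws descend from ``config.seed``.
    """
    config.validate()
    if admin_units is None:
        admin_units = make_admin_grid(config.n_regions,
                                      config.districts_per_region,
                                      config.cell_size_km,
                                      config.origin_lonlat)
    admin_units = list(admin_units)
    districts = [un for un in admin_units if un.level == 2]
    if not districts:
        raise ConfigError("admin unit set contains no level-2 districts")

    rng = np.random.default_rng(config.seed)
    graph = build_adjacency(districts)
    nd = len(districts)

    u = np.zeros((3, nd))
    v = np.zeros((3, nd))
    for k in range(3):
        u[k], v[k] = simulate_bym_effects(graph, config.sigma_u,
                                          config.sigma_v, rng)
    probs = district_probabilities(config.beta0, u, v)  # (nd, 4)

    id_order = {d: k for k, d in enumerate(graph.ids)}
    truth = pd.DataFrame({
        "district_id": graph.ids,
        "p_lt16": probs[:, 0], "p_16_17": probs[:, 1],
        "p_18_19": probs[:, 2], "p_none": probs[:, 3],
    })
    for k, band in enumerate(BANDS):
        truth[f"u_{band}"] = u[k]
        truth[f"v_{band}"] = v[k]

    # Clusters
    cluster_rows = []
    counts = rng.poisson(config.clusters_per_district_mean, size=nd)
    cid = 0
    for d_unit in districts:
        for _ in range(counts[id_order[d_unit.unit_id]]):
            cid += 1
            pt = _uniform_point_in(d_unit.geometry, rng)
            urban = bool(rng.random() < config.urban_fraction)
            lon, lat = displace_cluster((pt.x, pt.y), urban, rng)
            cluster_rows.append({
                "cluster_id": f"C{cid:05d}", "lon": lon, "lat": lat,
                "true_lon": pt.x, "true_lat": pt.y, "urban": urban,
                "district_id": d_unit.unit_id})
    clusters = pd.DataFrame(cluster_rows,
                            columns=["cluster_id", "lon", "lat", "true_lon",
                                     "true_lat", "urban", "district_id"])
    if config.reassign_district_from_displaced and len(clusters):
        from .survey_io import assign_districts_by_point
        clusters["district_id"] = assign_districts_by_point(clusters, districts)

    # Respondents
    resp_rows = []
    if len(clusters):
        sizes = _truncated_poisson_ge1(config.cluster_size_mean,
                                       len(clusters), rng)
        codes = list(BANDS) + [BASELINE]
        rid = 0
        for crow, size in zip(clusters.itertuples(index=False), sizes):
            p = probs[id_order[crow.district_id]]
            bands = rng.choice(4, size=size, p=p)
            ages = rng.integers(20, 30, size=size)
            for b, a in zip(bands, ages):
                rid += 1
                resp_rows.append({"respondent_id": f"W{rid:06d}",
                                  "cluster_id": crow.cluster_id,
                                  "weight": 1.0, "age_at_survey": int(a),
                                  "first_birth_band": codes[b]})
    respondents = pd.DataFrame(resp_rows,
                               columns=["respondent_id", "cluster_id",
                                        "weight", "age_at_survey",
                                        "first_birth_band"])
    if len(respondents) and config.weight_cv > 0:
        s2 = np.log1p(config.weight_cv ** 2)
        w = rng.lognormal(-s2 / 2.0, np.sqrt(s2), size=len(respondents))
        respondents["weight"] = w / w.mean()

    ds = SurveyDataset(respondents=respondents, clusters=clusters,
                       admin_units=admin_units)
    return ds, truth
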