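"""Adaptive-bandwidth kernel prevalence surfaces ("heat maps").

A prevalence surface is the cellwise ratio of two kernel density
estimates built with *identical* bandwidths and weights: a case surface
(band events per cluster) over a control surface (all respondents per
cluster).  Because numerator and denominator share every kernel term, the
ratio is a locally weighted prevalence: it is exactly constant when every
cluster has the same prevalence, and always lies between the minimum and
maximum cluster prevalence.

Bandwidths are adaptive, nearest-neighbour style: each cluster's radius
h_i grows until the kernels centred there encompass at least ``n_opt``
surveyed persons, so the surface is smooth in sparse rural areas and
sharp in dense urban ones.  ``n_opt`` is a tunable — around 500 for a
full national survey; :func:`default_n_opt` scales it for smaller
synthetic runs.

The kernel is an isotropic bivariate Gaussian over great-circle distance;
a truncated quartic (biweight) kernel is available for sensitivity
checks.  Cells whose control density falls below a support floor are
masked as no-data rather than reporting a far-extrapolated ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import KM_PER_DEG_LAT, haversine_km, pairwise_haversine_km

#: DHS-scale default for the optimal-number-of-persons parameter.
DEFAULT_N_OPT = 500


class GridMismatchError(ValueError):
    """Two rasters do not share the same grid."""


@dataclass(frozen=True)
class GridSpec:
    """Raster grid: north-west corner origin, row-major indexing.

    ``origin_lon``/``origin_lat`` locate the NW corner of the NW cell;
    rows advance southward, columns eastward, in steps of ``cell_size_km``
    under the local flat-earth frame anchored at the origin latitude.
    """

    origin_lon: float
    origin_lat: float
    cell_size_km: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.cell_size_km <= 0 or self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid needs positive cell size and dimensions")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) at cell centres."""
        dlat = self.cell_size_km / KM_PER_DEG_LAT
        dlon = self.cell_size_km / (KM_PER_DEG_LAT
                                    * np.cos(np.radians(self.origin_lat)))
        rows = np.arange(self.n_rows)
        cols = np.arange(self.n_cols)
        lat = self.origin_lat - (rows + 0.5) * dlat
        lon = self.origin_lon + (cols + 0.5) * dlon
        return np.meshgrid(lon, lat)

    @classmethod
    def covering(cls, lon, lat, cell_size_km: float,
                 pad_km: float = 0.0) -> "GridSpec":
        """Smallest grid covering the given points, with optional padding."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lat0 = float(lat.max())
        dlat = cell_size_km / KM_PER_DEG_LAT
        dlon = cell_size_km / (KM_PER_DEG_LAT * np.cos(np.radians(lat0)))
        pad_lat = pad_km / KM_PER_DEG_LAT
        pad_lon = pad_km / (KM_PER_DEG_LAT * np.cos(np.radians(lat0)))
        o_lon = float(lon.min()) - pad_lon
        o_lat = lat0 + pad_lat
        n_rows = int(np.ceil((o_lat - (lat.min() - pad_lat)) / dlat)) or 1
        n_cols = int(np.ceil(((lon.max() + pad_lon) - o_lon) / dlon)) or 1
        return cls(o_lon, o_lat, cell_size_km, n_rows, n_cols)


@dataclass
class PrevalenceSurface:
    """Raster of prevalence values with a support mask."""

    grid: GridSpec
    values: np.ndarray  # NaN where masked
    mask: np.ndarray    # True where supported

    def __post_init__(self):
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise GridMismatchError("values shape does not match grid")
        ok = self.values[self.mask]
        if ok.size and (np.isnan(ok).any()):
            raise ValueError("unmasked cells must carry values")


def default_n_opt(cluster_sizes: np.ndarray) -> int:
    """Synthetic-run default: max(5 x mean cluster size, total / 20)."""
    sizes = np.asarray(cluster_sizes, dtype=float)
    return int(max(5.0 * sizes.mean(), sizes.sum() / 20.0, 1.0))


def compute_bandwidths(clusters: pd.DataFrame, cluster_sizes,
                       n_opt: int) -> pd.DataFrame:
    """Adaptive nearest-neighbour bandwidth per cluster.

    h_i is the great-circle distance at which the cumulative respondent
    count — the cluster's own size plus all clusters within h_i — first
    reaches ``n_opt``.  A cluster already holding ``n_opt`` respondents
    takes the distance to its nearest other cluster (floor rule).  If the
    whole sample holds fewer than ``n_opt`` respondents, h_i is the
    distance to the farthest cluster and a warning is issued.
    """
    if n_opt < 1:
        raise ValueError("n_opt must be >= 1")
    if len(clusters) == 0:
        raise ValueError("at least one cluster required")
    sizes = np.asarray(cluster_sizes, dtype=float)
    dist = pairwise_haversine_km(clusters["lon"].to_numpy(),
                                 clusters["lat"].to_numpy())
    m = len(clusters)
    total = sizes.sum()
    if total < n_opt:
        warnings.warn(
            f"total sample {int(total)} < n_opt={n_opt}; bandwidths fall "
            "back to the farthest-cluster distance", stacklevel=2)
    h = np.empty(m)
    encompassed = np.empty(m, dtype=int)
    eps = 1e-6  # km floor against coincident coordinates
    for i in range(m):
        order = np.argsort(dist[i])
        d_sorted = dist[i][order]
        cum = np.cumsum(sizes[order])
        if total < n_opt:
            h[i] = max(d_sorted[-1], eps)
            encompassed[i] = int(total)
        elif sizes[i] >= n_opt and m > 1:
            h[i] = max(d_sorted[1], eps)  # nearest other cluster
            encompassed[i] = int(cum[np.searchsorted(d_sorted, h[i],
                                                     side="right") - 1])
        elif m == 1:
            warnings.warn("single cluster below n_opt; degenerate bandwidth",
                          stacklevel=2)
            h[i] = eps
            encompassed[i] = int(sizes[i])
        else:
            k = int(np.searchsorted(cum, n_opt))
            h[i] = max(d_sorted[k], eps)
            # ties: include every cluster at exactly distance h
            encompassed[i] = int(cum[np.searchsorted(d_sorted, h[i],
                                                     side="right") - 1])
    return pd.DataFrame({"cluster_id": clusters["cluster_id"].to_numpy(),
                         "bandwidth_km": h, "encompassed": encompassed})


def _kernel(d_over_h: np.ndarray, kind: str) -> np.ndarray:
    if kind == "gaussian":
        return np.exp(-0.5 * d_over_h ** 2) / (2.0 * np.pi)
    if kind == "quartic":
        t = 1.0 - d_over_h ** 2
        return np.where(d_over_h < 1.0, (3.0 / np.pi) * t * t, 0.0)
    raise ValueError(f"unknown kernel {kind!r}")


def density_surface(clusters: pd.DataFrame, values, weights, bandwidths,
                    grid: GridSpec, kernel: str = "gaussian") -> np.ndarray:
    """Weighted kernel density raster.

    Each cell holds ``sum_i value_i * w_i * K(d(cell, i) / h_i) / h_i**2``
    with K a bivariate Gaussian (or truncated quartic) and d great-circle
    distance in km.  Deterministic.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    h = np.asarray(bandwidths, dtype=float)
    if not len(clusters) == len(values) == len(weights) == len(h):
        raise ValueError("clusters, values, weights, bandwidths must align")
    if (h <= 0).any():
        raise ValueError("bandwidths must be strictly positive")
    lon_g, lat_g = grid.cell_centers()
    out = np.zeros(lon_g.shape)
    clon = clusters["lon"].to_numpy()
    clat = clusters["lat"].to_numpy()
    # loop over clusters: memory O(grid) instead of O(grid x clusters)
    for i in range(len(clusters)):
        d = haversine_km(lon_g, lat_g, clon[i], clat[i])
        out += values[i] * weights[i] * _kernel(d / h[i], kernel) / h[i] ** 2
    return out


def prevalence_surface(case_density: np.ndarray, control_density: np.ndarray,
                       grid: GridSpec,
                       support_floor: float) -> PrevalenceSurface:
    """Cellwise case/control density ratio where support suffices.

    Both rasters must come from :func:`density_surface` on the same grid
    with identical bandwidths and weights (cases = band events y_i,
    controls = all respondents n_i), which makes the ratio a prevalence.
    Cells with control density below ``support_floor`` are masked.
    """
    if case_density.shape != control_density.shape or \
            case_density.shape != (grid.n_rows, grid.n_cols):
        raise GridMismatchError("case/control rasters must share the grid")
    mask = control_density >= support_floor
    vals = np.full(case_density.shape, np.nan)
    np.divide(case_density, control_density, out=vals, where=mask)
    return PrevalenceSurface(grid=grid, values=vals, mask=mask)


def default_support_floor(bandwidths, kernel: str = "gaussian") -> float:
    """Density one respondent contributes at twice the median bandwidth.

    Guards the ratio against cells supported only by far kernel tails.
    """
    h = float(np.median(np.asarray(bandwidths, dtype=float)))
    return float(_kernel(np.asarray(2.0), kernel) / h ** 2)


def band_prevalence_surface(ds, band: str, n_opt: int | None = None,
                            cell_size_km: float = 5.0,
                            kernel: str = "gaussian",
                            weighted: bool = True,
                            support_floor: float | None = None,
                            pad_km: float = 20.0):
    """End-to-end surface for one age band from a survey dataset.

    Returns ``(surface, bandwidth_table, grid)``.  Case values are the
    per-cluster event counts y_i, control values the respondent counts
    n_i, sharing one kernel weight per cluster (the mean respondent
    weight, or 1 when ``weighted`` is False) — identical bandwidths and
    weights on both sides preserve the ratio's prevalence interpretation.
    """
    r = ds.respondents
    per_cluster = r.groupby("cluster_id").agg(
        n=("respondent_id", "size"),
        y=("first_birth_band", lambda s: int((s == band).sum())),
        wsum=("weight", "sum"))
    clusters = ds.clusters[ds.clusters["cluster_id"].isin(per_cluster.index)]
    clusters = clusters.reset_index(drop=True)
    stats = per_cluster.loc[clusters["cluster_id"]].reset_index(drop=True)
    if n_opt is None:
        n_opt = default_n_opt(stats["n"].to_numpy())
    bw = compute_bandwidths(clusters, stats["n"].to_numpy(), n_opt)
    grid = GridSpec.covering(clusters["lon"], clusters["lat"],
                             cell_size_km, pad_km=pad_km)
    n_i = stats["n"].to_numpy(dtype=float)
    y_i = stats["y"].to_numpy(dtype=float)
    w = (stats["wsum"].to_numpy() / n_i) if weighted else np.ones(len(clusters))
    h = bw["bandwidth_km"].to_numpy()
    control = density_surface(clusters, n_i, w, h, grid, kernel)
    case = density_surface(clusters, y_i, w, h, grid, kernel)
    if support_floor is None:
        support_floor = default_support_floor(h, kernel)
    surf = prevalence_surface(case, control, grid, support_floor)
    return surf, bw, grid


def write_ascii_grid(surface: PrevalenceSurface, path,
                     nodata: float = -9999.0) -> None:
    """Esri ASCII grid (.asc) with NODATA for masked cells.

    Cell size is written in degrees of latitude; east-west spacing matches
    only near the anchor latitude (inherent to plate-carree ASCII grids).
    """
    g = surface.grid
    dlat = g.cell_size_km / KM_PER_DEG_LAT
    vals = np.where(surface.mask, surface.values, nodata)
    lines = [
        f"ncols {g.n_cols}",
        f"nrows {g.n_rows}",
        f"xllcorner {g.origin_lon:.8f}",
        f"yllcorner {g.origin_lat - g.n_rows * dlat:.8f}",
        f"cellsize {dlat:.10f}",
        f"NODATA_value {nodata}",
    ]
    for row in vals:
        lines.append(" ".join(f"{v:.8g}" for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def surface_to_csv(surface: PrevalenceSurface, path) -> pd.DataFrame:
    """CSV of (lon, lat, value) for unmasked cells; returns the frame."""
    lon_g, lat_g = surface.grid.cell_centers()
    m = surface.mask
    df = pd.DataFrame({"lon": lon_g[m], "lat": lat_g[m],
                       "value": surface.values[m]})
    df.to_csv(path, index=False)
    return df
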