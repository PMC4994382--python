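"""Adaptive bandwidths and kernel prevalence surfaces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from prevmap import compute_bandwidths, density_surface, prevalence_surface
from prevmap.geometry import KM_PER_DEG_LAT
from prevmap.kde import (GridMismatchError, GridSpec, band_prevalence_surface,
                         default_support_floor, surface_to_csv,
                         write_ascii_grid)


def _collinear_clusters(km_positions):
    """Clusters along the equator at given eastward km offsets."""
    return pd.DataFrame({
        "cluster_id": [f"c{i}" for i in range(len(km_positions))],
        "lon": [30.0 + d / KM_PER_DEG_LAT for d in km_positions],
        "lat": 0.0})


class TestBandwidths:
    def test_cumulative_count_rule_on_collinear_clusters(self):
        clusters = _collinear_clusters([0.0, 1.0, 3.0])
        bw = compute_bandwidths(clusters, [10, 10, 10], n_opt=15)
        # at the origin cluster: own 10 < 15, plus the cluster 1 km away
        # reaches 20 >= 15, so h = 1 km
        assert bw.loc[0, "bandwidth_km"] == pytest.approx(1.0, rel=1e-6)
        assert bw.loc[0, "encompassed"] >= 15

    def test_nopt_one_gives_nearest_other_distance(self):
        clusters = _collinear_clusters([0.0, 2.0, 7.0])
        bw = compute_bandwidths(clusters, [5, 5, 5], n_opt=1)
        assert bw["bandwidth_km"].to_numpy() == pytest.approx(
            [2.0, 2.0, 5.0], rel=1e-6)

    @given(st.integers(1, 60))
    def test_doubling_nopt_never_shrinks_bandwidths(self, n_opt):
        clusters = _collinear_clusters([0.0, 1.5, 4.0, 4.5, 9.0])
        sizes = [7, 3, 12, 5, 9]
        h1 = compute_bandwidths(clusters, sizes, n_opt)["bandwidth_km"]
        h2 = compute_bandwidths(clusters, sizes, 2 * n_opt)["bandwidth_km"]
        assert (h2 >= h1 - 1e-12).all()

    def test_total_sample_below_nopt_warns_farthest_rule(self):
        clusters = _collinear_clusters([0.0, 10.0])
        with pytest.warns(UserWarning, match="n_opt"):
            bw = compute_bandwidths(clusters, [3, 3], n_opt=100)
        assert bw.loc[0, "bandwidth_km"] == pytest.approx(10.0, rel=1e-6)

    def test_requires_clusters(self):
        with pytest.raises(ValueError):
            compute_bandwidths(_collinear_clusters([]), [], 10)


class TestDensitySurface:
    def _grid_at(self, lon, lat, cell_km=1.0):
        # one cell whose centre coincides with (lon, lat)
        dlat = cell_km / KM_PER_DEG_LAT
        dlon = cell_km / (KM_PER_DEG_LAT * np.cos(np.radians(lat)))
        return GridSpec(lon - dlon / 2, lat + dlat / 2, cell_km, 1, 1)

    def test_central_ordinate_closed_form(self):
        clusters = _collinear_clusters([0.0])
        h = 3.0
        grid = self._grid_at(30.0, 0.0)
        d = density_surface(clusters, [1.0], [1.0], [h], grid)
        assert d[0, 0] == pytest.approx(1.0 / (2.0 * np.pi * h ** 2),
                                        rel=1e-9)

    def test_linearity_in_weights(self):
        clusters = _collinear_clusters([0.0, 5.0])
        grid = GridSpec.covering(clusters["lon"], clusters["lat"], 2.0,
                                 pad_km=10)
        d1 = density_surface(clusters, [2.0, 3.0], [1.0, 1.0], [4.0, 4.0],
                             grid)
        d2 = density_surface(clusters, [2.0, 3.0], [2.0, 2.0], [4.0, 4.0],
                             grid)
        assert np.allclose(d2, 2.0 * d1)

    def test_translation_invariance_along_parallel(self):
        clusters = _collinear_clusters([0.0, 5.0])
        grid = GridSpec.covering(clusters["lon"], clusters["lat"], 2.0,
                                 pad_km=10)
        d1 = density_surface(clusters, [1.0, 1.0], [1.0, 1.0], [4.0, 4.0],
                             grid)
        shift = 11.5
        moved = clusters.assign(lon=clusters["lon"] + shift)
        grid2 = GridSpec(grid.origin_lon + shift, grid.origin_lat,
                         grid.cell_size_km, grid.n_rows, grid.n_cols)
        d2 = density_surface(moved, [1.0, 1.0], [1.0, 1.0], [4.0, 4.0],
                             grid2)
        assert np.allclose(d1, d2)

    def test_zero_bandwidth_rejected(self):
        clusters = _collinear_clusters([0.0])
        grid = self._grid_at(30.0, 0.0)
        with pytest.raises(ValueError, match="positive"):
            density_surface(clusters, [1.0], [1.0], [0.0], grid)


class TestPrevalenceSurface:
    def _setup(self, fracs, sizes=None, h_km=15.0, cell_km=2.0):
        clusters = _collinear_clusters(
            [10.0 * k for k in range(len(fracs))])
        n = np.asarray(sizes if sizes is not None else [20.0] * len(fracs),
                       dtype=float)
        y = np.asarray(fracs) * n
        w = np.ones(len(fracs))
        h = np.full(len(fracs), h_km)
        grid = GridSpec.covering(clusters["lon"], clusters["lat"], cell_km,
                                 pad_km=20)
        case = density_surface(clusters, y, w, h, grid)
        control = density_surface(clusters, n, w, h, grid)
        return case, control, grid

    def test_constant_field_exactness(self):
        case, control, grid = self._setup([0.37, 0.37, 0.37],
                                          sizes=[10, 25, 40])
        surf = prevalence_surface(case, control, grid, support_floor=1e-12)
        assert np.allclose(surf.values[surf.mask], 0.37, atol=1e-13)

    def test_zero_cases_give_zero_surface(self):
        case, control, grid = self._setup([0.0, 0.0])
        surf = prevalence_surface(case, control, grid, support_floor=1e-12)
        assert np.all(surf.values[surf.mask] == 0.0)

    def test_values_within_cluster_prevalence_range(self):
        fracs = [0.1, 0.8, 0.4]
        case, control, grid = self._setup(fracs)
        surf = prevalence_surface(case, control, grid, support_floor=1e-12)
        vals = surf.values[surf.mask]
        assert vals.min() >= min(fracs) - 1e-12
        assert vals.max() <= max(fracs) + 1e-12

    def test_monotone_transect_between_opposite_clusters(self):
        fracs = [0.0, 1.0]
        case, control, grid = self._setup(fracs, cell_km=1.0)
        surf = prevalence_surface(case, control, grid, support_floor=1e-12)
        # row through the clusters (they sit on the equator)
        lon_g, lat_g = grid.cell_centers()
        row = np.argmin(np.abs(lat_g[:, 0]))
        transect = surf.values[row]
        interior = transect[1:-1]
        assert np.all(interior > 0.0) and np.all(interior < 1.0)
        assert np.all(np.diff(transect) >= -1e-12)

    def test_grid_mismatch_rejected(self):
        case, control, grid = self._setup([0.5, 0.5])
        with pytest.raises(GridMismatchError):
            prevalence_surface(case[:, :-1], control, grid, 1e-12)


def test_support_mask_excludes_far_cells():
    clusters = _collinear_clusters([0.0])
    grid = GridSpec.covering([30.0], [0.0], 2.0, pad_km=200)
    control = density_surface(clusters, [20.0], [1.0], [5.0], grid)
    case = density_surface(clusters, [10.0], [1.0], [5.0], grid)
    floor = 20.0 * default_support_floor([5.0])
    surf = prevalence_surface(case, control, grid, floor)
    assert surf.mask.any() and not surf.mask.all()
    assert np.isnan(surf.values[~surf.mask]).all()


def test_end_to_end_band_surface(small_survey, tmp_path):
    _, ds, _ = small_survey
    surf, bw, grid = band_prevalence_surface(ds, "LT16", cell_size_km=10.0)
    assert (bw["bandwidth_km"] > 0).all()
    vals = surf.values[surf.mask]
    assert np.all((vals >= 0) & (vals <= 1))

    asc = tmp_path / "s.asc"
    write_ascii_grid(surf, asc)
    header = asc.read_text().splitlines()[:6]
    assert header[0].split() == ["ncols", str(grid.n_cols)]
    data = np.loadtxt(asc, skiprows=6)
    data = np.atleast_2d(data)
    recovered = np.where(data == -9999.0, np.nan, data)
    assert np.allclose(recovered[surf.mask], surf.values[surf.mask],
                       rtol=1e-6)

    csv = surface_to_csv(surf, tmp_path / "s.csv")
    assert len(csv) == int(surf.mask.sum())
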