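"""Generator: admin lattice, ICAR/i.i.d. effect fields, survey simulation,
GPS displacement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from prevmap import (SyntheticConfig, displace_cluster, make_admin_grid,
                     simulate_bym_effects, simulate_survey)
from prevmap.adjacency import AdjacencyGraph, build_adjacency, grid_adjacency
from prevmap.geometry import haversine_km, lonlat_to_km_frame
from prevmap.synthetic import ConfigError, district_probabilities


def _planar_area_km2(polygon, lon0, lat0):
    """Independent shoelace area in the local km frame."""
    lon, lat = zip(*polygon.exterior.coords)
    x, y = lonlat_to_km_frame(np.array(lon), np.array(lat), lon0, lat0)
    return 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


class TestAdminGrid:
    def test_single_region_2x2_block(self):
        units = make_admin_grid(1, 4, 50, (30.0, 0.0))
        regions = [u for u in units if u.level == 1]
        districts = [u for u in units if u.level == 2]
        assert len(regions) == 1 and len(districts) == 4
        assert all(d.parent_id == regions[0].unit_id for d in districts)
        # 2x2 block: all four districts mutually queen-contiguous
        g = build_adjacency(districts)
        assert all(len(g.neighbors[d.unit_id]) == 3 for d in districts)

    def test_region_membership_partitions_districts(self):
        units = make_admin_grid(2, 2, 50, (30.0, 0.0))
        districts = [u for u in units if u.level == 2]
        region_ids = {u.unit_id for u in units if u.level == 1}
        assert len(districts) == 4
        parents = [d.parent_id for d in districts]
        assert set(parents) == region_ids
        assert all(parents.count(r) == 2 for r in region_ids)

    def test_total_area_matches_planar_oracle(self):
        origin = (30.0, 0.0)
        units = make_admin_grid(3, 9, 25, origin)
        districts = [u for u in units if u.level == 2]
        assert len(districts) == 27
        total = sum(_planar_area_km2(d.geometry, *origin) for d in districts)
        assert total == pytest.approx(27 * 25 ** 2, rel=1e-9)

    def test_no_gaps_no_overlaps(self):
        from shapely.ops import unary_union

        units = make_admin_grid(2, 6, 40, (31.0, -2.0))
        districts = [u for u in units if u.level == 2]
        union = unary_union([d.geometry for d in districts])
        assert union.area == pytest.approx(
            sum(d.geometry.area for d in districts), rel=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigError):
            make_admin_grid(0, 4, 50)
        with pytest.raises(ConfigError):
            make_admin_grid(2, 2, -1)


class TestBymEffects:
    def test_zero_variance_gives_zero_fields(self, grid6):
        u, v = simulate_bym_effects(grid6, 0.0, 0.0, 1)
        assert np.all(u == 0) and np.all(v == 0)

    def test_sum_to_zero_constraint(self, grid6):
        u, _ = simulate_bym_effects(grid6, 1.3, 0.2, 7)
        assert abs(u.sum()) < 1e-10

    def test_empirical_covariance_matches_laplacian_pseudoinverse(self):
        import networkx as nx

        g = grid_adjacency(np.arange(9).reshape(3, 3))
        draws = np.array([simulate_bym_effects(g, 1.0, 0.0, 1000 + k)[0]
                          for k in range(10_000)])
        emp = np.cov(draws.T)
        q = nx.laplacian_matrix(g.to_networkx(), nodelist=g.ids).toarray()
        expected = np.linalg.pinv(q)
        assert np.allclose(emp, expected, atol=0.05)

    def test_disconnected_graph_rejected(self):
        g = AdjacencyGraph(ids=["a", "b", "c"],
                           neighbors={"a": {"b"}, "b": {"a"}, "c": set()},
                           islands={"c"})
        with pytest.raises(ValueError, match="disconnected"):
            simulate_bym_effects(g, 1.0, 1.0, 0)


class TestDisplacement:
    @pytest.mark.parametrize("urban,limit", [(True, 2.0), (False, 5.0)])
    def test_bounds_and_mean(self, urban, limit):
        rng = np.random.default_rng(99)
        lon0, lat0 = 33.0, -1.5
        d = np.array([
            haversine_km(lon0, lat0, *displace_cluster((lon0, lat0), urban,
                                                       rng))
            for _ in range(4000)])
        assert np.all(d <= limit + 1e-3)  # +1 m flat-earth slack
        # mean of Uniform(0, limit) = limit / 2; 4-sigma Monte-Carlo band
        se = (limit / np.sqrt(12.0)) / np.sqrt(len(d))
        assert abs(d.mean() - limit / 2.0) < 4 * se


class TestSimulateSurvey:
    def test_degenerate_logits_yield_all_baseline(self):
        cfg = SyntheticConfig(n_regions=1, districts_per_region=4,
                              clusters_per_district_mean=3,
                              cluster_size_mean=5,
                              beta0=(-40.0, -40.0, -40.0), seed=3)
        ds, _ = simulate_survey(cfg)
        assert (ds.respondents["first_birth_band"] == "NONE_BEFORE_20").all()

    def test_pooled_prevalence_converges_without_random_effects(self):
        # beta0 chosen so the <16 band probability is exactly 0.10
        target = np.array([0.10, 0.20, 0.15, 0.55])
        beta0 = tuple(np.log(target[:3] / target[3]))
        cfg = SyntheticConfig(n_regions=2, districts_per_region=2,
                              clusters_per_district_mean=25,
                              cluster_size_mean=100, sigma_u=0.0,
                              sigma_v=0.0, beta0=beta0, seed=17)
        ds, truth = simulate_survey(cfg)
        assert np.allclose(truth[["p_lt16", "p_16_17", "p_18_19", "p_none"]],
                           target)
        n = len(ds.respondents)
        assert n > 5000
        share = (ds.respondents["first_birth_band"] == "LT16").mean()
        assert abs(share - 0.10) < 4 * np.sqrt(0.1 * 0.9 / n)

    def test_same_seed_reproduces_identical_tables(self):
        cfg = SyntheticConfig(n_regions=2, districts_per_region=2,
                              clusters_per_district_mean=4,
                              cluster_size_mean=6, seed=123)
        ds1, t1 = simulate_survey(cfg)
        ds2, t2 = simulate_survey(cfg)
        pd.testing.assert_frame_equal(ds1.respondents, ds2.respondents)
        pd.testing.assert_frame_equal(ds1.clusters, ds2.clusters)
        pd.testing.assert_frame_equal(t1, t2)

    def test_referential_integrity(self, small_survey):
        _, ds, _ = small_survey
        assert set(ds.respondents["cluster_id"]) <= set(ds.clusters["cluster_id"])
        district_ids = {u.unit_id for u in ds.districts}
        assert set(ds.clusters["district_id"]) <= district_ids

    def test_weights_positive_mean_one(self, small_survey):
        _, ds, _ = small_survey
        w = ds.respondents["weight"]
        assert (w > 0).all()
        assert w.mean() == pytest.approx(1.0)

    def test_truth_probabilities_sum_to_one(self, small_survey):
        _, _, truth = small_survey
        sums = truth[["p_lt16", "p_16_17", "p_18_19", "p_none"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_seed_mandatory(self):
        with pytest.raises(ConfigError, match="seed"):
            SyntheticConfig().validate()


@given(st.lists(st.floats(-8, 8), min_size=3, max_size=3),
       st.lists(st.floats(-3, 3), min_size=3, max_size=3))
def test_category_probabilities_valid_for_finite_logits(beta0, effects):
    u = np.array(effects).reshape(3, 1)
    p = district_probabilities(beta0, u, np.zeros((3, 1)))
    assert p.shape == (1, 4)
    assert np.all(p > 0) and np.all(p < 1)
    assert p.sum() == pytest.approx(1.0)
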