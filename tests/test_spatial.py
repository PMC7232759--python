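import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from charr_gsi import (CoastGrid, ScenarioConfig, drainage_regression,
                       generate_baseline, generate_mixture, generate_tagging,
                       least_cost_distance, least_cost_matrix,
                       assignment_geography, tagging_analysis)
from charr_gsi.gsi import assign
from charr_gsi.popgen import allele_counts
from charr_gsi.spatial import GridConnectivityError
from charr_gsi.types import MovementSummary

from oracles import bellman_ford_grid, enumerate_paths_shortest


def flat_grid(rows, cols, cell_km=1.0, lat0=60.0, lon0=-60.0):
    return CoastGrid(np.ones((rows, cols), dtype=bool), cell_km, lat0, lon0)


def sites_at(grid, cells, ids=None, role="river", area=None):
    rows = []
    for k, (r, c) in enumerate(cells):
        lat, lon = grid.rowcol_to_latlon(r, c)
        rows.append({"site_id": ids[k] if ids else f"s{k}", "latitude": lat,
                     "longitude": lon,
                     "drainage_area": area[k] if area else np.nan,
                     "role": role})
    return pd.DataFrame(rows)


class TestLeastCost:
    def test_straight_line_open_water(self):
        grid = flat_grid(3, 8, cell_km=10.0)
        s = sites_at(grid, [(1, 1), (1, 6)])
        res = least_cost_distance(grid, s.iloc[0], s.iloc[1])
        assert res.distance_km == pytest.approx(50.0)

    def test_same_site_zero(self):
        grid = flat_grid(3, 3)
        s = sites_at(grid, [(1, 1)])
        assert least_cost_distance(grid, s.iloc[0], s.iloc[0]).distance_km == 0.0

    def test_wall_forces_detour_matches_enumeration(self):
        sea = np.ones((5, 5), dtype=bool)
        sea[0:4, 2] = False          # wall with a gap at the bottom
        grid = CoastGrid(sea, 1.0, 60.0, -60.0)
        s = sites_at(grid, [(0, 0), (0, 4)])
        res = least_cost_distance(grid, s.iloc[0], s.iloc[1])
        expected = enumerate_paths_shortest(sea, 1.0, (0, 0), (0, 4))
        assert res.distance_km == pytest.approx(expected)
        assert res.distance_km > 4.0   # longer than the blocked straight line

    def test_disconnected_components_error(self):
        sea = np.ones((3, 5), dtype=bool)
        sea[:, 2] = False
        grid = CoastGrid(sea, 1.0, 60.0, -60.0)
        s = sites_at(grid, [(1, 0), (1, 4)])
        with pytest.raises(GridConnectivityError):
            least_cost_distance(grid, s.iloc[0], s.iloc[1])

    @given(st.integers(0, 300))
    def test_matches_relaxation_oracle_on_small_grids(self, seed):
        """Dijkstra agrees with Bellman-Ford relaxation on random grids."""
        rng = np.random.default_rng(seed)
        rows, cols = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        sea = rng.random((rows, cols)) > 0.3
        if not sea.any():
            sea[0, 0] = True
        grid = CoastGrid(sea, 1.0, 60.0, -60.0)
        cells = np.argwhere(sea)
        src = tuple(cells[rng.integers(len(cells))])
        ref = bellman_ford_grid(sea, 1.0, src)
        from charr_gsi.spatial import _sea_graph
        from scipy.sparse.csgraph import dijkstra
        graph, index = _sea_graph(grid)
        d = dijkstra(graph, directed=False, indices=int(index[src]))
        for r, c in cells:
            assert d[index[r, c]] == pytest.approx(ref[r, c], abs=1e-9) or \
                (np.isinf(d[index[r, c]]) and np.isinf(ref[r, c]))

    def test_triangle_inequality(self):
        grid = generate_baseline(ScenarioConfig(seed=2, n_loci_msat=5,
                                                inds_per_collection=5))[2]["grid"]
        cfg = ScenarioConfig(seed=2, n_loci_msat=5, inds_per_collection=5)
        _, sites, _ = generate_baseline(cfg)
        sub = sites.iloc[[0, 10, 25]].reset_index(drop=True)
        d = least_cost_matrix(grid, sub).to_numpy()
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_distance_at_least_straight_line(self):
        grid = flat_grid(6, 6, cell_km=2.0)
        s = sites_at(grid, [(0, 0), (5, 5)])
        res = least_cost_distance(grid, s.iloc[0], s.iloc[1])
        assert res.distance_km >= 5 * 2.0 * np.sqrt(2) - 1e-9


@pytest.fixture(scope="module")
def geo_scenario():
    """Separable baseline + a fishery mixture with known origins."""
    cfg = ScenarioConfig(n_regions=2, pops_per_region=(2, 2), f_region=0.3,
                         f_pop=0.2, n_loci_msat=40, inds_per_collection=30,
                         missing_rate=0.0, seed=31, n_fisheries=2)
    table, sites, truth = generate_baseline(cfg)
    mix, labels = generate_mixture(
        truth, {"P01": 0.5, "P02": 0.5}, 120, seed=3, fishery="F01")
    from charr_gsi.gsi import extend_registry
    counts = extend_registry(allele_counts(table), mix)
    res = assign(counts, mix, table.unit_of())
    return table, sites, truth, mix, labels, res


class TestAssignmentGeography:
    def test_all_origins_nearby_gives_fraction_one(self, geo_scenario):
        _, sites, truth, _, _, res = geo_scenario
        out = assignment_geography(res, sites, truth["grid"],
                                   prob_min=0.8, threshold_km=200.0)
        assert out.pooled_fraction == 1.0

    def test_fraction_matches_truth_label_oracle(self, geo_scenario):
        """Posterior-based fraction equals the direct count from truth."""
        _, sites, truth, _, labels, res = geo_scenario
        grid = truth["grid"]
        out = assignment_geography(res, sites, grid, prob_min=0.8,
                                   threshold_km=60.0)
        dmat = least_cost_matrix(
            grid, sites[sites.site_id.isin(["F01", "P01", "P02"])])
        keep = res.unit_probs.max(axis=1) > 0.8
        # strong divergence: MAP calls equal truth for confident individuals
        assert (res.map_unit[keep] == labels[keep]).all()
        near = np.array([dmat.loc["F01", u] <= 60.0 for u in labels[keep]])
        assert out.pooled_fraction == pytest.approx(near.mean())

    def test_prob_min_rule_excludes_uncertain_fish(self, geo_scenario):
        _, sites, truth, _, _, res = geo_scenario
        out = assignment_geography(res, sites, truth["grid"], prob_min=0.8)
        assert out.details["n_assigned"] == int(
            (res.unit_probs.max(axis=1) > 0.8).sum())

    def test_missing_site_raises(self, geo_scenario):
        _, sites, truth, _, _, res = geo_scenario
        bad = sites[sites.site_id != "P01"]
        with pytest.raises(ValueError, match="P01"):
            assignment_geography(res, bad, truth["grid"])


class TestDrainageRegression:
    def _summary(self, rows):
        counts = pd.DataFrame(rows, columns=["fishery", "unit", "n"])
        counts["distance_km"] = 0.0
        return MovementSummary(counts, pd.DataFrame())

    def _sites(self, units, areas):
        return pd.DataFrame({
            "site_id": units, "latitude": 60.0, "longitude": -60.0,
            "drainage_area": areas, "role": "river"})

    def test_proportions_proportional_to_area_r2_one(self):
        s = self._summary([("F1", "A", 10), ("F1", "B", 20), ("F1", "C", 70)])
        fit = drainage_regression(s, self._sites(["A", "B", "C"],
                                                 [100.0, 200.0, 700.0]))
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope > 0

    def test_two_contributor_fisheries_excluded(self):
        rows = [("F1", "A", 10), ("F1", "B", 20),   # only two contributors
                ("F2", "A", 10), ("F2", "B", 20), ("F2", "C", 70)]
        s = self._summary(rows)
        fit = drainage_regression(s, self._sites(["A", "B", "C"],
                                                 [1.0, 2.0, 7.0]))
        assert fit.n == 3      # only F2's three points enter

    def test_refuses_fewer_than_three_points(self):
        s = self._summary([("F1", "A", 10), ("F1", "B", 20)])
        with pytest.raises(ValueError):
            drainage_regression(s, self._sites(["A", "B"], [1.0, 2.0]))

    def test_independent_proportions_usually_not_significant(self):
        """Permuted areas should rarely reach p < 0.05."""
        rng = np.random.default_rng(4)
        units = [f"U{i}" for i in range(50)]
        areas = rng.lognormal(3, 1, size=50)
        rejections = 0
        for rep in range(20):
            props = rng.dirichlet(np.ones(50))
            rows = [("F1", u, p) for u, p in zip(units, props)]
            fit = drainage_regression(self._summary(rows),
                                      self._sites(units, list(areas)))
            rejections += fit.p_value < 0.05
        assert rejections <= 2


class TestTagging:
    @pytest.fixture(scope="class")
    def grid_sites(self):
        grid = flat_grid(40, 10, cell_km=5.0)
        cells = [(5, 1), (15, 1), (30, 1)]
        sites = sites_at(grid, cells, ids=["S1", "S2", "S3"])
        return grid, sites

    def test_all_recaptures_at_home_is_100pct(self, grid_sites):
        grid, sites = grid_sites
        tags = pd.DataFrame({
            "tag_id": [f"t{i}" for i in range(6)],
            "stock": ["S1", "S1", "S1", "S2", "S2", "S2"],
            "tag_site": ["S1"] * 3 + ["S2"] * 3,
            "recapture_site": ["S1"] * 3 + ["S2"] * 3,
            "recaptured": [True] * 6})
        region = {"S1": "north", "S2": "mid", "S3": "south"}
        out = tagging_analysis(tags, sites, grid, region)
        assert (out.per_group["pct_within_region"] == 100.0).all()
        assert (out.details["distances_km"] == 0.0).all()

    def test_mean_within_region_arithmetic(self, grid_sites):
        grid, sites = grid_sites
        # stock S1: 7/15 home; stock S2: 4/4 home -> mean of 46.67 and 100
        rows = []
        for i in range(15):
            rows.append({"tag_id": f"a{i}", "stock": "S1", "tag_site": "S1",
                         "recapture_site": "S1" if i < 7 else "S3",
                         "recaptured": True})
        for i in range(4):
            rows.append({"tag_id": f"b{i}", "stock": "S2", "tag_site": "S2",
                         "recapture_site": "S2", "recaptured": True})
        region = {"S1": "north", "S2": "mid", "S3": "south"}
        out = tagging_analysis(pd.DataFrame(rows), sites, grid, region)
        assert out.details["mean_pct_within_region"] == pytest.approx(
            (46.666666 + 100.0) / 2, abs=1e-3)

    def test_kernel_tags_show_negative_slope_and_mean_distance(self):
        """Generator-truth recovery: decay kernel -> negative distance slope."""
        grid = flat_grid(60, 8, cell_km=5.0)
        cells = [(i * 6 + 3, 1) for i in range(9)]
        ids = [f"S{i}" for i in range(9)]
        sites = sites_at(grid, cells, ids=ids)
        effort = {s: 1.0 for s in ids}
        tags = generate_tagging(sites, grid, {"S4": 3000}, 60.0, effort,
                                recapture_rate=0.8, seed=5)
        region = {s: s for s in ids}
        out = tagging_analysis(tags, sites, grid, region)
        assert out.regression.slope < 0
        d = np.array([least_cost_matrix(grid, sites).loc["S4", s] for s in ids])
        w = np.exp(-d / 60.0)
        expected_mean = (d * w).sum() / w.sum()
        got = out.details["distances_km"].mean()
        assert abs(got - expected_mean) / expected_mean < 0.1

    def test_unknown_site_records_skipped_with_warning(self, grid_sites):
        grid, sites = grid_sites
        tags = pd.DataFrame({
            "tag_id": ["t1", "t2"], "stock": ["S1", "S1"],
            "tag_site": ["S1", "XX"], "recapture_site": ["S1", "S1"],
            "recaptured": [True, True]})
        with pytest.warns(UserWarning, match="skipped"):
            out = tagging_analysis(tags, sites, grid, {"S1": "n"})
        assert out.details["n_recaptures"] == 1
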