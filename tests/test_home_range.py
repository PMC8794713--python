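import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from conftest import (
    half_plane_landscape,
    nest_row,
    points_frame,
    single_patch_landscape,
)
from larkscape.home_range import (
    build_home_range,
    composition_table,
    estimate_radius,
    habitat_use,
    weighted_percentile,
    weighted_surface_area,
)
from larkscape.io import Landscape
from larkscape.types import HabitatPatch


def brute_force_weighted_percentile(values, weights, q):
    """Independent oracle: walk the sorted sample accumulating weight."""
    order = np.argsort(values)
    total = np.sum(weights)
    acc = 0.0
    for i in order:
        acc += weights[i]
        if acc / total >= q - 1e-12:
            return values[i]
    return values[order[-1]]


class TestWeightedPercentile:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.uniform(0, 100, rng.integers(3, 40))
            w = rng.uniform(0.1, 3.0, v.size)
            q = rng.uniform(0.05, 1.0)
            assert weighted_percentile(v, w, q) == brute_force_weighted_percentile(
                v, w, q
            )

    def test_single_nest_percentile(self):
        d = np.arange(1.0, 101.0)
        assert weighted_percentile(d, np.ones(100), 0.95) == 95.0

    def test_all_equal_distances(self):
        d = np.full(7, 42.0)
        for q in (0.05, 0.5, 0.95, 1.0):
            assert weighted_percentile(d, np.ones(7), q) == 42.0

    def test_invalid_percentile(self):
        with pytest.raises(ValueError):
            weighted_percentile(np.arange(5.0), np.ones(5), 0.0)


class TestEstimateRadius:
    def _nests_points(self):
        nests = pd.DataFrame([nest_row("a", 0, 0), nest_row("b", 1000, 0)])
        pa = points_frame("a", np.arange(1.0, 101.0), np.zeros(100), session_id="sa")
        pb = points_frame("b", 1000 + np.arange(1.0, 11.0), np.zeros(10), session_id="sb")
        pb["point_id"] = [f"q{i}" for i in range(10)]
        return nests, pd.concat([pa, pb], ignore_index=True)

    def test_nest_weighting_balances_unequal_effort(self):
        nests, pts = self._nests_points()
        r = estimate_radius(nests, pts, 0.95)
        # each nest holds half the weight; oracle via explicit weights
        d = np.concatenate([np.arange(1.0, 101.0), np.arange(1.0, 11.0)])
        w = np.concatenate([np.full(100, 1 / 100), np.full(10, 1 / 10)])
        assert r == brute_force_weighted_percentile(d, w, 0.95)

    def test_invariant_to_duplicating_a_nest(self):
        nests, pts = self._nests_points()
        r1 = estimate_radius(nests, pts, 0.95)
        dup = pts[pts["nest_id"] == "a"].copy()
        dup["point_id"] = dup["point_id"] + "_dup"
        r2 = estimate_radius(nests, pd.concat([pts, dup], ignore_index=True), 0.95)
        assert r1 == r2

    def test_no_points_errors(self):
        nests = pd.DataFrame([nest_row("a")])
        with pytest.raises(ValueError):
            estimate_radius(nests, points_frame("a", [], []), 0.95)


class TestBuildHomeRange:
    def test_disc_area_in_single_field(self):
        hr = build_home_range(nest_row(), single_patch_landscape(), 188.0)
        disc_area = np.pi * 188.0**2
        assert len(hr.patches) == 1
        assert hr.patches[0][2].area == pytest.approx(disc_area, rel=1e-3)
        assert hr.coverage_gap_m2 < 1e-3 * disc_area

    def test_disc_area_at_188m_is_11_10_ha(self):
        hr = build_home_range(nest_row(), single_patch_landscape(), 188.0)
        area_ha = sum(g.area for _, _, g in hr.patches) / 1e4
        assert round(area_ha, 1) == 11.1

    def test_boundary_nest_splits_half_and_half(self):
        hr = build_home_range(nest_row(x=0.0), half_plane_landscape(0.0), 188.0)
        shares = hr.area_shares_pct()
        assert shares["winter_wheat"] == pytest.approx(50.0, abs=0.5)
        assert shares["sugar_beet"] == pytest.approx(50.0, abs=0.5)

    def test_coverage_gap_recorded(self):
        # landscape covers only the eastern half of the disc
        ls = Landscape([HabitatPatch("e", "corn", 2018, box(0, -500, 500, 500))])
        hr = build_home_range(nest_row(x=0.0), ls, 100.0)
        assert hr.coverage_gap_m2 == pytest.approx(np.pi * 100**2 / 2, rel=0.01)

    def test_nonpositive_radius(self):
        with pytest.raises(ValueError):
            build_home_range(nest_row(), single_patch_landscape(), 0.0)


class TestWeightedSurfaceArea:
    def test_flat_weighting_equals_area_share(self):
        hr = build_home_range(nest_row(x=0.0), half_plane_landscape(0.0), 188.0)
        shares = weighted_surface_area(hr, weighting="flat", grid_m=5.0)
        assert shares["winter_wheat"] == pytest.approx(50.0, abs=0.5)
        assert shares["sugar_beet"] == pytest.approx(50.0, abs=0.5)

    def test_flat_weighting_matches_exact_polygon_areas(self):
        # oracle: exact clipped-polygon areas from shapely
        ls = half_plane_landscape(60.0)
        hr = build_home_range(nest_row(x=0.0), ls, 188.0)
        shares = weighted_surface_area(hr, weighting="flat", grid_m=5.0)
        exact = hr.area_shares_pct()
        for hab in exact:
            assert shares[hab] == pytest.approx(exact[hab], abs=0.5)

    def test_single_habitat_is_100(self):
        hr = build_home_range(nest_row(), single_patch_landscape(), 188.0)
        for weighting, kw in (
            ("flat", {}),
            (
                "distance",
                {
                    "distances": np.linspace(5, 180, 100),
                    "dist_weights": np.ones(100),
                },
            ),
        ):
            shares = weighted_surface_area(hr, weighting=weighting, grid_m=5.0, **kw)
            assert shares == {"winter_wheat": pytest.approx(100.0)}

    def test_step_kernel_concentrated_inside_half_radius(self):
        # all flight distances below 94 m -> the annulus beyond gets weight 0
        ls = Landscape(
            [
                HabitatPatch(
                    "inner", "annual_flower_strip", 2018, Point(0, 0).buffer(94.0, 128)
                ),
                HabitatPatch(
                    "ring",
                    "winter_wheat",
                    2018,
                    Point(0, 0).buffer(400.0, 128).difference(Point(0, 0).buffer(94.0, 128)),
                ),
            ]
        )
        hr = build_home_range(nest_row(), ls, 188.0)
        d = np.random.default_rng(0).uniform(5, 90, 200)
        shares = weighted_surface_area(
            hr, distances=d, dist_weights=np.ones(200), grid_m=5.0
        )
        assert shares.get("annual_flower_strip", 0.0) == pytest.approx(100.0, abs=0.5)
        assert shares.get("winter_wheat", 0.0) == pytest.approx(0.0, abs=0.5)

    def test_grid_too_coarse_rejected(self):
        hr = build_home_range(nest_row(), single_patch_landscape(), 188.0)
        with pytest.raises(ValueError, match="grid"):
            weighted_surface_area(hr, weighting="flat", grid_m=50.0)

    def test_distance_weighting_needs_enough_pooled_points(self):
        hr = build_home_range(nest_row(), single_patch_landscape(), 188.0)
        with pytest.raises(ValueError, match="50"):
            weighted_surface_area(
                hr, distances=np.array([10.0]), dist_weights=np.array([1.0]), grid_m=5.0
            )


class TestHabitatUse:
    def test_simple_shares(self):
        hr = build_home_range(nest_row(x=0.0), half_plane_landscape(0.0), 188.0)
        xs = [-50] * 5 + [50] * 5
        used, info = habitat_use(
            hr, points_frame("n0", xs, np.zeros(10)), half_plane_landscape(0.0)
        )
        assert used["winter_wheat"] == 50.0 and used["sugar_beet"] == 50.0
        assert info["n_out_of_range"] == 0

    def test_all_points_beyond_radius_flagged(self):
        hr = build_home_range(nest_row(), single_patch_landscape(), 100.0)
        used, info = habitat_use(
            hr, points_frame("n0", [500, 600], [0, 0]), single_patch_landscape()
        )
        assert used == {} and info.get("empty") and info["n_out_of_range"] == 2

    def test_point_exactly_on_radius_included(self):
        hr = build_home_range(nest_row(), single_patch_landscape(), 100.0)
        used, info = habitat_use(
            hr, points_frame("n0", [100.0], [0.0]), single_patch_landscape()
        )
        assert used == {"winter_wheat": 100.0}
        assert info["n_out_of_range"] == 0


def test_availability_sums_to_100_per_nest(small_dataset):
    comp = composition_table(
        small_dataset.nests.head(4),
        small_dataset.landing_points[small_dataset.landing_points["safe"]],
        small_dataset.landscape,
        150.0,
    )
    sums = comp.groupby("nest_id")["available_pct"].sum()
    assert np.allclose(sums, 100.0, atol=1e-6)
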