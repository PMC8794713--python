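import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import nest_row, single_patch_landscape, small_truth
from larkscape import pipeline
from larkscape.home_range import build_home_range
from larkscape.rsf import (
    RSF_PREDICTORS,
    assign_weights,
    build_rsf_points,
    classify_selection,
    fit_penalized_logit,
    fit_rsf,
    generate_pseudo_absences,
    permutation_importance,
)
from larkscape.synth import HabitatDynamics, generate_dataset


@pytest.fixture(scope="module")
def wheat_disc():
    return build_home_range(nest_row(), single_patch_landscape(), 188.0)


class TestPseudoAbsences:
    def test_count_and_columns(self, wheat_disc):
        pts = generate_pseudo_absences(wheat_disc, 240, 0)
        assert len(pts) == 240
        assert (pts["kind"] == "pseudo_absence").all()
        assert (pts["distance_m"] <= 188.0).all()

    def test_deterministic_under_seed(self, wheat_disc):
        a = generate_pseudo_absences(wheat_disc, 100, 42)
        b = generate_pseudo_absences(wheat_disc, 100, 42)
        pd.testing.assert_frame_equal(a, b)

    def test_uniformity_mean_distance(self, wheat_disc):
        # mean distance of uniform points in a disc is (2/3) r
        pts = generate_pseudo_absences(wheat_disc, 100_000, 7)
        expect = 2.0 / 3.0 * 188.0
        assert abs(pts["distance_m"].mean() - expect) / expect < 0.01

    def test_disallowed_patches_error(self, wheat_disc):
        with pytest.raises(RuntimeError, match="n0"):
            generate_pseudo_absences(wheat_disc, 10, 0, allowed_patch_ids=set())

    def test_study_scale_total(self):
        # 42 home ranges x 240 points each = 10,080
        total = sum(
            len(generate_pseudo_absences(build_home_range(nest_row(f"n{i}"), single_patch_landscape(), 188.0), 240, i))
            for i in range(42)
        )
        assert total == 10_080


class TestWeights:
    def _points(self, n_by_nest):
        frames = []
        for nid, (n_pres, n_abs) in n_by_nest.items():
            frames.append(
                pd.DataFrame(
                    {
                        "nest_id": nid,
                        "kind": ["presence"] * n_pres + ["pseudo_absence"] * n_abs,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_presence_weight_is_one_over_n(self):
        w = assign_weights(self._points({"a": (10, 240)}))
        pres = w[w["kind"] == "presence"]
        assert np.allclose(pres["weight"], 0.1)

    def test_totals_balance_per_nest_and_globally(self):
        w = assign_weights(self._points({"a": (40, 240), "b": (7, 240), "c": (12, 60)}))
        sums = w.groupby(["nest_id", "kind"])["weight"].sum()
        assert np.allclose(sums, 1.0)
        tot = w.groupby("kind")["weight"].sum()
        assert tot["presence"] == pytest.approx(tot["pseudo_absence"])
        assert tot["presence"] == pytest.approx(3.0)

    def test_nest_without_presences_dropped(self):
        with pytest.warns(UserWarning, match="b"):
            w = assign_weights(self._points({"a": (5, 20), "b": (0, 20)}))
        assert set(w["nest_id"]) == {"a"}


class TestPenalizedLogit:
    def _sim(self, n=600, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-1, 1, (n, 1))
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.4 + 1.3 * x[:, 0]))))
        X = np.column_stack([np.ones(n), x])
        w = rng.uniform(0.5, 2.0, n)
        return y, X, w

    def test_zero_penalty_equals_glm(self):
        y, X, w = self._sim()
        ours = fit_penalized_logit(y, X, np.zeros((2, 2)), w)
        glm = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit()
        assert np.allclose(ours.params, glm.params, atol=1e-6)
        assert ours.deviance == pytest.approx(glm.deviance, abs=1e-6)
        assert ours.edf_by_col.sum() == pytest.approx(2.0, abs=1e-6)

    def test_heavy_penalty_shrinks_to_penalty_null_space(self):
        y, X, w = self._sim()
        S = np.zeros((2, 2))
        S[1, 1] = 1e9  # ridge on the slope only
        ours = fit_penalized_logit(y, X, S, w)
        assert abs(ours.params[1]) < 1e-3
        assert ours.edf_by_col[1] < 0.01

    def test_edf_decreases_with_penalty(self):
        y, X, w = self._sim()
        edfs = []
        for a in (0.0, 10.0, 1e4):
            S = np.zeros((2, 2))
            S[1, 1] = a
            edfs.append(fit_penalized_logit(y, X, S, w).edf_by_col.sum())
        assert edfs[0] > edfs[1] > edfs[2]

    def test_penalized_fit_never_beats_null_backwards(self):
        # the penalized optimum can never have a larger deviance than the
        # intercept-only model (which is feasible at zero penalty cost)
        y, X, w = self._sim()
        S = np.zeros((2, 2))
        S[1, 1] = 50.0
        ours = fit_penalized_logit(y, X, S, w)
        null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(), var_weights=w).fit()
        assert ours.deviance <= null.deviance + 1e-8


@pytest.fixture(scope="module")
def fitted_rsf():
    """Distance-driven synthetic study, fitted once for downstream tests."""
    truth = small_truth(
        seed=11,
        n_nests=8,
        n_nests_surveyed=8,
        distance_decay_lambda_m=60.0,
        habitat_weights={},
        default_habitat_weight=HabitatDynamics(1.0),
        mean_observation_days=5.0,
    )
    ds = generate_dataset(truth)
    hr = pipeline.home_range_stage(ds)
    cov = pipeline.covariate_stage(ds, hr)
    nests = ds.nests
    hrs = [hr["home_ranges"][nid] for nid in nests["nest_id"]]
    pts = build_rsf_points(hrs, hr["safe_points"], cov, 60, 3)
    return fit_rsf(pts, k_basis=8, alpha=[1.0, 1.0, 1.0, 1.0])


class TestFitRSF:
    def test_distance_term_dominates(self, fitted_rsf):
        assert fitted_rsf.pvalues["distance"] < 0.001
        assert 0.0 < fitted_rsf.deviance_explained < 1.0

    def test_per_term_edf_positive(self, fitted_rsf):
        for name in ("vegetation_cover", "arthropod_biomass", "insect_diversity", "distance"):
            assert fitted_rsf.edf[name] > 0

    def test_needs_enough_data(self, fitted_rsf):
        with pytest.raises(ValueError):
            fit_rsf(fitted_rsf.data.head(50))


class TestSelectionCurves:
    def test_no_point_both_preferred_and_avoided(self, fitted_rsf):
        for name in ("vegetation_cover", "distance"):
            c = classify_selection(fitted_rsf, name)
            assert not np.any((c.lower > 0) & (c.upper < 0))
            assert set(c.classification) <= {"preferred", "neutral", "avoided"}

    def test_distance_preferred_near_avoided_far(self, fitted_rsf):
        c = classify_selection(fitted_rsf, "distance")
        pref = c.grid[c.classification == "preferred"]
        avd = c.grid[c.classification == "avoided"]
        assert pref.size and avd.size
        assert pref.max() < avd.min()

    def test_unknown_predictor(self, fitted_rsf):
        with pytest.raises(KeyError):
            classify_selection(fitted_rsf, "moon_phase")

    def test_flat_true_effect_mostly_neutral(self, fitted_rsf):
        # covariates played no role in the simulation: their curves should
        # be neutral almost everywhere
        fracs = []
        for name in ("vegetation_cover", "arthropod_biomass", "insect_diversity"):
            c = classify_selection(fitted_rsf, name)
            fracs.append(np.mean(c.classification == "neutral"))
        assert np.mean(fracs) >= 0.9


class TestPermutationImportance:
    def test_percentages_sum_to_100_and_scores_bounded(self, fitted_rsf):
        imp = permutation_importance(fitted_rsf, n_reps=20, seed=0)
        assert imp.relative_pct.sum() == pytest.approx(100.0, abs=0.1)
        raw = imp.raw_scores.to_numpy()
        assert (raw >= 0).all() and (raw <= 2).all()

    def test_distance_most_important(self, fitted_rsf):
        imp = permutation_importance(fitted_rsf, n_reps=20, seed=0)
        assert imp.relative_pct.idxmax() == "distance"

    def test_zeroed_term_scores_zero_and_single_term_gets_all(self, fitted_rsf):
        import copy

        crippled = copy.deepcopy(fitted_rsf)
        for name in crippled.term_names:
            if name != "distance":
                sl = crippled.term_slices[name]
                crippled.fit.params[sl] = 0.0
        imp = permutation_importance(crippled, n_reps=10, seed=1)
        assert imp.relative_pct["distance"] == pytest.approx(100.0, abs=1e-9)
        for name in imp.relative_pct.index:
            if name != "distance":
                assert imp.relative_pct[name] == 0.0
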