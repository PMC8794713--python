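import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from larkscape.compositional import (
    _lambda_signflip,
    composition_matrix,
    compositional_analysis,
    logratio_differences,
    randomization_test,
    ranking_matrix,
    select_categories,
    wilks_lambda,
)


def manova_lambda_oracle(d):
    """Independent one-sample MANOVA Λ straight from its definition."""
    d = np.asarray(d, float)
    n = d.shape[0]
    mean = d.sum(axis=0) / n
    r1 = sum(np.outer(row - mean, row - mean) for row in d)
    r0 = sum(np.outer(row, row) for row in d)
    return np.linalg.det(r1) / np.linalg.det(r0)


def comp_table(avail, used, nest_ids=None):
    """Long composition table from two (nest × habitat) dicts of arrays."""
    habs = list(avail)
    n = len(next(iter(avail.values())))
    nest_ids = nest_ids or [f"n{i}" for i in range(n)]
    rows = []
    for i, nid in enumerate(nest_ids):
        for h in habs:
            rows.append(
                {
                    "nest_id": nid,
                    "habitat": h,
                    "available_pct": avail[h][i],
                    "used_pct": used[h][i],
                }
            )
    return pd.DataFrame(rows)


class TestSelectCategories:
    def _table(self):
        # habitat 'a','b' everywhere; 'c' in 30% of 10 nests; 'd' in 20%
        avail = {
            "a": np.full(10, 40.0),
            "b": np.full(10, 40.0),
            "c": np.array([20.0] * 3 + [0.0] * 7),
            "d": np.array([20.0] * 2 + [0.0] * 8),
        }
        used = {h: v * 0 + 25 for h, v in avail.items()}
        return comp_table(avail, used)

    def test_one_third_threshold(self):
        cats = select_categories(self._table(), 1.0 / 3.0)
        assert cats == ["a", "b", "other"]

    def test_quarter_threshold_admits_more(self):
        cats = select_categories(self._table(), 0.25)
        assert cats == ["a", "b", "c", "other"]

    def test_ubiquitous_only(self):
        cats = select_categories(self._table(), 1.0)
        assert cats == ["a", "b", "other"]


class TestLogratioDifferences:
    def test_use_equal_availability_gives_zeros(self):
        avail = {"a": np.full(4, 50.0), "b": np.full(4, 30.0), "c": np.full(4, 20.0)}
        tbl = comp_table(avail, avail)
        used, av = composition_matrix(tbl, ["a", "b", "c"])
        d = logratio_differences(used, av)
        assert np.allclose(d.to_numpy(), 0.0, atol=1e-12)

    def test_hand_computed_single_nest(self):
        # use (1/2, 1/2) vs avail (1/4, 3/4), ref = second category:
        # d = ln(1) - ln(1/3) = ln 3
        used = pd.DataFrame([[0.5, 0.5]], columns=["a", "b"], index=["n0"])
        avail = pd.DataFrame([[0.25, 0.75]], columns=["a", "b"], index=["n0"])
        d = logratio_differences(used, avail, reference="b")
        assert d.loc["n0", "a"] == pytest.approx(np.log(3.0), abs=1e-10)

    def test_zero_use_replaced_and_finite(self):
        used = pd.DataFrame([[0.0, 1.0]], columns=["a", "b"], index=["n0"])
        avail = pd.DataFrame([[0.3, 0.7]], columns=["a", "b"], index=["n0"])
        d = logratio_differences(used, avail, reference="b", zero_replacement=1e-4)
        assert np.isfinite(d.loc["n0", "a"])
        assert d.loc["n0", "a"] == pytest.approx(np.log(1e-4 / 1.0) - np.log(0.3 / 0.7))

    def test_unavailable_category_mean_substituted(self):
        used = pd.DataFrame(
            [[0.5, 0.2, 0.3], [0.4, 0.0, 0.6]], columns=["a", "b", "c"],
            index=["n0", "n1"],
        )
        avail = pd.DataFrame(
            [[0.5, 0.2, 0.3], [0.6, 0.0, 0.4]], columns=["a", "b", "c"],
            index=["n0", "n1"],
        )
        d = logratio_differences(used, avail, reference="c")
        assert d.loc["n1", "b"] == pytest.approx(d.loc["n0", "b"])


class TestWilksLambda:
    def test_all_zero_differences(self):
        assert wilks_lambda(np.zeros((6, 2))) == 1.0

    def test_sign_symmetric_data(self):
        rng = np.random.default_rng(1)
        half = rng.normal(0, 1, (5, 3))
        d = np.vstack([half, -half])  # mean exactly zero => R1 = R0
        assert wilks_lambda(d) == pytest.approx(1.0, abs=1e-12)

    def test_one_dimensional_closed_form(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.4, 1.0, (9, 1))
        lam = wilks_lambda(d)
        closed = 1.0 - 9 * d.mean() ** 2 / np.sum(d**2)
        assert lam == pytest.approx(closed, abs=1e-12)

    @pytest.mark.parametrize("shape", [(5, 2), (8, 3), (12, 4)])
    def test_matches_manova_oracle(self, shape):
        rng = np.random.default_rng(shape[1])
        d = rng.normal(0.3, 1.0, shape)
        assert wilks_lambda(d) == pytest.approx(manova_lambda_oracle(d), abs=1e-10)

    def test_rank_one_update_identity(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.2, 1.0, (10, 3))
        lam_det = wilks_lambda(d)
        lam_lemma = _lambda_signflip(d, np.ones((1, 10)))[0]
        assert lam_det == pytest.approx(lam_lemma, abs=1e-12)

    def test_scaling_leaves_lambda_unchanged(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.2, 1.0, (10, 3))
        assert wilks_lambda(3.7 * d) <= wilks_lambda(d) + 1e-12

    def test_reference_category_invariance(self):
        rng = np.random.default_rng(7)
        n = 12
        use = rng.dirichlet(np.full(4, 2.0), n)
        av = rng.dirichlet(np.full(4, 2.0), n)
        cats = ["a", "b", "c", "d"]
        used = pd.DataFrame(use, columns=cats)
        avail = pd.DataFrame(av, columns=cats)
        lams = [
            wilks_lambda(logratio_differences(used, avail, reference=ref))
            for ref in cats
        ]
        assert max(lams) - min(lams) < 1e-8

    def test_too_few_nests(self):
        with pytest.raises(ValueError):
            wilks_lambda(np.ones((3, 3)))


class TestRandomization:
    def test_lambda_one_gives_p_one(self):
        res = randomization_test(np.zeros((8, 2)), n_iter=200, seed=0)
        assert res["lambda"] == 1.0 and res["p_value"] == 1.0

    def test_symmetric_data_p_is_one(self):
        rng = np.random.default_rng(1)
        half = rng.normal(0, 1, (4, 2))
        d = np.vstack([half, -half])
        res = randomization_test(d, n_iter=500, seed=0)
        assert res["p_value"] == 1.0

    def test_matches_exhaustive_enumeration(self):
        # n = 8 nests: compare against all 2^8 sign assignments
        rng = np.random.default_rng(3)
        d = rng.normal(0.5, 1.0, (8, 2))
        lam_obs = wilks_lambda(d)
        count = 0
        for signs in itertools.product([-1.0, 1.0], repeat=8):
            if wilks_lambda(np.asarray(signs)[:, None] * d) <= lam_obs + 1e-12:
                count += 1
        p_exact = count / 2**8
        res = randomization_test(d, n_iter=10_000, seed=5)
        assert abs(res["p_value"] - p_exact) <= 0.02

    def test_strong_selection_detected(self):
        rng = np.random.default_rng(4)
        d = rng.normal(1.5, 0.5, (15, 2))  # large consistent departure
        res = randomization_test(d, n_iter=1000, seed=0)
        assert res["p_value"] < 0.01


class TestRankingMatrix:
    def test_matches_pairwise_ttest_oracle(self):
        rng = np.random.default_rng(8)
        n = 6
        used = pd.DataFrame(rng.dirichlet(np.full(3, 2.0), n), columns=list("abc"))
        avail = pd.DataFrame(rng.dirichlet(np.full(3, 2.0), n), columns=list("abc"))
        res = ranking_matrix(used, avail)
        lu, la = np.log(used.to_numpy()), np.log(avail.to_numpy())
        for j, k in itertools.permutations(range(3), 2):
            dvec = (lu[:, j] - lu[:, k]) - (la[:, j] - la[:, k])
            t_or = stats.ttest_1samp(dvec, 0.0)
            assert res.mean_diff.iloc[j, k] == pytest.approx(dvec.mean(), abs=1e-10)
            assert res.t_stat.iloc[j, k] == pytest.approx(t_or.statistic, abs=1e-10)

    def test_dominant_category_gets_top_rank(self):
        n = 5
        used = pd.DataFrame(
            np.tile([0.8, 0.1, 0.1], (n, 1)), columns=list("abc")
        )
        avail = pd.DataFrame(np.tile([1 / 3] * 3, (n, 1)), columns=list("abc"))
        res = ranking_matrix(used, avail)
        assert res.ranks["a"] == 2  # beats both others

    def test_no_departure_all_ranks_zero(self):
        n = 5
        m = pd.DataFrame(np.tile([0.5, 0.3, 0.2], (n, 1)), columns=list("abc"))
        res = ranking_matrix(m, m.copy())
        assert (res.ranks == 0).all()
        assert not res.significant.to_numpy().any()

    def test_needs_three_nests(self):
        m = pd.DataFrame(np.tile([0.5, 0.5], (2, 1)), columns=list("ab"))
        with pytest.raises(ValueError):
            ranking_matrix(m, m.copy())


def test_full_compositional_pipeline_on_random_use():
    # use drawn independently of availability but around it: weak departure
    rng = np.random.default_rng(9)
    n = 20
    avail = {h: rng.uniform(10, 40, n) for h in ("a", "b", "c")}
    used = {h: v * rng.lognormal(0, 0.1, n) for h, v in avail.items()}
    res = compositional_analysis(comp_table(avail, used), threshold_fraction=0.33, seed=1)
    assert 0 < res["lambda"] <= 1
    assert 0 < res["p_value"] <= 1
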