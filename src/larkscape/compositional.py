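"""Compositional analysis of habitat use versus availability.

Per nest, the used and available habitat proportions are compared through
log-ratio differences d_ij = ln(use_ij/use_i,ref) − ln(avail_ij/avail_i,ref)
(Aebischer-style third-order selection). Non-random use is tested with a
one-sample Wilk's Λ = det(R₁)/det(R₀), where R₁ is the SSCP of the
differences about their mean and R₀ about zero; smaller Λ means stronger
departure. The null distribution comes from randomly flipping the sign of
each nest's difference vector (use and availability exchangeable within
nest), with the observed statistic included in the count. Habitats are
ranked by the pairwise matrix of mean log-ratio differences with one-sample
t statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def select_categories(
    composition: pd.DataFrame, threshold_fraction: float = 1.0 / 3.0
) -> list[str]:
    """Habitat categories present in at least a fraction of home ranges.

    Presence means ``available_pct > 0`` for that nest; everything below the
    threshold is pooled as ``other``. Input is the long composition table
    (nest_id, habitat, available_pct, used_pct).
    """
    n_nests = composition["nest_id"].nunique()
    if n_nests == 0:
        raise ValueError("no home ranges")
    present = (
        composition[composition["available_pct"] > 0]
        .groupby("habitat")["nest_id"]
        .nunique()
    )
    frequent = sorted(present[present >= threshold_fraction * n_nests].index)
    cats = [h for h in frequent if not h.startswith("other")]
    # a namespaced habitat frequent enough keeps its own category
    cats += [h for h in frequent if h.startswith("other:")]
    return cats + ["other"]


def composition_matrix(
    composition: pd.DataFrame, categories: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nests × categories use and availability proportion matrices.

    Habitats outside the named categories are pooled into ``other``; rows
    are renormalized to sum to 1.
    """
    named = [c for c in categories if c != "other"]

    def pool(df: pd.DataFrame, col: str) -> pd.DataFrame:
        d = df.copy()
        d["cat"] = np.where(d["habitat"].isin(named), d["habitat"], "other")
        wide = d.pivot_table(index="nest_id", columns="cat", values=col, aggfunc="sum")
        wide = wide.reindex(columns=categories).fillna(0.0)
        totals = wide.sum(axis=1)
        return wide.div(totals.replace(0.0, np.nan), axis=0)

    used = pool(composition, "used_pct")
    avail = pool(composition, "available_pct")
    # a category available to no nest at all (e.g. an empty 'other' pool)
    # carries no information and would break the log-ratio transform
    nonempty = avail.columns[(avail > 0).any(axis=0)]
    return used[nonempty], avail[nonempty]


def logratio_differences(
    used: pd.DataFrame,
    available: pd.DataFrame,
    reference: str | None = None,
    zero_replacement: float = 1e-4,
    drop_incomplete: bool = False,
) -> pd.DataFrame:
    """Nest × (D−1) matrix of use-vs-availability log-ratio differences.

    Zero used proportions are replaced by ``zero_replacement`` (0.01%)
    before transforming. Cells where a category is unavailable to a nest
    are undefined and filled with the column mean over the defined nests
    (mean substitution), or the nest is dropped if ``drop_incomplete``.
    """
    if reference is None:
        # the category available to the most nests anchors the log-ratios,
        # minimizing undefined cells (Λ itself is reference-invariant)
        reference = (available > 0).sum(axis=0).idxmax()
    if reference not in used.columns:
        raise KeyError(f"reference {reference!r} not among categories")
    cats = [c for c in used.columns if c != reference]
    u = used.to_numpy(float)
    a = available.to_numpy(float)
    u = np.where(u <= 0, zero_replacement, u)
    ref_i = list(used.columns).index(reference)
    with np.errstate(divide="ignore", invalid="ignore"):
        lu = np.log(u) - np.log(u[:, [ref_i]])
        la = np.log(a) - np.log(a[:, [ref_i]])
    d = lu - la
    d = np.delete(d, ref_i, axis=1)
    df = pd.DataFrame(d, index=used.index, columns=cats)
    df = df.replace([np.inf, -np.inf], np.nan)
    if drop_incomplete:
        df = df.dropna()
    else:
        df = df.fillna(df.mean())
    if df.isna().any().any():
        raise ValueError("columns with no defined value cannot be mean-substituted")
    return df


def wilks_lambda(differences: pd.DataFrame | np.ndarray) -> float:
    """One-sample Wilk's Λ = det(R₁)/det(R₀) of the difference matrix."""
    d = np.asarray(differences, float)
    n, k = d.shape
    if n < k + 1:
        raise ValueError("need more nests than habitat categories")
    r0 = d.T @ d
    dc = d - d.mean(axis=0)
    r1 = dc.T @ dc
    det0 = np.linalg.det(r0)
    det1 = np.linalg.det(r1)
    if det0 == 0.0:
        if det1 == 0.0 and not d.any():
            return 1.0  # no departure at all
        raise np.linalg.LinAlgError(
            "singular SSCP matrix; consider pooling rare categories"
        )
    return float(det1 / det0)


def _lambda_signflip(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Λ for many sign-flip replicates at once.

    Sign flips leave R₀ unchanged, so by the matrix-determinant lemma
    Λ = det(R₀ − n·m̄m̄ᵀ)/det(R₀) = 1 − n·m̄ᵀR₀⁻¹m̄ with m̄ the flipped mean.
    """
    n = d.shape[0]
    r0 = d.T @ d
    r0_inv = np.linalg.inv(r0)
    means = (signs @ d) / n  # (reps, k)
    return 1.0 - n * np.einsum("rk,kl,rl->r", means, r0_inv, means)


def randomization_test(
    differences: pd.DataFrame | np.ndarray,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Randomization p-value for Wilk's Λ by per-nest sign flipping.

    p = (1 + #{Λ_rand ≤ Λ_obs}) / (1 + n_iter); one-sided, small Λ =
    strong departure from random use.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = np.asarray(differences, float)
    lam_obs = wilks_lambda(d)
    if lam_obs >= 1.0 - 1e-15:  # no departure: every replicate is as extreme
        return {
            "lambda": lam_obs,
            "p_value": 1.0,
            "n_randomizations": int(n_iter),
            "lambda_null": np.ones(n_iter),
        }
    signs = rng.choice([-1.0, 1.0], size=(n_iter, d.shape[0]))
    lam_rand = _lambda_signflip(d, signs)
    p = (1.0 + int(np.sum(lam_rand <= lam_obs + 1e-12))) / (1.0 + n_iter)
    return {
        "lambda": lam_obs,
        "p_value": float(p),
        "n_randomizations": int(n_iter),
        "lambda_null": lam_rand,
    }


@dataclass
class RankingResult:
    mean_diff: pd.DataFrame  # categories × categories mean log-ratio differences
    t_stat: pd.DataFrame
    significant: pd.DataFrame  # |t| beyond two-sided 5% critical value
    ranks: pd.Series  # number of categories each one beats


def ranking_matrix(
    used: pd.DataFrame,
    available: pd.DataFrame,
    zero_replacement: float = 1e-4,
) -> RankingResult:
    """Pairwise habitat comparison matrix with one-sample t statistics.

    Entry (j, k) is the mean over nests of ln(use_j/use_k) −
    ln(avail_j/avail_k); a positive value means j is used more than k
    relative to availability. A category's rank counts how many others it
    beats.
    """
    if len(used) < 3:
        raise ValueError("need at least 3 nests for the ranking matrix")
    cats = list(used.columns)
    u = np.where(used.to_numpy(float) <= 0, zero_replacement, used.to_numpy(float))
    a = available.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lu, la = np.log(u), np.log(a)
    D = len(cats)
    mean = np.full((D, D), 0.0)
    tstat = np.full((D, D), 0.0)
    sig = np.zeros((D, D), bool)
    for j in range(D):
        for k in range(D):
            if j == k:
                continue
            with np.errstate(invalid="ignore"):
                dvec = (lu[:, j] - lu[:, k]) - (la[:, j] - la[:, k])
            dvec = dvec[np.isfinite(dvec)]
            if dvec.size < 2:
                continue
            mean[j, k] = dvec.mean()
            sd = dvec.std(ddof=1)
            if sd > 0:
                tstat[j, k] = mean[j, k] / (sd / np.sqrt(dvec.size))
                crit = stats.t.ppf(0.975, dvec.size - 1)
                sig[j, k] = abs(tstat[j, k]) > crit
    ranks = pd.Series((mean > 0).sum(axis=1), index=cats)
    return RankingResult(
        mean_diff=pd.DataFrame(mean, index=cats, columns=cats),
        t_stat=pd.DataFrame(tstat, index=cats, columns=cats),
        significant=pd.DataFrame(sig, index=cats, columns=cats),
        ranks=ranks,
    )


def compositional_analysis(
    composition: pd.DataFrame,
    threshold_fraction: float = 1.0 / 3.0,
    n_iter: int = 1000,
    seed: int = 0,
    zero_replacement: float = 1e-4,
) -> dict:
    """Full pipeline: categories → matrices → Λ, p, ranking."""
    cats = select_categories(composition, threshold_fraction)
    used, avail = composition_matrix(composition, cats)
    d = logratio_differences(used, avail, zero_replacement=zero_replacement)
    test = randomization_test(d, n_iter=n_iter, seed=seed)
    ranking = ranking_matrix(used, avail, zero_replacement)
    return {
        "categories": cats,
        "lambda": test["lambda"],
        "p_value": test["p_value"],
        "n_randomizations": n_iter,
        "ranking": ranking,
        "used": used,
        "available": avail,
    }
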