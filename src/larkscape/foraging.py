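"""Foraging parameters and their seasonal trend models.

Three session/point/nest-level descriptors of provisioning effort:

* feeding frequency — landing points per observation session divided by
  session length, per hour and per hour-and-chick (sessions spanning
  sunset and nests with unclear brood size are excluded);
* flight distance — Euclidean nest-to-landing-point distance of every safe
  point (no home-range truncation);
* MCP95 — area of the convex hull of the 95% of a nest's points closest to
  their centroid, for nests with at least 20 points.

Trends over the breeding season are modeled with linear mixed models
(random nest intercept, equal nest weighting) for the two frequencies and
the distance, and an ordinary linear model for the MCP95 area.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from shapely.geometry import MultiPoint

from .glmm import MixedFitResult, fit_linear_mixed
from .home_range import weighted_percentile
from .io import day_of_season
from .types import StudyConfig


def feeding_frequencies(
    sessions: pd.DataFrame,
    landing_points: pd.DataFrame,
    unclear_brood_nests: set[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-session feeding frequencies with the exclusion log.

    All recorded landing points of a session count as feedings (ambiguous
    landing *locations* still were nest visits). Sessions that did not end
    before sunset are dropped; nests with unclear brood size are dropped
    entirely.
    """
    if (sessions["duration_min"] <= 0).any():
        raise ValueError("non-positive session duration")
    unclear = unclear_brood_nests or set()
    n_points = landing_points.groupby("session_id").size()
    log = {
        "n_sessions_total": len(sessions),
        "n_excluded_sunset": int((~sessions["ended_before_sunset"].astype(bool)).sum()),
        "n_excluded_unclear_brood": int(sessions["nest_id"].isin(unclear).sum()),
    }
    keep = sessions[
        sessions["ended_before_sunset"].astype(bool)
        & ~sessions["nest_id"].isin(unclear)
    ].copy()
    keep["n_landings"] = keep["session_id"].map(n_points).fillna(0).astype(int)
    keep["feeding_frequency_per_h"] = keep["n_landings"] / keep["duration_min"] * 60.0
    keep["feeding_frequency_per_h_chick"] = (
        keep["feeding_frequency_per_h"] / keep["brood_size"]
    )
    log["n_sessions_kept"] = len(keep)
    return keep, log


def flight_distances(nests: pd.DataFrame, landing_points: pd.DataFrame) -> pd.DataFrame:
    """Nest-to-point distance for every safe landing point (all of them)."""
    pts = landing_points[landing_points["safe"].astype(bool)]
    merged = pts.merge(
        nests[["nest_id", "x", "y"]].rename(columns={"x": "nx", "y": "ny"}),
        on="nest_id",
        validate="many_to_one",
    )
    merged["distance_m"] = np.hypot(merged["x"] - merged["nx"], merged["y"] - merged["ny"])
    return merged[["point_id", "session_id", "nest_id", "distance_m"]]


@dataclass
class MCPResult:
    nest_id: str
    area_ha: float | None
    n_points: int
    n_retained: int
    excluded_reason: str | None = None
    hull: object | None = None


def mcp95(
    points_xy: np.ndarray,
    fraction: float = 0.95,
    min_points: int = 20,
    nest_id: str = "",
) -> MCPResult:
    """Peeled minimum convex polygon of one nest's landing points.

    Points farther from the unweighted centroid than the ``fraction``
    percentile of centroid distances (same closed percentile convention as
    the home-range radius) are peeled off before taking the hull.
    """
    pts = np.asarray(points_xy, float)
    n = len(pts)
    if n < min_points:
        return MCPResult(nest_id, None, n, 0, "insufficient_points")
    centroid = pts.mean(axis=0)
    d = np.hypot(*(pts - centroid).T)
    cut = weighted_percentile(d, np.ones(n), fraction)
    kept = pts[d <= cut]
    hull = MultiPoint([tuple(p) for p in kept]).convex_hull
    return MCPResult(nest_id, float(hull.area / 1e4), n, len(kept), None, hull)


def mcp95_per_nest(
    landing_points: pd.DataFrame,
    fraction: float = 0.95,
    min_points: int = 20,
) -> list[MCPResult]:
    pts = landing_points[landing_points["safe"].astype(bool)]
    return [
        mcp95(grp[["x", "y"]].to_numpy(), fraction, min_points, nest_id=nid)
        for nid, grp in pts.groupby("nest_id")
    ]


# ---------------------------------------------------------------------------
# trend models


@dataclass
class TrendModels:
    frequency_per_h: MixedFitResult
    frequency_per_h_chick: MixedFitResult
    distance: MixedFitResult
    mcp95: object  # statsmodels OLS results
    diagnostics: dict


def _session_design(records: pd.DataFrame, nests: pd.DataFrame, cfg: StudyConfig):
    df = records.merge(
        nests[["nest_id", "radio_tagged", "year"]], on="nest_id", validate="many_to_one"
    )
    df["day"] = day_of_season(df["date"], cfg)
    ref_year = sorted(df["year"].unique())[0]
    cols = {
        "day": df["day"].astype(float),
        "chick_age": df["chick_age_days"].astype(float),
        "daytime_min": df["start_time_min"].astype(float),
        "temperature": df["temperature_C"].astype(float),
        "wind": df["wind_kmh"].astype(float),
        "radio_tagged": df["radio_tagged"].astype(float),
    }
    names = ["intercept"] + list(cols)
    X = np.column_stack([np.ones(len(df))] + [v.to_numpy() for v in cols.values()])
    if df["year"].nunique() > 1:
        X = np.column_stack([X, (df["year"] != ref_year).to_numpy(float)])
        names.append(f"year_not_{ref_year}")
    w = 1.0 / df.groupby("nest_id")["nest_id"].transform("size").to_numpy()
    w = w * (len(w) / w.sum())  # equal-nest ratios at mean weight 1
    return df, X, names, w


def fit_trend_models(
    sessions_records: pd.DataFrame,
    distance_records: pd.DataFrame,
    mcp_results: list[MCPResult],
    nests: pd.DataFrame,
    config: StudyConfig | None = None,
) -> TrendModels:
    """The three mixed models plus the MCP95 linear model.

    ``sessions_records`` comes from :func:`feeding_frequencies`,
    ``distance_records`` from :func:`flight_distances` (sessions joined for
    covariates). Equal nest weighting is observation weight 1/nᵢ.
    """
    cfg = config or StudyConfig()
    df, X, names, w = _session_design(sessions_records, nests, cfg)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        sds = X.std(axis=0)
        aliased = [n for n, s in zip(names, sds) if s == 0 and n != "intercept"]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    groups = df["nest_id"].to_numpy()
    fit_fh = fit_linear_mixed(
        df["feeding_frequency_per_h"].to_numpy(float), X, groups, w, names
    )
    fit_fhc = fit_linear_mixed(
        df["feeding_frequency_per_h_chick"].to_numpy(float), X, groups, w, names
    )

    dmerged = distance_records.merge(
        sessions_records[
            [
                "session_id",
                "date",
                "chick_age_days",
                "start_time_min",
                "temperature_C",
                "wind_kmh",
            ]
        ],
        on="session_id",
        validate="many_to_one",
    )
    ddf, Xd, dnames, wd = _session_design(dmerged, nests, cfg)
    fit_d = fit_linear_mixed(
        ddf["distance_m"].to_numpy(float), Xd, ddf["nest_id"].to_numpy(), wd, dnames
    )

    # MCP95 linear model: one row per included nest
    sess_by_nest = sessions_records.groupby("nest_id")
    rows = []
    for r in mcp_results:
        if r.area_ha is None or r.nest_id not in sess_by_nest.groups:
            continue
        g = sess_by_nest.get_group(r.nest_id)
        nest = nests.set_index("nest_id").loc[r.nest_id]
        rows.append(
            {
                "nest_id": r.nest_id,
                "area_ha": r.area_ha,
                "hatch_day": day_of_season(pd.Timestamp(nest["hatch_date"]), cfg),
                "pct_before_noon": 100.0 * (g["start_time_min"] < 720).mean(),
                "mean_temperature": g["temperature_C"].mean(),
                "mean_wind": g["wind_kmh"].mean(),
                "radio_tagged": float(nest["radio_tagged"]),
                "year": int(nest["year"]),
            }
        )
    mdf = pd.DataFrame(rows)
    ref_year = sorted(mdf["year"].unique())[0]
    Xm = pd.DataFrame(
        {
            "intercept": 1.0,
            "hatch_day": mdf["hatch_day"],
            "pct_before_noon": mdf["pct_before_noon"],
            "mean_temperature": mdf["mean_temperature"],
            "mean_wind": mdf["mean_wind"],
            "radio_tagged": mdf["radio_tagged"],
        }
    )
    if mdf["year"].nunique() > 1:
        Xm[f"year_not_{ref_year}"] = (mdf["year"] != ref_year).astype(float)
    ols = sm.OLS(mdf["area_ha"].to_numpy(float), Xm).fit()

    resid = ols.resid
    diagnostics = {
        "mcp_residual_vs_fitted": pd.DataFrame(
            {"fitted": ols.fittedvalues, "residual": resid}
        ),
        "mcp_residual_quantiles": np.percentile(resid, [5, 25, 50, 75, 95]).tolist(),
        "n_mcp": len(mdf),
    }
    return TrendModels(fit_fh, fit_fhc, fit_d, ols, diagnostics)
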