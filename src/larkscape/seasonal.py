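"""Per-habitat seasonal-use models.

For each frequent habitat category, every in-range safe landing point of a
nest whose home range contains that habitat becomes a Bernoulli trial
(landed in the focal habitat or not). A logistic mixed model with a random
nest intercept regresses this on the day of season, adjusted for the
habitat's weighted surface area and the study year; observations are
weighted so that each nest contributes equally per observation day. The
prediction curve at the average weighted surface area is classified per day
against the availability line (preferred / proportional / avoided).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .glmm import MixedFitResult, fit_logistic_mixed
from .home_range import HomeRange
from .io import Landscape
from .types import StudyConfig


def build_seasonal_design(
    focal_habitat: str,
    home_ranges: list[HomeRange],
    availability: pd.DataFrame,
    landing_points: pd.DataFrame,
    sessions: pd.DataFrame,
    nests: pd.DataFrame,
    landscape: Landscape,
    config: StudyConfig | None = None,
) -> pd.DataFrame:
    """One row per in-range safe landing point of an included nest.

    ``availability`` is the long composition table (nest_id, habitat,
    available_pct); nests whose home range lacks the focal habitat are
    excluded. The ``weight`` column implements equal nest weighting per
    observation day: 1 / (points of that nest on that day).
    """
    from .io import day_of_season

    cfg = config or StudyConfig()
    avail = availability[
        (availability["habitat"] == focal_habitat) & (availability["available_pct"] > 0)
    ].set_index("nest_id")["available_pct"]
    included = [hr for hr in home_ranges if hr.nest_id in avail.index]
    if not included:
        raise ValueError(f"no home range contains habitat {focal_habitat!r}")

    sess = sessions.set_index("session_id")
    year_by_nest = nests.set_index("nest_id")["year"]
    rows = []
    for hr in included:
        pts = landing_points[
            landing_points["safe"].astype(bool)
            & (landing_points["nest_id"] == hr.nest_id)
        ]
        if pts.empty:
            continue
        d = np.hypot(pts["x"] - hr.center[0], pts["y"] - hr.center[1])
        pts = pts[d <= hr.radius_m]
        if pts.empty:
            continue
        habs = landscape.habitat_at(pts["x"].to_numpy(), pts["y"].to_numpy())
        dates = sess.loc[pts["session_id"], "date"].to_numpy()
        days = day_of_season(pd.Series(dates), cfg)
        for (_, pt), hab, day in zip(pts.iterrows(), habs, days):
            rows.append(
                {
                    "nest_id": hr.nest_id,
                    "point_id": pt["point_id"],
                    "response": int(hab == focal_habitat),
                    "day": int(day),
                    "weighted_surface_area_pct": float(avail[hr.nest_id]),
                    "year": int(year_by_nest[hr.nest_id]),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError(f"no usable landing points for habitat {focal_habitat!r}")
    per_day = df.groupby(["nest_id", "day"])["response"].transform("size")
    df["weight"] = 1.0 / per_day
    return df


@dataclass
class SeasonalModelResult:
    habitat: str
    n_points: int
    n_nests: int
    fit: MixedFitResult
    mean_wsa_pct: float
    reference_year: int

    def summary_frame(self) -> pd.DataFrame:
        return self.fit.summary_frame()


def fit_seasonal_model(
    design: pd.DataFrame, habitat: str = "", weighted: bool = True
) -> SeasonalModelResult:
    """Logistic mixed model: response ~ day + weighted surface area + year."""
    if design["nest_id"].nunique() < 2:
        raise ValueError("need at least 2 nests")
    if design["response"].nunique() < 2:
        raise ValueError("both response classes must be present")
    years = sorted(design["year"].unique())
    ref_year = years[0]
    X = np.column_stack(
        [
            np.ones(len(design)),
            design["day"].to_numpy(float),
            design["weighted_surface_area_pct"].to_numpy(float),
            (design["year"] != ref_year).to_numpy(float),
        ]
    )
    names = ["intercept", "day", "weighted_surface_area_pct", f"year_not_{ref_year}"]
    if len(years) == 1:  # year indicator would be aliased
        X = X[:, :3]
        names = names[:3]
    if weighted:
        # relative equal-per-nest-day weights rescaled to mean 1 so the
        # likelihood keeps the conventional effective sample size
        w = design["weight"].to_numpy(float)
        w = w * (len(w) / w.sum())
    else:
        w = None
    fit = fit_logistic_mixed(
        design["response"].to_numpy(float),
        X,
        design["nest_id"].to_numpy(),
        weights=w,
        names=names,
    )
    if not fit.converged:
        raise RuntimeError(f"seasonal model for {habitat!r} did not converge")
    return SeasonalModelResult(
        habitat=habitat,
        n_points=len(design),
        n_nests=design["nest_id"].nunique(),
        fit=fit,
        mean_wsa_pct=float(
            design.groupby("nest_id")["weighted_surface_area_pct"].first().mean()
        ),
        reference_year=ref_year,
    )


def classify_against_availability(
    result: SeasonalModelResult,
    mean_wsa_pct: float | None = None,
    days: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predicted use probability per day vs the availability dashed line.

    Predictions are conditional on the average nest (random intercept 0),
    at the mean weighted surface area and the reference year; the line is
    ``mean_wsa_pct / 100``. Classified ``preferred`` where the lower CI
    bound exceeds the line, ``avoided`` where the upper bound is below it,
    else ``proportional``.
    """
    wsa = result.mean_wsa_pct if mean_wsa_pct is None else mean_wsa_pct
    if wsa <= 0:
        raise ValueError("mean weighted surface area must be positive")
    if days is None:
        days = np.arange(1, 101)
    days = np.asarray(days, float)
    n = days.size
    cols = list(result.fit.params.index)
    X = np.zeros((n, len(cols)))
    X[:, cols.index("intercept")] = 1.0
    X[:, cols.index("day")] = days
    X[:, cols.index("weighted_surface_area_pct")] = wsa
    beta = result.fit.params.to_numpy()
    eta = X @ beta
    if result.fit.cov_params is not None:
        var = np.einsum("ij,jk,ik->i", X, result.fit.cov_params, X)
    else:  # fall back to independent-normal approximation
        var = (X**2) @ (result.fit.bse.to_numpy() ** 2)
    var = np.maximum(var, 0.0)
    lo, hi = eta - 1.96 * np.sqrt(var), eta + 1.96 * np.sqrt(var)
    p, plo, phi = expit(eta), expit(lo), expit(hi)
    line = wsa / 100.0
    cls = np.where(plo > line, "preferred", np.where(phi < line, "avoided", "proportional"))
    return pd.DataFrame(
        {
            "day": days.astype(int),
            "predicted_use": p,
            "lower": plo,
            "upper": phi,
            "availability": line,
            "classification": cls,
        }
    )
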