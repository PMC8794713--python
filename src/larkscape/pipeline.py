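"""End-to-end orchestration of the analysis stages on one dataset."""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import compositional, covariates, foraging, home_range, rsf, seasonal
from .io import Dataset, filter_safe_points


def home_range_stage(ds: Dataset, weighting: str = "distance") -> dict:
    """Global radius, per-nest home ranges, availability/use composition."""
    cfg = ds.config
    safe, excl = filter_safe_points(ds.landing_points)
    radius = home_range.estimate_radius(ds.nests, safe, cfg.home_range_percentile)
    hrs = {
        n["nest_id"]: home_range.build_home_range(n, ds.landscape, radius)
        for _, n in ds.nests.iterrows()
    }
    comp = home_range.composition_table(
        ds.nests, safe, ds.landscape, radius, cfg, weighting=weighting
    )
    return {
        "radius_m": radius,
        "home_ranges": hrs,
        "composition": comp,
        "exclusion": excl,
        "safe_points": safe,
    }


def covariate_stage(ds: Dataset, hr_stage: dict) -> pd.DataFrame:
    """Per-patch covariate tables for all surveyed nests, concatenated."""
    nests = ds.nests
    surveyed = (
        nests[nests["surveyed"].astype(bool)] if "surveyed" in nests else nests
    )
    frames = [
        covariates.assemble_covariates(
            hr_stage["home_ranges"][nid], ds.arthropod_samples, ds.vegetation
        )
        for nid in surveyed["nest_id"]
    ]
    return pd.concat(frames, ignore_index=True)


def rsf_stage(
    ds: Dataset,
    hr_stage: dict,
    cov: pd.DataFrame,
    seed: int,
    n_absences: int | None = None,
    n_perm: int = 100,
    k_basis: int = 10,
    alpha: list[float] | None = None,
) -> dict:
    cfg = ds.config
    nests = ds.nests
    surveyed = (
        nests[nests["surveyed"].astype(bool)] if "surveyed" in nests else nests
    )
    hrs = [hr_stage["home_ranges"][nid] for nid in surveyed["nest_id"]]
    pts = rsf.build_rsf_points(
        hrs,
        hr_stage["safe_points"],
        cov,
        n_absences or cfg.pseudo_absences_per_home_range,
        seed,
    )
    fit = rsf.fit_rsf(pts, k_basis=k_basis, alpha=alpha)
    curves = {
        name: rsf.classify_selection(fit, name)
        for name in rsf.PREDICTOR_LABELS.values()
    }
    imp = rsf.permutation_importance(fit, n_reps=n_perm, seed=seed + 1)
    return {"points": pts, "fit": fit, "curves": curves, "importance": imp}


def compositional_stage(ds: Dataset, hr_stage: dict, seed: int) -> dict:
    cfg = ds.config
    return compositional.compositional_analysis(
        hr_stage["composition"],
        threshold_fraction=cfg.frequent_habitat_fraction,
        n_iter=cfg.n_randomizations,
        seed=seed,
        zero_replacement=cfg.zero_use_replacement,
    )


def seasonal_stage(ds: Dataset, hr_stage: dict, comp_result: dict) -> dict:
    cfg = ds.config
    hrs = list(hr_stage["home_ranges"].values())
    out = {}
    for hab in comp_result["categories"]:
        if hab == "other":
            continue
        try:
            design = seasonal.build_seasonal_design(
                hab,
                hrs,
                hr_stage["composition"],
                hr_stage["safe_points"],
                ds.sessions,
                ds.nests,
                ds.landscape,
                cfg,
            )
            res = seasonal.fit_seasonal_model(design, habitat=hab)
            out[hab] = {
                "model": res,
                "classification": seasonal.classify_against_availability(res),
            }
        except (ValueError, RuntimeError) as exc:
            out[hab] = {"error": str(exc)}
    return out


def foraging_stage(ds: Dataset) -> dict:
    cfg = ds.config
    freq, log = foraging.feeding_frequencies(ds.sessions, ds.landing_points)
    dist = foraging.flight_distances(ds.nests, ds.landing_points)
    mcps = foraging.mcp95_per_nest(
        ds.landing_points, cfg.mcp_fraction, cfg.mcp_min_points
    )
    trends = foraging.fit_trend_models(freq, dist, mcps, ds.nests, cfg)
    areas = [m.area_ha for m in mcps if m.area_ha is not None]
    return {
        "frequencies": freq,
        "exclusion_log": log,
        "distances": dist,
        "mcp": mcps,
        "trends": trends,
        "summary": {
            "mean_frequency_per_h": float(freq["feeding_frequency_per_h"].mean()),
            "mean_frequency_per_h_chick": float(
                freq["feeding_frequency_per_h_chick"].mean()
            ),
            "mean_distance_m": float(dist["distance_m"].mean()),
            "mean_mcp95_ha": float(np.mean(areas)) if areas else None,
            "n_mcp_nests": len(areas),
        },
    }


def run_all(ds: Dataset, seed: int = 0, n_perm: int = 100) -> dict:
    hr = home_range_stage(ds)
    cov = covariate_stage(ds, hr)
    results = {
        "home_range": hr,
        "covariates": cov,
        "rsf": rsf_stage(ds, hr, cov, seed=seed, n_perm=n_perm),
        "compositional": compositional_stage(ds, hr, seed=seed),
        "foraging": foraging_stage(ds),
    }
    results["seasonal"] = seasonal_stage(ds, hr, results["compositional"])
    return results
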