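"""Per-patch covariates: biomass density, insect diversity, vegetation cover.

Arthropod dry mass is converted to g/m² using the vacuum-sampler geometry
(n touchdowns × tube cross-section). The Shannon index uses natural
logarithms and counts of *insect* orders only; spiders and other non-insect
groups contribute to biomass but not to diversity. Fractional vegetation
cover (FVC) is the mean of up to three observer estimates, forced to zero
for field paths and for vegetation no taller than 5 cm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .home_range import HomeRange
from .types import NON_INSECT_GROUPS


def shannon_index(counts_by_order: dict[str, float] | pd.Series) -> float:
    """H = −Σ pᵢ ln pᵢ over orders with positive counts (natural log)."""
    counts = np.array(
        [c for c in dict(counts_by_order).values() if c > 0], dtype=float
    )
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("Shannon index undefined for all-zero counts")
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def sampled_area_m2(device_diameter_m: float, n_touchdowns: int) -> float:
    if device_diameter_m <= 0:
        raise ValueError("device diameter must be positive")
    if n_touchdowns <= 0:
        raise ValueError("touchdown count must be positive")
    return n_touchdowns * math.pi * (device_diameter_m / 2.0) ** 2


def biomass_density(sample: pd.Series | dict) -> float:
    """Dry mass per sampled ground area, g/m²."""
    area = sampled_area_m2(
        float(sample["device_diameter_m"]), int(sample["n_touchdowns"])
    )
    mass = float(sample["dry_mass_g"])
    if mass < 0:
        raise ValueError("negative dry mass")
    return mass / area


def fvc(record: pd.Series | dict) -> float:
    """Mean observer cover estimate; zero for field paths and low swards."""
    rec = dict(record)
    if rec.get("is_field_path") or rec.get("low_vegetation"):
        return 0.0
    ests = [
        float(rec[k])
        for k in ("est_1", "est_2", "est_3")
        if k in rec and pd.notna(rec[k])
    ]
    if not ests:
        raise ValueError("no observer estimates and no zero-cover rule applies")
    return float(np.mean(ests))


def _insect_counts(sample: pd.Series | dict) -> dict[str, float]:
    out = {}
    for k, v in dict(sample).items():
        if k.startswith("count_") and pd.notna(v):
            order = k[len("count_"):]
            if order.lower() not in NON_INSECT_GROUPS:
                out[order] = float(v)
    return out


def sample_covariates(sample: pd.Series | dict) -> tuple[float, float | None]:
    """(biomass g/m², Shannon H or None when no insects were caught)."""
    dens = biomass_density(sample)
    counts = _insect_counts(sample)
    try:
        H = shannon_index(counts)
    except ValueError:
        H = None
    return dens, H


def assemble_covariates(
    home_range: HomeRange,
    samples: pd.DataFrame,
    vegetation: pd.DataFrame,
) -> pd.DataFrame:
    """One covariate row per clipped patch of a home range.

    A patch missing a covariate gets the mean of same-habitat patches in the
    *same* home range (provenance ``imputed_same_type``); if none exists the
    gap is kept (provenance ``missing``). Imputation never crosses home
    ranges or habitat types.
    """
    s_by_patch = {r["patch_id"]: r for _, r in samples.iterrows()}
    v_by_patch: dict[str, list] = {}
    for _, r in vegetation.iterrows():
        v_by_patch.setdefault(r["patch_id"], []).append(r)

    rows = []
    for patch_id, habitat, geom in home_range.patches:
        row = {
            "nest_id": home_range.nest_id,
            "patch_id": patch_id,
            "habitat": habitat,
            "clipped_area_m2": geom.area,
        }
        if patch_id in s_by_patch:
            dens, H = sample_covariates(s_by_patch[patch_id])
            row["biomass_gm2"], row["biomass_prov"] = dens, "measured"
            row["shannon_H"] = H
            row["shannon_prov"] = "measured" if H is not None else "missing"
        else:
            row["biomass_gm2"] = row["shannon_H"] = np.nan
            row["biomass_prov"] = row["shannon_prov"] = "missing"
        if patch_id in v_by_patch:
            row["fvc_pct"] = float(np.mean([fvc(r) for r in v_by_patch[patch_id]]))
            row["fvc_prov"] = "measured"
        else:
            row["fvc_pct"], row["fvc_prov"] = np.nan, "missing"
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df

    for col, prov in (
        ("biomass_gm2", "biomass_prov"),
        ("shannon_H", "shannon_prov"),
        ("fvc_pct", "fvc_prov"),
    ):
        means = df.groupby("habitat")[col].transform("mean")
        gap = df[col].isna() & means.notna()
        df.loc[gap, col] = means[gap]
        df.loc[gap, prov] = "imputed_same_type"
    return df
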