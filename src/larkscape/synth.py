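"""Synthetic central-place-foraging study generator with known ground truth.

The generator emulates the structure of a two-year field study of
chick-provisioning Skylarks in a heterogeneous crop mosaic:

* a space-filling farmland landscape (row-strip mosaic with thin field-path
  strips, mean field size ~5.1 ha, crop shares as observed),
* nests with hatch dates spanning late April–July and per-nest observation
  sessions (capped at 10 flights or 90 min),
* foraging flights drawn on a 5-m grid with probability proportional to
  ``exp(-d/λ) × weight(habitat, day)`` — an exponential distance-decay
  kernel times a time-varying habitat attractiveness,
* per-patch arthropod communities (negative-binomial counts by order,
  lognormal dry mass) and logistic vegetation growth scored by three
  observers on a 10% grid.

Everything is deterministic given ``SimulationTruth.rng_seed``; the truth
object records every parameter so each pipeline stage can be tested for
parameter recovery.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .io import Dataset, Landscape, write_dataset
from .types import HabitatPatch, StudyConfig

HALF_MONTH_DAYS = 15  # season bucket width for arthropod dynamics


@dataclass
class HabitatDynamics:
    """Attractiveness of one habitat as a function of day-of-season.

    ``weight(day) = base * exp(slope * (day - 45))``; ``slope=0`` is a
    constant preference, negative slopes emulate habitats growing too dense
    to forage in later in the season.
    """

    base: float
    slope: float = 0.0

    def weight(self, day: float) -> float:
        return self.base * math.exp(self.slope * (day - 45.0))


@dataclass
class VegGrowth:
    """Logistic cover curve: asymptote / (1 + exp(-rate·(day − midpoint)))."""

    asymptote: float  # percent, <= 100
    midpoint_day: float
    rate: float

    def cover(self, day: float) -> float:
        return self.asymptote / (1.0 + math.exp(-self.rate * (day - self.midpoint_day)))


@dataclass
class ArthropodCommunity:
    """Mid-season mean counts per sampled transect, by arthropod group."""

    order_means: dict[str, float]
    biomass_gm2: float
    seasonal_multipliers: tuple[float, ...] = (0.6, 0.8, 1.0, 1.2, 1.3, 1.4)

    def means_at(self, day: float) -> dict[str, float]:
        idx = min(max(int((day - 1) // HALF_MONTH_DAYS), 0), len(self.seasonal_multipliers) - 1)
        m = self.seasonal_multipliers[idx]
        return {k: v * m for k, v in self.order_means.items()}


@dataclass
class SimulationTruth:
    """All ground-truth parameters of one simulated study."""

    rng_seed: int = 0
    # landscape
    landscape_size_m: float = 2800.0
    mean_field_ha: float = 5.1
    path_width_m: float = 3.0
    habitat_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "winter_wheat": 0.345,
            "sugar_beet": 0.203,
            "corn": 0.092,
            "other:winter_barley": 0.080,
            "other:winter_rape": 0.071,
            "annual_flower_strip": 0.031,
            "other:fallow": 0.014,
            "other:grassland": 0.027,
            "other:trial_plot": 0.137,
        }
    )
    # flights
    distance_decay_lambda_m: float = 40.0
    habitat_weights: dict[str, HabitatDynamics] = field(
        default_factory=lambda: {
            "winter_wheat": HabitatDynamics(0.9, 0.010),
            "sugar_beet": HabitatDynamics(1.1, -0.010),
            "corn": HabitatDynamics(1.0, 0.0),
            "annual_flower_strip": HabitatDynamics(2.0, -0.020),
            "field_path": HabitatDynamics(2.0, 0.0),
        }
    )
    default_habitat_weight: HabitatDynamics = field(
        default_factory=lambda: HabitatDynamics(0.8, 0.0)
    )
    flight_radius_m: float = 500.0
    flight_grid_m: float = 5.0
    ambiguous_rate: float = 0.024
    # nests & sessions
    n_nests: int = 51
    n_nests_surveyed: int = 42
    years: tuple[int, ...] = (2018, 2019)
    hatch_day_range: tuple[int, int] = (0, 70)  # offset from April 25
    mean_observation_days: float = 5.2
    feeding_rate_base: float = 7.3  # visits/h at chick age 0
    feeding_rate_age_slope: float = 1.0
    feeding_rate_sd: float = 3.0
    brood_mean: float = 3.3
    radio_tag_fraction: float = 0.24
    not_before_sunset_rate: float = 0.03
    # covariates
    dispersion: float = 2.0  # negative-binomial size; inf => Poisson
    dry_mass_sigma: float = 0.4
    device_diameter_m: float = 0.14
    n_touchdowns: int = 20
    fvc_observer_noise: float = 10.0
    arthropod: dict[str, ArthropodCommunity] = field(
        default_factory=lambda: {
            "winter_wheat": ArthropodCommunity(
                {"diptera": 18, "hemiptera": 14, "coleoptera": 8, "hymenoptera": 5, "araneae": 6},
                0.10,
            ),
            "sugar_beet": ArthropodCommunity(
                {"diptera": 20, "hemiptera": 2, "coleoptera": 2, "hymenoptera": 1, "araneae": 2},
                0.04,
            ),
            "corn": ArthropodCommunity(
                {"diptera": 8, "hemiptera": 6, "coleoptera": 4, "hymenoptera": 2, "araneae": 2},
                0.06,
            ),
            "annual_flower_strip": ArthropodCommunity(
                {
                    "diptera": 16,
                    "hemiptera": 12,
                    "coleoptera": 10,
                    "hymenoptera": 8,
                    "lepidoptera": 3,
                    "araneae": 8,
                },
                0.15,
            ),
            "field_path": ArthropodCommunity(
                {
                    "diptera": 15,
                    "hemiptera": 12,
                    "coleoptera": 12,
                    "hymenoptera": 10,
                    "orthoptera": 5,
                    "araneae": 9,
                },
                0.22,
            ),
        }
    )
    default_arthropod: ArthropodCommunity = field(
        default_factory=lambda: ArthropodCommunity(
            {"diptera": 12, "hemiptera": 6, "coleoptera": 5, "hymenoptera": 3, "araneae": 4},
            0.08,
        )
    )
    veg_growth: dict[str, VegGrowth] = field(
        default_factory=lambda: {
            "winter_wheat": VegGrowth(95.0, 0.0, 0.10),
            "sugar_beet": VegGrowth(88.0, 48.0, 0.09),
            "corn": VegGrowth(92.0, 58.0, 0.09),
            "annual_flower_strip": VegGrowth(92.0, 38.0, 0.10),
            "field_path": VegGrowth(0.0, 50.0, 0.10),
        }
    )
    default_veg_growth: VegGrowth = field(default_factory=lambda: VegGrowth(80.0, 45.0, 0.08))

    def habitat_weight(self, habitat: str, day: float) -> float:
        dyn = self.habitat_weights.get(habitat, self.default_habitat_weight)
        return dyn.weight(day)

    def to_json(self, path: str | Path) -> None:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=enc)


def _rng(truth: SimulationTruth, stage: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([stage, truth.rng_seed % (2**31)])


# ---------------------------------------------------------------------------
# landscape


def generate_landscape(truth: SimulationTruth) -> Landscape:
    """Row-strip farmland mosaic with field-path strips between rows.

    Rows of random height are split into fields of random width whose
    expected area equals ``mean_field_ha``; habitats are drawn from the
    configured proportions. Fully space-filling: fields plus paths tile the
    square exactly.
    """
    rng = _rng(truth, 1)
    size = truth.landscape_size_m
    mean_area = truth.mean_field_ha * 1e4
    year = truth.years[0]
    habs = list(truth.habitat_proportions)
    probs = np.array([truth.habitat_proportions[h] for h in habs], float)
    probs = probs / probs.sum()

    patches: list[HabitatPatch] = []
    k = 0
    y = 0.0
    while y < size - 1e-9:
        h = min(rng.uniform(180.0, 260.0), size - y)
        x = 0.0
        while x < size - 1e-9:
            w = min(mean_area * rng.uniform(0.6, 1.4) / h, size - x)
            hab = habs[rng.choice(len(habs), p=probs)]
            patches.append(
                HabitatPatch(f"f{k:04d}", hab, year, box(x, y, x + w, y + h))
            )
            k += 1
            x += w
        y += h
        if y < size - 1e-9:
            pw = min(truth.path_width_m, size - y)
            patches.append(
                HabitatPatch(f"p{k:04d}", "field_path", year, box(0.0, y, size, y + pw))
            )
            k += 1
            y += pw
    return Landscape(patches)


# ---------------------------------------------------------------------------
# nests


def simulate_nests(truth: SimulationTruth, landscape: Landscape) -> pd.DataFrame:
    rng = _rng(truth, 2)
    xmin, ymin, xmax, ymax = landscape.bounds()
    margin = 50.0
    rows = []
    for i in range(truth.n_nests):
        year = truth.years[i % len(truth.years)]
        offset = int(rng.integers(truth.hatch_day_range[0], truth.hatch_day_range[1] + 1))
        hatch = dt.date(year, 4, 25) + dt.timedelta(days=offset)
        brood = int(1 + rng.binomial(5, (truth.brood_mean - 1) / 5.0))
        rows.append(
            {
                "nest_id": f"n{i:03d}",
                "x": rng.uniform(xmin + margin, xmax - margin),
                "y": rng.uniform(ymin + margin, ymax - margin),
                "year": year,
                "hatch_date": pd.Timestamp(hatch),
                "brood_size": brood,
                "fate": "predated" if rng.random() < 0.2 else "success",
                "radio_tagged": bool(rng.random() < truth.radio_tag_fraction),
                "surveyed": i < truth.n_nests_surveyed,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flights


class _NestGrid:
    """Candidate landing cells around one nest, with exact probabilities."""

    def __init__(self, truth: SimulationTruth, landscape: Landscape, nx: float, ny: float):
        g = truth.flight_grid_m
        R = truth.flight_radius_m
        off = np.arange(-R, R + g / 2, g)
        dx, dy = np.meshgrid(off, off)
        dx, dy = dx.ravel(), dy.ravel()
        d = np.hypot(dx, dy)
        keep = (d <= R) & (d > 0)
        self.x = nx + dx[keep]
        self.y = ny + dy[keep]
        self.d = d[keep]
        hab = landscape.habitat_at(self.x, self.y)
        covered = hab != ""
        if not covered.any():
            raise ValueError("nest outside the landscape (no covered cells)")
        self.x, self.y, self.d = self.x[covered], self.y[covered], self.d[covered]
        self.habitat = hab[covered]
        self.kernel = np.exp(-self.d / truth.distance_decay_lambda_m)
        self._truth = truth
        self._hab_uniq, self._hab_codes = np.unique(self.habitat, return_inverse=True)

    def probabilities(self, day: float) -> np.ndarray:
        w = np.array([self._truth.habitat_weight(h, day) for h in self._hab_uniq])
        p = self.kernel * w[self._hab_codes]
        total = p.sum()
        if total <= 0:
            raise ValueError("all landing-cell weights are zero")
        return p / total


def simulate_flights(
    truth: SimulationTruth, landscape: Landscape, nests: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observation sessions and landing points for every nest.

    Each observation day yields one session ending at 10 recorded flights or
    90 min, whichever comes first; landing cells are drawn with probability
    ∝ exp(−d/λ) × weight(habitat, day).
    """
    rng = _rng(truth, 3)
    sessions, points = [], []
    si = pi = 0
    for nest in nests.itertuples(index=False):
        grid = _NestGrid(truth, landscape, nest.x, nest.y)
        p_obs = min(1.0, (truth.mean_observation_days - 1) / 7.0)
        n_days = 1 + rng.binomial(7, p_obs)
        hatch = pd.Timestamp(nest.hatch_date)
        for age in range(1, n_days + 1):
            date = hatch + pd.Timedelta(days=age)
            day = (date - pd.Timestamp(date.year, 4, 25)).days + 1
            rate = max(
                2.0,
                truth.feeding_rate_base
                + truth.feeding_rate_age_slope * age
                + rng.normal(0.0, truth.feeding_rate_sd),
            )
            t10 = 600.0 / rate
            if t10 <= 90.0:
                duration, n_fl = t10, 10
            else:
                duration, n_fl = 90.0, max(1, min(10, int(round(rate * 1.5))))
            sid = f"s{si:04d}"
            sessions.append(
                {
                    "session_id": sid,
                    "nest_id": nest.nest_id,
                    "date": date,
                    "start_time_min": float(rng.uniform(300, 1140)),
                    "duration_min": round(duration, 2),
                    "chick_age_days": age,
                    "brood_size": nest.brood_size,
                    "temperature_C": round(float(rng.normal(17.0, 5.0)), 1),
                    "wind_kmh": round(abs(float(rng.normal(8.0, 4.0))), 1),
                    "ended_before_sunset": bool(
                        rng.random() > truth.not_before_sunset_rate
                    ),
                }
            )
            si += 1
            prob = grid.probabilities(day)
            cells = rng.choice(len(prob), size=n_fl, p=prob)
            for c in cells:
                points.append(
                    {
                        "point_id": f"lp{pi:05d}",
                        "session_id": sid,
                        "nest_id": nest.nest_id,
                        "x": float(grid.x[c]),
                        "y": float(grid.y[c]),
                        "safe": bool(rng.random() > truth.ambiguous_rate),
                        "habitat_type_observed": str(grid.habitat[c]),
                    }
                )
                pi += 1
    return pd.DataFrame(sessions), pd.DataFrame(points)


# ---------------------------------------------------------------------------
# covariates


def _draw_count(rng: np.random.Generator, mean: float, size_param: float) -> int:
    if mean <= 0:
        return 0
    if not np.isfinite(size_param):
        return int(rng.poisson(mean))
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def simulate_covariates(
    truth: SimulationTruth,
    landscape: Landscape,
    patch_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One arthropod sample and one vegetation record per (selected) patch.

    Counts per arthropod group are negative binomial around habitat ×
    half-month means; dry mass is lognormal around the configured biomass
    density times the sampled area; cover is the habitat's logistic growth
    curve read by three observers with ±10 noise, rounded to 10% steps.
    """
    rng = _rng(truth, 4)
    sel = set(patch_ids) if patch_ids is not None else None
    all_orders = sorted(
        {o for c in truth.arthropod.values() for o in c.order_means}
        | set(truth.default_arthropod.order_means)
    )
    area = truth.n_touchdowns * math.pi * (truth.device_diameter_m / 2.0) ** 2
    samples, veg = [], []
    for j, patch in enumerate(landscape.patches):
        if sel is not None and patch.patch_id not in sel:
            continue
        day = int(rng.integers(10, 81))
        date = pd.Timestamp(patch.year if patch.year else truth.years[0], 4, 25) + pd.Timedelta(
            days=day - 1
        )
        comm = truth.arthropod.get(patch.habitat_type, truth.default_arthropod)
        means = comm.means_at(day)
        row = {
            "sample_id": f"a{j:04d}",
            "patch_id": patch.patch_id,
            "date": date,
            "device_diameter_m": truth.device_diameter_m,
            "n_touchdowns": truth.n_touchdowns,
            "dry_mass_g": round(
                comm.biomass_gm2
                * area
                * float(rng.lognormal(-truth.dry_mass_sigma**2 / 2, truth.dry_mass_sigma)),
                5,
            ),
        }
        for o in all_orders:
            row[f"count_{o}"] = _draw_count(rng, means.get(o, 0.0), truth.dispersion)
        samples.append(row)

        growth = truth.veg_growth.get(patch.habitat_type, truth.default_veg_growth)
        true_cover = growth.cover(day)
        ests = np.clip(
            np.round(
                (true_cover + rng.uniform(-truth.fvc_observer_noise, truth.fvc_observer_noise, 3))
                / 10.0
            )
            * 10.0,
            0.0,
            100.0,
        )
        veg.append(
            {
                "record_id": f"v{j:04d}",
                "patch_id": patch.patch_id,
                "date": date,
                "low_vegetation": False,
                "is_field_path": patch.habitat_type == "field_path",
                "est_1": ests[0],
                "est_2": ests[1],
                "est_3": ests[2],
            }
        )
    return pd.DataFrame(samples), pd.DataFrame(veg)


# ---------------------------------------------------------------------------
# full dataset


def surveyed_patch_ids(
    landscape: Landscape, nests: pd.DataFrame, radius_m: float = 300.0
) -> list[str]:
    """Patches within the survey radius of any covariate-mapped nest."""
    import shapely

    surveyed = nests[nests.get("surveyed", pd.Series(True, index=nests.index))]
    if surveyed.empty:
        return []
    discs = [
        shapely.Point(r.x, r.y).buffer(radius_m, quad_segs=16)
        for r in surveyed.itertuples(index=False)
    ]
    union = shapely.union_all(discs)
    return [p.patch_id for p in landscape.patches if p.geometry.intersects(union)]


def generate_dataset(truth: SimulationTruth, config: StudyConfig | None = None) -> Dataset:
    """Run all generators; covariates cover only surveyed-nest surroundings."""
    landscape = generate_landscape(truth)
    nests = simulate_nests(truth, landscape)
    sessions, points = simulate_flights(truth, landscape, nests)
    pids = surveyed_patch_ids(landscape, nests)
    samples, veg = simulate_covariates(truth, landscape, pids)
    cfg = config or StudyConfig(rng_seed=truth.rng_seed)
    return Dataset(
        landscape=landscape,
        nests=nests,
        sessions=sessions,
        landing_points=points,
        arthropod_samples=samples,
        vegetation=veg,
        config=cfg,
    )


def write_simulation(truth: SimulationTruth, out_dir: str | Path) -> Dataset:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(truth)
    write_dataset(ds, out)
    truth.to_json(out / "truth.json")
    return ds
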