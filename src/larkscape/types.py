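"""Domain types shared by every pipeline stage.

Coordinates are planar metric (meters) throughout; all distances are
Euclidean. The study extent is a few kilometers, so no geodesy is needed
and none is performed.
"""
from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

from shapely.geometry.base import BaseGeometry

#: The five habitat categories the analyses treat as canonical; every other
#: label is auto-namespaced under ``other:<label>``.
CANONICAL_HABITATS = (
    "winter_wheat",
    "sugar_beet",
    "corn",
    "annual_flower_strip",
    "field_path",
)

#: Arthropod groups counted in samples that are not insect orders; they
#: contribute to dry biomass but are excluded from the Shannon diversity
#: index (identification to order level covered insects only).
NON_INSECT_GROUPS = frozenset(
    {
        "araneae",
        "opiliones",
        "acari",
        "isopoda",
        "chilopoda",
        "diplopoda",
        "collembola",
        "gastropoda",
    }
)


def normalize_habitat(label: str) -> str:
    """Map a free-form habitat label onto the canonical vocabulary.

    Canonical labels and already-namespaced ``other:`` labels pass through;
    anything else becomes ``other:<label>`` with a warning.
    """
    label = label.strip()
    if label in CANONICAL_HABITATS or label.startswith("other:"):
        return label
    warnings.warn(
        f"unknown habitat label {label!r} mapped to 'other:{label}'",
        stacklevel=2,
    )
    return f"other:{label}"


@dataclass(frozen=True)
class HabitatPatch:
    """One polygon of the crop mosaic."""

    patch_id: str
    habitat_type: str
    year: int
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise ValueError(f"patch {self.patch_id}: invalid geometry")
        if self.geometry.area <= 0:
            raise ValueError(f"patch {self.patch_id}: zero-area geometry")


@dataclass(frozen=True)
class Nest:
    nest_id: str
    x: float
    y: float
    year: int
    hatch_date: dt.date
    brood_size: int
    fate: str = "success"
    radio_tagged: bool = False


@dataclass(frozen=True)
class ObservationSession:
    session_id: str
    nest_id: str
    date: dt.date
    start_time_min: float
    duration_min: float
    chick_age_days: int
    brood_size: int
    temperature_C: float
    wind_kmh: float
    ended_before_sunset: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.duration_min <= 90:
            raise ValueError(
                f"session {self.session_id}: duration {self.duration_min} min "
                "outside (0, 90]"
            )


@dataclass(frozen=True)
class LandingPoint:
    point_id: str
    session_id: str
    nest_id: str
    x: float
    y: float
    safe: bool = True
    habitat_type_observed: str = ""


@dataclass
class StudyConfig:
    """Analysis conventions shared across stages.

    ``day_one`` anchors the day-of-season index (day 1 = April 25, the
    earliest documented hatching date); it is stored as (month, day) and
    applied within each observation's own calendar year.
    """

    day_one: tuple[int, int] = (4, 25)
    home_range_percentile: float = 0.95
    pseudo_absences_per_home_range: int = 240
    n_randomizations: int = 1000
    frequent_habitat_fraction: float = 1.0 / 3.0
    mcp_fraction: float = 0.95
    mcp_min_points: int = 20
    rng_seed: int = 0
    zero_use_replacement: float = 1e-4
    shannon_log_base: str = "natural"
    wsa_grid_m: float = 5.0
    wsa_bin_m: float = 10.0

    def __post_init__(self) -> None:
        for name in ("home_range_percentile", "frequent_habitat_fraction", "mcp_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")

    @classmethod
    def from_toml(cls, path) -> "StudyConfig":
        """Load conventions from a TOML file (unknown keys rejected)."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "day_one" in data:
            data["day_one"] = tuple(data["day_one"])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ExclusionSummary:
    """Bookkeeping from the one central ambiguous-point filter."""

    n_total: int
    n_excluded: int
    excluded_pct: float | None

    @property
    def n_kept(self) -> int:
        return self.n_total - self.n_excluded
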