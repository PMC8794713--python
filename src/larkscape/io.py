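"""Readers, writers and integrity checks for the tabular/GeoJSON data model.

On disk a study is a directory of plain-text files::

    landscape.geojson    FeatureCollection; properties patch_id, habitat_type, year
    nests.csv            nest_id,x,y,year,hatch_date,brood_size,fate,radio_tagged
    sessions.csv         session_id,nest_id,date,start_time_min,duration_min,
                         chick_age_days,brood_size,temperature_C,wind_kmh,
                         ended_before_sunset
    landing_points.csv   point_id,session_id,nest_id,x,y,safe,habitat_type_observed
    arthropod_samples.csv sample_id,patch_id,date,device_diameter_m,n_touchdowns,
                          dry_mass_g,count_<group>...
    vegetation.csv       record_id,patch_id,date,low_vegetation,is_field_path,
                         est_1[,est_2,est_3]

In memory the tables are pandas DataFrames (dates parsed to ``datetime64``)
and the landscape a :class:`Landscape` wrapping shapely polygons with a
spatial index.
"""
from __future__ import annotations

import datetime as dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.strtree import STRtree

from .types import ExclusionSummary, HabitatPatch, StudyConfig, normalize_habitat

TABLE_FILES = {
    "nests": "nests.csv",
    "sessions": "sessions.csv",
    "landing_points": "landing_points.csv",
    "arthropod_samples": "arthropod_samples.csv",
    "vegetation": "vegetation.csv",
}


class Landscape:
    """A space-filling habitat-polygon mosaic with point-lookup support."""

    def __init__(self, patches: list[HabitatPatch]):
        if not patches:
            raise ValueError("landscape has no patches")
        ids = [p.patch_id for p in patches]
        per_year: dict[int, set] = {}
        for p in patches:
            seen = per_year.setdefault(p.year, set())
            if p.patch_id in seen:
                raise ValueError(f"duplicate patch_id {p.patch_id!r} in year {p.year}")
            seen.add(p.patch_id)
        self.patches = list(patches)
        self._geoms = np.array([p.geometry for p in patches], dtype=object)
        self._tree = STRtree(list(self._geoms))

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def habitat_types(self) -> list[str]:
        return sorted({p.habitat_type for p in self.patches})

    def bounds(self) -> tuple[float, float, float, float]:
        return shapely.union_all(self._geoms).bounds

    def patch_index_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Index of the covering patch for each point, -1 where uncovered.

        Points on shared boundaries resolve to the lowest patch index.
        """
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        res = np.full(len(pts), -1, dtype=int)
        p_idx, g_idx = self._tree.query(pts, predicate="intersects")
        # keep first (lowest geometry index) match per point
        order = np.lexsort((g_idx, p_idx))
        p_idx, g_idx = p_idx[order], g_idx[order]
        first = np.unique(p_idx, return_index=True)[1]
        res[p_idx[first]] = g_idx[first]
        return res

    def habitat_at(self, x, y) -> np.ndarray:
        """Habitat label at each point; empty string where uncovered."""
        idx = self.patch_index_at(np.atleast_1d(x), np.atleast_1d(y))
        labels = np.array([p.habitat_type for p in self.patches] + [""], dtype=object)
        return labels[idx]


@dataclass
class Dataset:
    """One study's full data bundle."""

    landscape: Landscape
    nests: pd.DataFrame
    sessions: pd.DataFrame
    landing_points: pd.DataFrame
    arthropod_samples: pd.DataFrame
    vegetation: pd.DataFrame
    config: StudyConfig = field(default_factory=StudyConfig)


# ---------------------------------------------------------------------------
# landscape I/O


def read_landscape(path: str | Path, year: int | None = None) -> Landscape:
    """Read a GeoJSON habitat mosaic.

    Unknown habitat labels are namespaced under ``other:`` with a warning;
    malformed or zero-area geometries and missing ``habitat_type`` are hard
    errors naming the offending feature.
    """
    with open(path) as fh:
        gj = json.load(fh)
    patches = []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties", {}) or {}
        pid = str(props.get("patch_id", f"feature_{i}"))
        if "habitat_type" not in props:
            raise ValueError(f"feature {pid}: missing habitat_type property")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"feature {pid}: invalid geometry")
        if geom.area <= 0:
            raise ValueError(f"feature {pid}: zero-area geometry")
        fyear = int(props.get("year", year if year is not None else 0))
        if year is not None and fyear != year:
            continue
        patches.append(
            HabitatPatch(pid, normalize_habitat(str(props["habitat_type"])), fyear, geom)
        )
    return Landscape(patches)


def write_landscape(landscape: Landscape, path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {
                "patch_id": p.patch_id,
                "habitat_type": p.habitat_type,
                "year": p.year,
            },
            "geometry": mapping(p.geometry),
        }
        for p in landscape.patches
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# table I/O


def _parse_dates(df: pd.DataFrame, cols: tuple[str, ...]) -> pd.DataFrame:
    for c in cols:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c], format="%Y-%m-%d")
    return df


def read_tables(dir_path: str | Path) -> dict[str, pd.DataFrame]:
    """Read the five CSV tables and validate cross-references.

    Dangling foreign keys, sessions longer than 90 min, and sessions with
    more than 10 landing points are hard errors.
    """
    d = Path(dir_path)
    tables = {}
    for key, fname in TABLE_FILES.items():
        tables[key] = pd.read_csv(d / fname)
    tables["nests"] = _parse_dates(tables["nests"], ("hatch_date",))
    for key in ("sessions", "arthropod_samples", "vegetation"):
        tables[key] = _parse_dates(tables[key], ("date",))
    for col in ("safe",):
        if col in tables["landing_points"]:
            tables["landing_points"][col] = tables["landing_points"][col].astype(bool)
    for col in ("radio_tagged",):
        if col in tables["nests"]:
            tables["nests"][col] = tables["nests"][col].astype(bool)
    if "ended_before_sunset" in tables["sessions"]:
        tables["sessions"]["ended_before_sunset"] = tables["sessions"][
            "ended_before_sunset"
        ].astype(bool)
    errors = validate_tables(tables)
    if errors:
        raise ValueError("integrity errors:\n" + "\n".join(errors))
    return tables


def validate_tables(tables: dict[str, pd.DataFrame]) -> list[str]:
    """Return a list of integrity-error messages (empty when clean)."""
    errors: list[str] = []
    nests, sessions, points = (
        tables["nests"],
        tables["sessions"],
        tables["landing_points"],
    )
    nest_ids = set(nests["nest_id"])
    if len(nest_ids) != len(nests):
        errors.append("duplicate nest_ids")
    session_ids = set(sessions["session_id"])
    bad = sorted(set(sessions["nest_id"]) - nest_ids)
    if bad:
        errors.append(f"sessions reference unknown nests: {bad}")
    bad = sorted(set(points["nest_id"]) - nest_ids)
    if bad:
        errors.append(f"landing points reference unknown nests: {bad}")
    bad = sorted(set(points["session_id"]) - session_ids)
    if bad:
        errors.append(f"landing points reference unknown sessions: {bad}")
    too_long = sessions.loc[sessions["duration_min"] > 90, "session_id"].tolist()
    if too_long:
        errors.append(f"sessions exceed 90 min: {too_long}")
    nonpos = sessions.loc[sessions["duration_min"] <= 0, "session_id"].tolist()
    if nonpos:
        errors.append(f"sessions with non-positive duration: {nonpos}")
    per_session = points.groupby("session_id").size()
    crowded = per_session[per_session > 10].index.tolist()
    if crowded:
        errors.append(f"sessions with more than 10 landing points: {crowded}")
    return errors


def write_tables(tables: dict[str, pd.DataFrame], dir_path: str | Path) -> None:
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    for key, fname in TABLE_FILES.items():
        df = tables[key].copy()
        for c in ("hatch_date", "date"):
            if c in df.columns:
                df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
        df.to_csv(d / fname, index=False)


def read_dataset(dir_path: str | Path, config: StudyConfig | None = None) -> Dataset:
    d = Path(dir_path)
    tables = read_tables(d)
    return Dataset(
        landscape=read_landscape(d / "landscape.geojson"),
        config=config or StudyConfig(),
        **tables,
    )


def write_dataset(ds: Dataset, dir_path: str | Path) -> None:
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    write_landscape(ds.landscape, d / "landscape.geojson")
    write_tables(
        {
            "nests": ds.nests,
            "sessions": ds.sessions,
            "landing_points": ds.landing_points,
            "arthropod_samples": ds.arthropod_samples,
            "vegetation": ds.vegetation,
        },
        d,
    )


# ---------------------------------------------------------------------------
# calendar and filters


def day_of_season(date, config: StudyConfig | None = None):
    """Day index with day 1 = April 25 of the observation's own year.

    Dates before the anchor yield values ≤ 0 and raise a warning (they are
    allowed but flag suspect records). Accepts scalars or array-likes.
    """
    config = config or StudyConfig()
    month, day = config.day_one
    dates = pd.to_datetime(pd.Series(np.atleast_1d(np.asarray(date, dtype=object))))
    anchors = pd.to_datetime(
        {"year": dates.dt.year, "month": month, "day": day}
    )
    out = (dates - anchors).dt.days.to_numpy() + 1
    if (out <= 0).any():
        warnings.warn("date(s) before the season anchor (day-of-season <= 0)", stacklevel=2)
    if np.isscalar(date) or isinstance(date, (dt.date, dt.datetime, str, pd.Timestamp)):
        return int(out[0])
    return out


def percentage(part: float, whole: float, decimals: int = 1) -> float | None:
    """Share of ``part`` in ``whole`` as a percent, rounded; None if empty."""
    if whole == 0:
        return None
    return round(100.0 * part / whole, decimals)


def filter_safe_points(points: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionSummary]:
    """Drop ambiguous landing points, once, centrally.

    The summary carries the excluded percentage rounded to one decimal
    (``None`` for empty input).
    """
    n = len(points)
    safe = points[points["safe"].astype(bool)].copy()
    n_excl = n - len(safe)
    return safe, ExclusionSummary(
        n_total=n, n_excluded=n_excl, excluded_pct=percentage(n_excl, n)
    )


def nest_accounting(nests: pd.DataFrame) -> dict:
    """Tally the active-nest roster into analyzable and excluded groups.

    Expects an ``exclusion_reason`` column where the empty string / ``"none"``
    marks nests with documented foraging flights.
    """
    reasons = nests["exclusion_reason"].fillna("none").replace("", "none")
    counts = reasons.value_counts().to_dict()
    n_analyzable = counts.pop("none", 0)
    return {
        "n_active": len(nests),
        "n_analyzable": n_analyzable,
        "excluded_by_reason": counts,
    }
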