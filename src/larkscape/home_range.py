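"""Fixed-radius home ranges and (distance-weighted) habitat availability.

The home range is a disc of one global radius around each nest, the radius
being the nest-weighted 95th percentile of flight distances. Availability
inside the disc is either the plain area share of each habitat or the
*weighted surface area*: each location is weighted by the per-unit-area
intensity of the pooled distance-use distribution, f̂(d)/(2πd), so that
near-nest area counts for more. With flat weighting the weighted surface
area reduces exactly to the plain area share.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.strtree import STRtree

from .io import Landscape
from .types import StudyConfig

DISC_QUAD_SEGS = 64  # 256-vertex polygonization of the disc


def nest_weighted_distances(
    nests: pd.DataFrame, landing_points: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Distances of safe landing points to their own nest, with weights 1/nᵢ.

    Every nest contributes total weight 1 regardless of how many flights it
    has, so well-observed nests do not dominate the pooled distribution.
    """
    pts = landing_points[landing_points["safe"].astype(bool)]
    if pts.empty:
        raise ValueError("no safe landing points")
    # inner join: points of nests outside the given set are ignored, so the
    # pooled distribution can be computed for any nest subset
    merged = pts.merge(
        nests[["nest_id", "x", "y"]].rename(columns={"x": "nest_x", "y": "nest_y"}),
        on="nest_id",
        how="inner",
        validate="many_to_one",
    )
    if merged.empty:
        raise ValueError("no safe landing points for the given nests")
    d = np.hypot(merged["x"] - merged["nest_x"], merged["y"] - merged["nest_y"]).to_numpy()
    w = (1.0 / merged.groupby("nest_id")["nest_id"].transform("size")).to_numpy()
    return d, w


def weighted_percentile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Smallest order statistic whose cumulative normalized weight ≥ q.

    No interpolation: under unequal weights the percentile is defined as the
    first observed value at which the weighted CDF reaches the target.
    """
    if not 0 < q <= 1:
        raise ValueError("percentile must lie in (0, 1]")
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    if values.size == 0:
        raise ValueError("empty sample")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    cum /= cum[-1]
    idx = np.searchsorted(cum, q - 1e-12)
    return float(values[order][min(idx, values.size - 1)])


def estimate_radius(
    nests: pd.DataFrame,
    landing_points: pd.DataFrame,
    percentile: float = 0.95,
) -> float:
    """Global home-range radius: nest-weighted percentile of flight distances."""
    d, w = nest_weighted_distances(nests, landing_points)
    return weighted_percentile(d, w, percentile)


@dataclass
class HomeRange:
    """One nest's disc, clipped against the habitat mosaic."""

    nest_id: str
    center: tuple[float, float]
    radius_m: float
    patches: list  # (patch_id, habitat_type, clipped geometry)
    coverage_gap_m2: float

    @property
    def disc(self):
        return Point(*self.center).buffer(self.radius_m, quad_segs=DISC_QUAD_SEGS)

    def area_shares_pct(self) -> dict[str, float]:
        """Plain per-habitat area percentages of the mapped part of the disc."""
        areas: dict[str, float] = {}
        for _, hab, geom in self.patches:
            areas[hab] = areas.get(hab, 0.0) + geom.area
        total = sum(areas.values())
        return {h: 100.0 * a / total for h, a in areas.items()}


def build_home_range(
    nest: pd.Series | dict, landscape: Landscape, radius_m: float
) -> HomeRange:
    """Clip the landscape to the nest's disc; record unmapped area as a gap."""
    if radius_m <= 0:
        raise ValueError("radius must be positive")
    cx, cy = float(nest["x"]), float(nest["y"])
    disc = Point(cx, cy).buffer(radius_m, quad_segs=DISC_QUAD_SEGS)
    tree = STRtree([p.geometry for p in landscape.patches])
    clipped = []
    covered = 0.0
    for gi in sorted(tree.query(disc, predicate="intersects")):
        patch = landscape.patches[gi]
        inter = patch.geometry.intersection(disc)
        if inter.area > 0:
            clipped.append((patch.patch_id, patch.habitat_type, inter))
            covered += inter.area
    return HomeRange(
        nest_id=str(nest["nest_id"]),
        center=(cx, cy),
        radius_m=float(radius_m),
        patches=clipped,
        coverage_gap_m2=max(disc.area - covered, 0.0),
    )


def distance_use_density(
    distances: np.ndarray,
    weights: np.ndarray,
    radius_m: float,
    bin_m: float = 10.0,
):
    """Histogram estimate f̂ of the nest-weighted flight-distance density.

    Returns ``(bin_edges, density)`` with the density normalized over
    [0, radius]; distances beyond the radius are excluded (they are outside
    every home range by construction).
    """
    edges = np.arange(0.0, radius_m + bin_m, bin_m)
    edges[-1] = max(edges[-1], radius_m)
    inside = distances <= radius_m
    hist, edges = np.histogram(
        distances[inside], bins=edges, weights=weights[inside], density=True
    )
    return edges, hist


def _disc_grid(hr: HomeRange, grid_m: float):
    cx, cy = hr.center
    r = hr.radius_m
    half = np.arange(grid_m / 2.0, r, grid_m)
    off = np.concatenate([-half[::-1], half])  # symmetric about the nest
    dx, dy = np.meshgrid(off, off)
    dx, dy = dx.ravel(), dy.ravel()
    d = np.hypot(dx, dy)
    keep = d <= r
    return cx + dx[keep], cy + dy[keep], d[keep]


def weighted_surface_area(
    home_range: HomeRange,
    distances: np.ndarray | None = None,
    dist_weights: np.ndarray | None = None,
    grid_m: float = 5.0,
    bin_m: float = 10.0,
    weighting: str = "distance",
) -> dict[str, float]:
    """Per-habitat availability (%) inside the disc.

    ``weighting="distance"`` weights each grid cell by f̂(d)/(2πd), the
    per-unit-area intensity implied by the pooled distance-use distribution;
    ``"flat"`` weights uniformly per area and equals the plain area share.
    Cells in coverage gaps are excluded from the denominator.
    """
    if grid_m > home_range.radius_m / 10.0:
        raise ValueError("grid coarser than radius/10")
    if weighting not in ("distance", "flat"):
        raise ValueError(f"unknown weighting {weighting!r}")
    x, y, d = _disc_grid(home_range, grid_m)
    tree = STRtree([geom for _, _, geom in home_range.patches])
    habs = np.array([hab for _, hab, _ in home_range.patches] + [""], dtype=object)
    idx = np.full(x.size, -1, dtype=int)
    pts = shapely.points(x, y)
    pi, gi = tree.query(pts, predicate="intersects")
    order = np.lexsort((gi, pi))
    pi, gi = pi[order], gi[order]
    first = np.unique(pi, return_index=True)[1]
    idx[pi[first]] = gi[first]
    cell_hab = habs[idx]
    mapped = cell_hab != ""

    if weighting == "flat":
        w = np.ones(x.size)
    else:
        if distances is None or dist_weights is None:
            raise ValueError("distance weighting needs the pooled distance sample")
        if np.sum(distances <= home_range.radius_m) < 50:
            raise ValueError("too few pooled flight distances (< 50) to estimate f̂")
        edges, f = distance_use_density(
            np.asarray(distances, float),
            np.asarray(dist_weights, float),
            home_range.radius_m,
            bin_m,
        )
        b = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, f.size - 1)
        w = f[b] / (2.0 * np.pi * np.maximum(d, grid_m / 2.0))

    w = w * mapped
    total = w.sum()
    if total <= 0:
        raise ValueError("no weighted availability inside the mapped disc")
    out: dict[str, float] = {}
    for hab in np.unique(cell_hab[mapped]):
        out[str(hab)] = float(100.0 * w[cell_hab == hab].sum() / total)
    return out


def habitat_use(
    home_range: HomeRange,
    landing_points: pd.DataFrame,
    landscape: Landscape,
) -> tuple[dict[str, float], dict]:
    """Per-habitat use (%) from in-range safe landing points.

    Membership in the disc is closed (distance ≤ radius). The habitat of a
    point is the mapped habitat at its coordinates; the observer's label is
    kept in the input table for QC only. Returns ``(used_pct, info)`` where
    ``info`` counts out-of-range and unmapped points.
    """
    pts = landing_points[
        landing_points["safe"].astype(bool)
        & (landing_points["nest_id"] == home_range.nest_id)
    ]
    cx, cy = home_range.center
    d = np.hypot(pts["x"] - cx, pts["y"] - cy)
    in_range = pts[d <= home_range.radius_m]
    info = {"n_out_of_range": int(len(pts) - len(in_range)), "n_unmapped": 0}
    if in_range.empty:
        info["empty"] = True
        return {}, info
    habs = landscape.habitat_at(in_range["x"].to_numpy(), in_range["y"].to_numpy())
    mapped = habs != ""
    info["n_unmapped"] = int((~mapped).sum())
    habs = habs[mapped]
    if habs.size == 0:
        info["empty"] = True
        return {}, info
    uniq, counts = np.unique(habs, return_counts=True)
    return {str(h): 100.0 * c / habs.size for h, c in zip(uniq, counts)}, info


def composition_table(
    nests: pd.DataFrame,
    landing_points: pd.DataFrame,
    landscape: Landscape,
    radius_m: float,
    config: StudyConfig | None = None,
    weighting: str = "distance",
) -> pd.DataFrame:
    """Long-format per-nest availability and use percentages.

    One row per (nest, habitat): ``available_pct`` is the weighted surface
    area, ``used_pct`` the share of in-range safe landing points.
    """
    cfg = config or StudyConfig()
    d, w = nest_weighted_distances(nests, landing_points)
    rows = []
    for _, nest in nests.iterrows():
        hr = build_home_range(nest, landscape, radius_m)
        avail = weighted_surface_area(
            hr, d, w, grid_m=cfg.wsa_grid_m, bin_m=cfg.wsa_bin_m, weighting=weighting
        )
        used, _ = habitat_use(hr, landing_points, landscape)
        for hab in sorted(set(avail) | set(used)):
            rows.append(
                {
                    "nest_id": nest["nest_id"],
                    "habitat": hab,
                    "available_pct": avail.get(hab, 0.0),
                    "used_pct": used.get(hab, 0.0),
                }
            )
    return pd.DataFrame(rows)
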