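"""Seasonal windowing, minimum convex polygons, and range parameters.

The hydrological year splits into three seasons — rainy (Dec-Mar), early
flood (Apr-Jul) and late flood (Aug-Nov).  To keep seasons distinct, the
first and last two weeks of each animal-season block are trimmed.  The
minimum convex polygon (MCP) over the remaining fixes defines the area,
and hence habitats, available to an animal; the population MCP pools all
animals in a season-year.  Two derived parameters feed the utilisation
distribution: the time threshold T_max = diameter / (10 x median hourly
distance), beyond which successive fixes are treated as uncorrelated, and
the minimum smoothing parameter h_min = MDT + 50 m (herd spread).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

SEASON_OF_MONTH = {
    12: "rainy", 1: "rainy", 2: "rainy", 3: "rainy",
    4: "early_flood", 5: "early_flood", 6: "early_flood", 7: "early_flood",
    8: "late_flood", 9: "late_flood", 10: "late_flood", 11: "late_flood",
}


@dataclass
class PolygonRange:
    """Convex-hull range of one animal (or the population) in one season."""

    owner: str
    season: str
    year: int
    polygon: Polygon
    n_points: int

    @property
    def area_km2(self) -> float:
        return self.polygon.area / 1e6

    @property
    def diameter_m(self) -> float:
        verts = np.asarray(self.polygon.exterior.coords)[:-1]
        d = np.hypot(
            verts[:, None, 0] - verts[None, :, 0],
            verts[:, None, 1] - verts[None, :, 1],
        )
        return float(d.max())


@dataclass
class RangeParams:
    """Per animal-season parameters driving the movement-based UD."""

    mdt_m: float
    t_max_h: float
    h_min_m: float

    def __post_init__(self) -> None:
        if self.t_max_h <= 0:
            raise ValueError("time threshold must be positive")
        if abs(self.h_min_m - (self.mdt_m + 50.0)) > 1e-9:
            raise ValueError("h_min must equal MDT + 50 m")


def season_of(timestamps: pd.Series) -> pd.DataFrame:
    """Season label and season-year for each timestamp.

    December is assigned to the following calendar year's rainy season so
    that each rainy season (Dec-Mar) carries a single year label.
    """
    ts = pd.to_datetime(timestamps)
    months = ts.dt.month
    season = months.map(SEASON_OF_MONTH)
    year = ts.dt.year + (months == 12).astype(int)
    return pd.DataFrame({"season": season, "season_year": year})


def season_split(
    traj: pd.DataFrame, trim_days: int = 14
) -> dict[tuple[str, str, int], pd.DataFrame]:
    """Split a trajectory into trimmed animal-season blocks.

    Returns a dict keyed by (animal_id, season, season_year).  The first
    and last ``trim_days`` days of each block are dropped; blocks shorter
    than ``2 * trim_days`` come back empty with a warning.
    """
    if trim_days < 0:
        raise ValueError("trim_days must be non-negative")
    df = traj.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values(["animal_id", "timestamp"])
    lab = season_of(df["timestamp"])
    df["season"] = lab["season"].to_numpy()
    df["season_year"] = lab["season_year"].to_numpy()
    out = {}
    for (animal, season, year), block in df.groupby(
        ["animal_id", "season", "season_year"]
    ):
        t0 = block["timestamp"].min() + pd.Timedelta(days=trim_days)
        t1 = block["timestamp"].max() - pd.Timedelta(days=trim_days)
        kept = block.loc[(block["timestamp"] >= t0) & (block["timestamp"] <= t1)]
        if kept.empty:
            warnings.warn(
                f"season block {animal}/{season}/{year} shorter than "
                f"{2 * trim_days} days; empty after trimming",
                stacklevel=2,
            )
        out[(animal, season, int(year))] = kept.reset_index(drop=True)
    return out


def mcp(points, owner: str = "", season: str = "", year: int = 0) -> PolygonRange:
    """Minimum convex polygon over all points (100% MCP, no peeling)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 (x, y) points")
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("points are collinear; convex hull is degenerate")
    return PolygonRange(owner=owner, season=season, year=year, polygon=hull,
                        n_points=len(pts))


def median_hourly_distance(traj: pd.DataFrame, tol_min: float = 5.0) -> float:
    """Median step length over steps whose interval is 1 h +/- ``tol_min``."""
    df = traj.sort_values("timestamp")
    dt_h = df["timestamp"].diff().dt.total_seconds().to_numpy()[1:] / 3600.0
    steps = np.hypot(df["x"].diff().to_numpy()[1:], df["y"].diff().to_numpy()[1:])
    hourly = np.abs(dt_h - 1.0) <= tol_min / 60.0
    if not hourly.any():
        raise ValueError("no hourly steps in trajectory")
    return float(np.median(steps[hourly]))


def time_threshold(
    mcp_diameter_m: float, median_hourly_distance_m: float, cap_h: float | None = None
) -> float:
    """T_max = MCP diameter / (10 x median hourly distance), optionally capped."""
    if mcp_diameter_m <= 0 or median_hourly_distance_m <= 0:
        raise ValueError("diameter and median hourly distance must be positive")
    t = mcp_diameter_m / (10.0 * median_hourly_distance_m)
    if cap_h is not None:
        t = min(t, cap_h)
    return t


def smoothing_parameter(mdt_m: float) -> float:
    """Minimum smoothing bandwidth h_min = MDT + 50 m (herd spread)."""
    if mdt_m < 0:
        raise ValueError("MDT must be non-negative")
    return mdt_m + 50.0


def population_range(
    season_blocks: dict[tuple[str, str, int], pd.DataFrame]
) -> dict[tuple[str, int], PolygonRange]:
    """One pooled MCP per (season, year) over all animals' fixes."""
    pooled: dict[tuple[str, int], list[pd.DataFrame]] = {}
    for (animal, season, year), block in season_blocks.items():
        if len(block):
            pooled.setdefault((season, year), []).append(block[["x", "y"]])
    out = {}
    for (season, year), frames in pooled.items():
        pts = pd.concat(frames).to_numpy()
        out[(season, year)] = mcp(pts, owner="population", season=season, year=year)
    return out
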