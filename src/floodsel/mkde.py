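"""Movement-based kernel density estimation of utilisation distributions.

Instead of smoothing around raw fixes, the estimator smooths along the
interpolated movement path between successive fixes that are close enough
in time to be serially correlated (interval <= the time threshold T_max).
Each such active step contributes a chain of Gaussian kernels along the
segment whose variance follows the biased-random-bridge profile

    h(p)^2 = h_min^2 + 4 p (1 - p) D dt,

maximal mid-step and shrinking to the minimum bandwidth h_min at the end
points; D is a plug-in diffusion coefficient (m^2/h).  Resting fixes
(displacement <= the collar's MDT) and fixes beyond the time threshold
contribute a single kernel of variance h_min^2 weighted by their dwell
time.  A boundary polyline (e.g. a veterinary fence) clips mass to the
side the animal occupies, and the surface renormalises to unit mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, box
from shapely.ops import split as shapely_split

from .home_range import RangeParams
from .raster import HabitatRaster


@dataclass
class UDGrid:
    """Utilisation distribution on the habitat-raster lattice."""

    raster: HabitatRaster
    weights: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.raster.classes.shape:
            raise ValueError("weights shape must match raster")

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def entropy(self) -> float:
        w = self.weights[self.weights > 0]
        return float(-(w * np.log(w)).sum())

    def write_ascii(self, path) -> None:
        from pathlib import Path

        r = self.raster
        header = (
            f"ncols {r.n_cols}\nnrows {r.n_rows}\n"
            f"xllcorner {r.origin_x}\nyllcorner {r.origin_y}\n"
            f"cellsize {r.pixel_size}\nNODATA_value -9999\n"
        )
        with Path(path).open("w") as fh:
            fh.write(header)
            for row in self.weights[::-1]:
                fh.write(" ".join(f"{v:.10e}" for v in row) + "\n")


def classify_activity(
    traj: pd.DataFrame, mdt: float, t_max: float | None = None
) -> pd.DataFrame:
    """Step table with rest/active and (optionally) bridged flags.

    A fix whose displacement from the previous fix is <= MDT is resting —
    such displacements are indistinguishable from collar error.  With
    ``t_max`` given, steps whose interval exceeds it are marked
    un-bridged (no interpolation between their endpoints).
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 fixes")
    ts = pd.to_datetime(traj["timestamp"]).to_numpy()
    if (np.diff(ts).astype("timedelta64[s]").astype(float) <= 0).any():
        raise ValueError("timestamps must be strictly increasing")
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    dt_h = np.diff(ts).astype("timedelta64[s]").astype(float) / 3600.0
    length = np.hypot(np.diff(x), np.diff(y))
    steps = pd.DataFrame(
        {
            "x0": x[:-1], "y0": y[:-1], "x1": x[1:], "y1": y[1:],
            "dt_h": dt_h, "length_m": length, "rest": length <= mdt,
        }
    )
    if t_max is not None:
        steps["bridged"] = steps["dt_h"] <= t_max
    return steps


def estimate_diffusion(steps: pd.DataFrame) -> float:
    """Plug-in diffusion coefficient D (m^2/h).

    The median over active bridged steps of L^2 / (4 dt) — the diffusion
    that would, on average, carry a Brownian bridge the observed distance.
    """
    sel = ~steps["rest"]
    if "bridged" in steps:
        sel &= steps["bridged"]
    active = steps.loc[sel]
    if len(active) < 5:
        raise ValueError("need at least 5 active bridged steps to estimate D")
    stat = active["length_m"] ** 2 / (4.0 * active["dt_h"])
    return float(stat.median())


def _near_side_mask(
    raster: HabitatRaster, boundary: LineString, ref_xy: tuple[float, float]
) -> np.ndarray:
    """True for cells on the same side of the boundary as the reference point."""
    bbox = box(*raster.extent)
    try:
        pieces = shapely_split(bbox, boundary)
    except Exception:
        return np.ones_like(raster.classes, dtype=bool)
    if len(pieces.geoms) < 2:
        return np.ones_like(raster.classes, dtype=bool)
    ref = Point(ref_xy)
    near = [g for g in pieces.geoms if g.contains(ref) or g.distance(ref) < 1e-9]
    if not near:
        return np.ones_like(raster.classes, dtype=bool)
    X, Y = raster.cell_centres()
    pts = shapely.points(X.ravel(), Y.ravel())
    mask = np.zeros(pts.shape, dtype=bool)
    for g in near:
        mask |= shapely.contains(g, pts)
    return mask.reshape(raster.classes.shape)


def _accumulate(grid, raster, cx, cy, sd, wt, trunc_sds):
    """Add a truncated isotropic Gaussian kernel to the grid (midpoint rule)."""
    s = raster.pixel_size
    r = trunc_sds * sd
    j0 = max(int((cx - r - raster.origin_x) // s), 0)
    j1 = min(int((cx + r - raster.origin_x) // s) + 1, raster.n_cols)
    i0 = max(int((cy - r - raster.origin_y) // s), 0)
    i1 = min(int((cy + r - raster.origin_y) // s) + 1, raster.n_rows)
    if i0 >= i1 or j0 >= j1:
        return
    xs = raster.origin_x + (np.arange(j0, j1) + 0.5) * s
    ys = raster.origin_y + (np.arange(i0, i1) + 0.5) * s
    gx = np.exp(-0.5 * ((xs - cx) / sd) ** 2)
    gy = np.exp(-0.5 * ((ys - cy) / sd) ** 2)
    dens = np.outer(gy, gx) / (2 * np.pi * sd**2)
    grid[i0:i1, j0:j1] += wt * dens * s**2


def ud(
    traj: pd.DataFrame,
    raster: HabitatRaster,
    params: RangeParams,
    D: float,
    boundary: LineString | np.ndarray | None = None,
    n_substeps: int = 10,
    trunc_sds: float = 4.0,
) -> UDGrid:
    """Movement-based kernel UD of one trajectory on the raster lattice.

    Bridged active steps lay ``n_substeps`` kernels at fractions
    p = (k - 1/2)/n_substeps along the segment with the bridge variance
    profile, each carrying dt/n_substeps hours of dwell weight.  Rest and
    un-bridged fixes get a single h_min kernel weighted by their dwell
    time.  Mass beyond the boundary polyline (if any) and on nodata cells
    is zeroed before the final renormalisation to unit mass.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    h2 = params.h_min_m**2
    grid = np.zeros_like(raster.classes, dtype=float)
    xs = traj["x"].to_numpy(dtype=float)
    ys = traj["y"].to_numpy(dtype=float)
    xmin, ymin, xmax, ymax = raster.extent
    inside = (xs >= xmin) & (xs < xmax) & (ys >= ymin) & (ys < ymax)
    if not inside.any():
        raise ValueError("trajectory lies wholly outside the raster")

    if len(traj) == 1:
        _accumulate(grid, raster, xs[0], ys[0], params.h_min_m, 1.0, trunc_sds)
    else:
        steps = classify_activity(traj, params.mdt_m, t_max=params.t_max_h)
        # dwell of the first fix: one nominal hour at the start position
        _accumulate(grid, raster, xs[0], ys[0], params.h_min_m, 1.0, trunc_sds)
        p = (np.arange(n_substeps) + 0.5) / n_substeps
        var_shape = 4.0 * p * (1.0 - p)
        for st in steps.itertuples(index=False):
            if (not st.rest) and st.bridged:
                cx = st.x0 + p * (st.x1 - st.x0)
                cy = st.y0 + p * (st.y1 - st.y0)
                sds = np.sqrt(h2 + var_shape * D * st.dt_h)
                w = st.dt_h / n_substeps
                for k in range(n_substeps):
                    _accumulate(grid, raster, cx[k], cy[k], sds[k], w, trunc_sds)
            else:
                _accumulate(
                    grid, raster, st.x1, st.y1, params.h_min_m, st.dt_h, trunc_sds
                )

    grid[raster.classes == raster.nodata] = 0.0
    bmode = "none"
    if boundary is not None:
        line = boundary if isinstance(boundary, LineString) else LineString(
            np.asarray(boundary, dtype=float)
        )
        ref = (float(xs[inside].mean()), float(ys[inside].mean()))
        grid[~_near_side_mask(raster, line, ref)] = 0.0
        bmode = "clip"
    total = grid.sum()
    if total <= 0:
        raise ValueError("UD has no mass on the raster")
    return UDGrid(
        raster=raster,
        weights=grid / total,
        meta={
            "h_min": params.h_min_m, "t_max": params.t_max_h, "D": D,
            "n_substeps": n_substeps, "boundary": bmode, "trunc_sds": trunc_sds,
        },
    )


def ud_weighted_use(udgrid: UDGrid, raster: HabitatRaster) -> dict[int, float]:
    """Per-habitat proportions of UD mass (third-order 'use')."""
    if udgrid.raster.classes.shape != raster.classes.shape or (
        udgrid.raster.pixel_size != raster.pixel_size
    ):
        raise ValueError("UD and raster geometries differ")
    out = {}
    for code in np.unique(raster.classes):
        if code == raster.nodata:
            continue
        out[int(code)] = float(udgrid.weights[raster.classes == code].sum())
    total = sum(out.values())
    if total <= 0:
        raise ValueError("UD carries no mass on valid habitat cells")
    return {k: v / total for k, v in out.items()}
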