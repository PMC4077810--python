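"""Synthetic landscapes, trajectories, collar tests and field tables.

The generator emulates the structure of a flood-pulsed savanna study
system: a categorical habitat map banded by distance to a permanent water
channel, hourly GPS fixes from herbivores switching between four latent
movement states (rest, graze, walk, relocate), stationary collar-error
tests, and field records (disc-pasture-meter drops, quadrat dry weights,
herd demography and ordinal body-condition scores with a year effect).

Every function is a pure function of its parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from shapely.geometry import LineString

from .field_stats import DPM_INTERCEPT, DPM_SLOPE
from .raster import HABITAT_NAMES, HabitatRaster, SEASONALLY_FLOODED
from . import study

STATES = ("rest", "graze", "walk", "relocate")


# --------------------------------------------------------------------------
# Movement-state specification
# --------------------------------------------------------------------------


@dataclass
class MovementStateSpec:
    """Per-state step-length / turning-angle moments and state transitions.

    Step lengths are metres per hourly step; turning angles are absolute
    angles between successive displacement vectors in degrees [0, 180].
    Step means must strictly increase rest < graze < walk < relocate and
    angle means must strictly decrease with step mean (long moves are
    straighter).
    """

    step_mean: dict[str, float]
    step_sd: dict[str, float]
    angle_mean: dict[str, float]
    angle_sd: dict[str, float]
    transition: np.ndarray  # 4x4, row-stochastic, state order as STATES

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        means = [self.step_mean[s] for s in STATES]
        if not all(a < b for a, b in zip(means, means[1:])):
            raise ValueError("step means must strictly increase rest<graze<walk<relocate")
        angles = [self.angle_mean[s] for s in STATES]
        if not all(a > b for a, b in zip(angles, angles[1:])):
            raise ValueError("angle means must strictly decrease with step mean")
        if self.transition.shape != (4, 4):
            raise ValueError("transition matrix must be 4x4")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if (self.transition < 0).any():
            raise ValueError("transition probabilities must be non-negative")

    @classmethod
    def from_study(cls, persistence: float = 0.6) -> "MovementStateSpec":
        """Spec parameterised from the bundled per-animal state summaries.

        The transition matrix mixes identity with the observed mean time
        budget, so the chain's stationary distribution reproduces that
        budget while states persist from hour to hour.
        """
        pooled = study.pooled_state_parameters()
        budgets = study.time_budgets()[list(STATES)].mean().to_numpy()
        pi = budgets / budgets.sum()
        trans = persistence * np.eye(4) + (1 - persistence) * np.tile(pi, (4, 1))
        return cls(
            step_mean={s: pooled[s]["step_mean"] for s in STATES},
            step_sd={s: pooled[s]["step_sd"] for s in STATES},
            angle_mean={s: pooled[s]["angle_mean"] for s in STATES},
            angle_sd={s: pooled[s]["angle_sd"] for s in STATES},
            transition=trans,
        )

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the state chain."""
        vals, vecs = np.linalg.eig(self.transition.T)
        v = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
        return v / v.sum()


# --------------------------------------------------------------------------
# Landscape
# --------------------------------------------------------------------------


def _channel_line(extent, axis_spec) -> LineString:
    xmin, ymin, xmax, ymax = extent
    if isinstance(axis_spec, (list, tuple, np.ndarray)) and not isinstance(
        axis_spec, str
    ):
        return LineString(np.asarray(axis_spec, dtype=float))
    width, height = xmax - xmin, ymax - ymin
    t = np.linspace(0.0, 1.0, 64)
    if axis_spec == "west":
        pts = np.c_[xmin + 0.05 * width + 0.03 * width * np.sin(4 * np.pi * t), ymin + t * height]
    elif axis_spec == "east":
        pts = np.c_[xmax - 0.05 * width - 0.03 * width * np.sin(4 * np.pi * t), ymin + t * height]
    elif axis_spec == "south":
        pts = np.c_[xmin + t * width, ymin + 0.05 * height + 0.03 * height * np.sin(4 * np.pi * t)]
    elif axis_spec == "north":
        pts = np.c_[xmin + t * width, ymax - 0.05 * height - 0.03 * height * np.sin(4 * np.pi * t)]
    else:
        raise ValueError(f"unknown channel axis spec: {axis_spec!r}")
    return LineString(pts)


def generate_landscape(
    n_rows: int,
    n_cols: int,
    pixel_size: float = 50.0,
    channel_axis_spec="west",
    seed: int = 0,
    boundary: np.ndarray | None = None,
    grassland_fraction: float = 0.12,
) -> HabitatRaster:
    """Generate a banded habitat raster around a permanent water channel.

    Habitat bands are ordered by distance to the channel — secondary
    floodplain nearest, then tertiary floodplain, riparian woodland,
    mopane woodland and mixed acacia woodland farthest — with grassland
    patches interspersed throughout, mirroring the layout of a
    flood-pulsed delta margin.
    """
    if n_rows < 10 or n_cols < 10:
        raise ValueError("n_rows and n_cols must be at least 10")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rng = np.random.default_rng(seed)
    base = HabitatRaster(
        classes=np.ones((n_rows, n_cols), dtype=int),
        pixel_size=pixel_size,
        boundary=boundary,
    )
    channel = _channel_line(base.extent, channel_axis_spec)
    import shapely

    X, Y = base.cell_centres()
    pts = shapely.points(X.ravel(), Y.ravel())
    dist = shapely.distance(pts, channel).reshape(n_rows, n_cols)

    # distance-quantile bands: near-water floodplains grading to dry woodland
    q = np.quantile(dist, [0.10, 0.25, 0.40, 0.75])
    classes = np.full((n_rows, n_cols), 6, dtype=int)
    classes[dist < q[3]] = 5
    classes[dist < q[2]] = 4
    classes[dist < q[1]] = 2
    classes[dist < q[0]] = 1

    # grassland occurs throughout the range as roundish patches
    n_cells = n_rows * n_cols
    target = int(grassland_fraction * n_cells)
    placed = 0
    grass = np.zeros((n_rows, n_cols), dtype=bool)
    ii, jj = np.mgrid[0:n_rows, 0:n_cols]
    while placed < target:
        ci = rng.integers(0, n_rows)
        cj = rng.integers(0, n_cols)
        r = rng.uniform(2.0, max(3.0, 0.05 * min(n_rows, n_cols)))
        blob = (ii - ci) ** 2 + (jj - cj) ** 2 <= r**2
        grass |= blob
        placed = int(grass.sum())
    classes[grass] = 3

    return HabitatRaster(
        classes=classes,
        pixel_size=pixel_size,
        dist_water=dist,
        boundary=boundary,
        meta={"channel": np.asarray(channel.coords), "seed": seed},
    )


def apply_flood(
    raster: HabitatRaster, flood_level: float, reach_cells: float = 12.0
) -> tuple[HabitatRaster, dict[int, float]]:
    """Flag inundated cells and derive per-class biomass multipliers.

    The inundation front advances linearly with ``flood_level`` up to
    ``reach_cells`` pixels from the channel.  Biomass in the two
    seasonally-flooded classes scales as ``1 - 0.8 * flood_level``;
    dry-habitat multipliers stay at 1.
    """
    if not 0.0 <= flood_level <= 1.0:
        raise ValueError("flood_level must be in [0, 1]")
    if raster.dist_water is None:
        raise ValueError("raster has no distance-to-water grid")
    reach = flood_level * reach_cells * raster.pixel_size
    inundated = raster.dist_water <= reach if flood_level > 0 else np.zeros_like(
        raster.dist_water, dtype=bool
    )
    multipliers = {
        code: (1.0 - 0.8 * flood_level) if code in SEASONALLY_FLOODED else 1.0
        for code in HABITAT_NAMES.values()
    }
    flooded = HabitatRaster(
        classes=raster.classes,
        origin_x=raster.origin_x,
        origin_y=raster.origin_y,
        pixel_size=raster.pixel_size,
        dist_water=raster.dist_water,
        boundary=raster.boundary,
        inundated=inundated,
        meta={**raster.meta, "flood_level": flood_level},
    )
    return flooded, multipliers


# --------------------------------------------------------------------------
# Trajectories
# --------------------------------------------------------------------------

_N_HEADINGS = 16
_HEADINGS = np.arange(_N_HEADINGS) * (2 * np.pi / _N_HEADINGS)


def _angle_weight(turn_deg: np.ndarray, mean: float, sd: float) -> np.ndarray:
    # folded-normal density of the absolute turning angle
    return norm.pdf(turn_deg, mean, sd) + norm.pdf(-turn_deg, mean, sd)


def simulate_trajectory(
    raster: HabitatRaster,
    spec: MovementStateSpec,
    habitat_preference_weights: dict[int, float] | None = None,
    n_hours: int = 24 * 30,
    start: tuple[float, float] | None = None,
    seed: int = 0,
    animal_id: str = "S1",
    start_time: str = "2008-08-15T00:00:00",
    dropout: float = 0.0,
) -> pd.DataFrame:
    """Simulate an hourly GPS trajectory with latent movement states.

    Each hour a state is drawn from the transition matrix; a step length
    (gamma, moment-matched) and candidate headings follow.  Headings are a
    weighted choice over 16 compass directions, weighted by the state's
    folded-normal turning-angle density and the preference weight of the
    habitat at the candidate endpoint; candidates leaving the raster or
    crossing the boundary polyline get zero weight, which reflects the
    walk back inside.

    Returns a DataFrame with columns ``animal_id, timestamp, x, y, state``.
    """
    if n_hours < 24:
        raise ValueError("n_hours must be at least 24")
    prefs = dict.fromkeys(HABITAT_NAMES.values(), 1.0)
    if habitat_preference_weights:
        bad = [c for c, w in habitat_preference_weights.items() if w <= 0]
        if bad:
            raise ValueError(f"preference weights must be positive, got {bad}")
        prefs.update(habitat_preference_weights)
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = raster.extent
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
    x, y = start if start is not None else (cx, cy)
    if not raster.contains(x, y):
        raise ValueError("start position outside raster")
    boundary = raster.boundary_line()

    shapes = {s: (spec.step_mean[s] / spec.step_sd[s]) ** 2 for s in STATES}
    scales = {s: spec.step_sd[s] ** 2 / spec.step_mean[s] for s in STATES}
    state_idx = int(rng.choice(4, p=spec.stationary()))
    heading = rng.uniform(0, 2 * np.pi)

    xs = np.empty(n_hours)
    ys = np.empty(n_hours)
    labels = np.empty(n_hours, dtype=object)
    xs[0], ys[0] = x, y
    labels[0] = STATES[state_idx]

    for t in range(1, n_hours):
        state_idx = int(rng.choice(4, p=spec.transition[state_idx]))
        state = STATES[state_idx]
        L = rng.gamma(shapes[state], scales[state])
        # random rotation of the candidate fan avoids a 22.5-degree lattice
        # in the realised turning angles
        headings = _HEADINGS + rng.uniform(0, 2 * np.pi / _N_HEADINGS)
        ex = x + L * np.cos(headings)
        ey = y + L * np.sin(headings)
        turn = np.degrees(
            np.abs(((headings - heading) + np.pi) % (2 * np.pi) - np.pi)
        )
        if state == "rest":
            w = np.ones(_N_HEADINGS)
        else:
            w = _angle_weight(turn, spec.angle_mean[state], spec.angle_sd[state])
        codes = raster.class_at(ex, ey)
        hab_w = np.array(
            [prefs.get(c, 0.0) if c in HABITAT_NAMES.values() else 0.0 for c in codes]
        )
        w = w * hab_w
        if boundary is not None and w.sum() > 0:
            for k in np.flatnonzero(w):
                if LineString([(x, y), (ex[k], ey[k])]).intersects(boundary):
                    w[k] = 0.0
        if w.sum() <= 0:
            # trapped near an edge: step back toward the raster centre
            d = np.hypot(cx - x, cy - y)
            frac = min(L, 0.5 * d) / d if d > 0 else 0.0
            x, y = x + frac * (cx - x), y + frac * (cy - y)
        else:
            k = int(rng.choice(_N_HEADINGS, p=w / w.sum()))
            x, y, heading = ex[k], ey[k], headings[k]
        xs[t], ys[t] = x, y
        labels[t] = state

    traj = pd.DataFrame(
        {
            "animal_id": animal_id,
            "timestamp": pd.date_range(start_time, periods=n_hours, freq="h"),
            "x": xs,
            "y": ys,
            "state": labels,
        }
    )
    if dropout > 0:
        keep = rng.uniform(size=n_hours) >= dropout
        keep[0] = True
        traj = traj.loc[keep].reset_index(drop=True)
    return traj


# --------------------------------------------------------------------------
# Collar calibration fixes
# --------------------------------------------------------------------------


@dataclass
class CalibrationSet:
    """Stationary-test fixes for one collar."""

    collar_id: str
    true_xy: tuple[float, float] | None
    fixes: np.ndarray  # (n, 2) metres

    def __post_init__(self) -> None:
        self.fixes = np.asarray(self.fixes, dtype=float)
        if self.fixes.ndim != 2 or self.fixes.shape[1] != 2:
            raise ValueError("fixes must be an (n, 2) array")
        if not np.isfinite(self.fixes).all():
            raise ValueError("fixes must be finite")
        if len(self.fixes) < 100:
            import warnings

            warnings.warn(
                f"calibration set {self.collar_id} has {len(self.fixes)} < 100 fixes",
                stacklevel=2,
            )


def simulate_calibration_fixes(
    true_xy: tuple[float, float],
    error_sd_m: float,
    n: int = 120,
    seed: int = 0,
    collar_id: str = "C1",
) -> CalibrationSet:
    """Fixes around a known position with isotropic Gaussian error per axis."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if error_sd_m < 0:
        raise ValueError("error_sd_m must be non-negative")
    rng = np.random.default_rng(seed)
    fixes = np.asarray(true_xy, dtype=float) + rng.normal(0, error_sd_m, size=(n, 2))
    return CalibrationSet(collar_id=collar_id, true_xy=tuple(true_xy), fixes=fixes)


# --------------------------------------------------------------------------
# Field records
# --------------------------------------------------------------------------

#: Zero-flood herbaceous biomass by habitat code, kg/ha (dry season baseline).
BASELINE_BIOMASS = {1: 4000.0, 2: 3400.0, 3: 2800.0, 4: 2300.0, 5: 1800.0, 6: 1500.0}

BCS_CATEGORIES = ("adult_male", "adult_female", "subadult", "young")

#: Habitats sampled for biomass (the four most used in the late flood season).
BIOMASS_HABITATS = (1, 2, 3, 4)


@dataclass
class DemographyParams:
    p_calf: dict[int, float] = field(default_factory=lambda: {2008: 0.20, 2009: 0.15})
    p_young: dict[int, float] = field(default_factory=lambda: {2008: 0.48, 2009: 0.53})
    p_adult_male: dict[int, float] = field(
        default_factory=lambda: {2008: 0.30, 2009: 0.27}
    )
    mean_adult_females: float = 30.0
    mean_subadults: float = 10.0


@dataclass
class BCSParams:
    cutpoints: tuple[float, ...] = (-3.0, -1.0, 1.0, 3.0)
    category_effects: dict[str, float] = field(
        default_factory=lambda: {
            "adult_male": 0.0,
            "adult_female": -0.4,
            "subadult": 0.3,
            "young": 0.6,
        }
    )
    year_effect: float = 0.5  # shift in 2009 on the latent scale
    herd_sd: float = 0.3


@dataclass
class FieldRecords:
    """Field tables: DPM drops, quadrat weights, herd demography, BCS counts."""

    dpm: pd.DataFrame  # site_id, habitat, year, height_1..height_50 (cm)
    quadrats: pd.DataFrame  # site_id, habitat, year, w1..w4 (g dry weight)
    herds: pd.DataFrame  # herd_id, year, adult_male, adult_female, subadult, young, calf
    bcs: pd.DataFrame  # herd_id, year, category, bcs_1..bcs_5 counts


def simulate_field_records(
    raster: HabitatRaster,
    flood_levels_by_year: dict[int, float],
    demography_params: DemographyParams | None = None,
    bcs_params: BCSParams | None = None,
    n_herds: dict[int, int] | int = 18,
    n_sites_per_habitat: dict[int, dict[int, int]] | int = 30,
    seed: int = 0,
    dpm_height_cv: float = 0.35,
) -> FieldRecords:
    """Generate biomass, demography and body-condition field tables.

    DPM settling heights are drawn around the habitat-year true biomass via
    the inverse of the disc-pasture-meter calibration; quadrat dry weights
    are produced for flooded floodplain sites; calf and young counts are
    binomial per herd with year-dependent probabilities; BCS counts follow
    a cumulative-logit model with category and year effects and a
    herd-level random intercept.
    """
    demo = demography_params or DemographyParams()
    bcs_p = bcs_params or BCSParams()
    for p in list(demo.p_calf.values()) + list(demo.p_young.values()) + list(
        demo.p_adult_male.values()
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError("demography probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)

    dpm_rows, quad_rows = [], []
    site_counter = 0
    for year, level in flood_levels_by_year.items():
        _, mult = apply_flood(raster, level)
        if isinstance(n_sites_per_habitat, dict):
            counts = n_sites_per_habitat[year]
        else:
            counts = dict.fromkeys(BIOMASS_HABITATS, n_sites_per_habitat)
        for hab in BIOMASS_HABITATS:
            true_b = BASELINE_BIOMASS[hab] * mult[hab]
            true_x = ((true_b - DPM_INTERCEPT) / DPM_SLOPE) ** 2
            for _ in range(counts[hab]):
                site_counter += 1
                site_b = max(50.0, true_b * rng.lognormal(0, 0.25))
                site_x = ((site_b - DPM_INTERCEPT) / DPM_SLOPE) ** 2
                flooded_site = hab in SEASONALLY_FLOODED and level >= 0.6
                row = {"site_id": f"S{site_counter:04d}", "habitat": hab, "year": year}
                if flooded_site:
                    # grass cut from 4 quadrats (0.25 m2 each) at inundated sites
                    per_quad = site_b / 10.0 / 4.0  # g per quadrat
                    ws = rng.gamma(6.0, per_quad / 6.0, size=4)
                    quad_rows.append(
                        {**row, **{f"w{i+1}": ws[i] for i in range(4)}}
                    )
                else:
                    shape = 1.0 / dpm_height_cv**2
                    heights = rng.gamma(shape, site_x / shape, size=50)
                    dpm_rows.append(
                        {**row, **{f"height_{i+1}": heights[i] for i in range(50)}}
                    )
    dpm = pd.DataFrame(dpm_rows)
    quadrats = pd.DataFrame(quad_rows)

    herd_rows, bcs_rows = [], []
    herd_counter = 0
    for year in flood_levels_by_year:
        n_h = n_herds[year] if isinstance(n_herds, dict) else n_herds
        for _ in range(n_h):
            herd_counter += 1
            hid = f"H{herd_counter:03d}"
            n_af = int(rng.poisson(demo.mean_adult_females)) + 5
            n_am = int(rng.binomial(n_af, demo.p_adult_male.get(year, 0.3)))
            n_sub = int(rng.poisson(demo.mean_subadults))
            n_young = int(rng.binomial(n_af, demo.p_young.get(year, 0.5)))
            n_calf = int(rng.binomial(n_af, demo.p_calf.get(year, 0.2)))
            n_calf = min(n_calf, n_young) if n_young > 0 else n_calf
            herd_rows.append(
                {
                    "herd_id": hid,
                    "year": year,
                    "adult_male": n_am,
                    "adult_female": n_af,
                    "subadult": n_sub,
                    "young": n_young,
                    "calf": n_calf,
                }
            )
            b_h = rng.normal(0, bcs_p.herd_sd)
            year_shift = bcs_p.year_effect if year != min(flood_levels_by_year) else 0.0
            sizes = {
                "adult_male": n_am,
                "adult_female": n_af,
                "subadult": n_sub,
                "young": n_young,
            }
            for cat in BCS_CATEGORIES:
                eta = bcs_p.category_effects[cat] + year_shift + b_h
                cum = expit(np.asarray(bcs_p.cutpoints) - eta)
                probs = np.diff(np.r_[0.0, cum, 1.0])
                counts5 = rng.multinomial(sizes[cat], probs)
                bcs_rows.append(
                    {
                        "herd_id": hid,
                        "year": year,
                        "category": cat,
                        **{f"bcs_{k+1}": int(counts5[k]) for k in range(5)},
                    }
                )
    herds = pd.DataFrame(herd_rows)
    bcs = pd.DataFrame(bcs_rows)
    return FieldRecords(dpm=dpm, quadrats=quadrats, herds=herds, bcs=bcs)
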