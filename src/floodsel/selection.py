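"""Design-III habitat selection: ratios, chi-square tests and MANOVA.

A selection ratio w = (proportion of use) / (proportion of availability)
is computed per habitat; w > 1 indicates selection and w < 1 avoidance,
significant when the 95% confidence interval excludes 1.  Second-order
selection compares an individual's MCP composition to the population
range; third-order compares UD-weighted use to the individual MCP.  Both
are design III: use and availability measured per individual.

Group tables (one CI per habitat over animals) use the between-animal
sample SE of w; single-animal count-based tables use the binomial
variance o(1-o)/(n pi^2).  An overall log-likelihood chi-square tests
use-vs-availability across animals, and ratio matrices are compared
between seasons or years by a Pillai-trace MANOVA with Mahalanobis
outlier screening and per-habitat follow-up ANOVAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon

from .raster import HabitatRaster


# --------------------------------------------------------------------------
# Availability and use
# --------------------------------------------------------------------------


def availability(raster: HabitatRaster, polygon: Polygon) -> dict[int, float]:
    """Habitat composition of a polygon by cell-centre inclusion.

    Cells whose centre falls inside (or on) the polygon are counted per
    class; habitats absent from the polygon are simply not in the result.
    """
    X, Y = raster.cell_centres()
    pts = shapely.points(X.ravel(), Y.ravel())
    inside = shapely.covers(polygon, pts).reshape(raster.classes.shape)
    inside &= raster.classes != raster.nodata
    if not inside.any():
        raise ValueError("polygon covers no valid raster cells")
    return raster.class_proportions(mask=inside)


def second_order_inputs(
    individual_mcp: Polygon, population_mcp: Polygon, raster: HabitatRaster
) -> tuple[dict[int, float], dict[int, float]]:
    """(use, availability) for second-order selection.

    Use is the habitat composition of the individual MCP; availability is
    the composition of the population MCP for the same season-year.
    """
    return availability(raster, individual_mcp), availability(raster, population_mcp)


# --------------------------------------------------------------------------
# Selection ratios
# --------------------------------------------------------------------------


def _align(o: dict, pi: dict) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Common habitat set with pi > 0; use on an unavailable habitat is an error."""
    impossible = [h for h, v in o.items() if v > 0 and pi.get(h, 0.0) == 0.0]
    if impossible:
        raise ValueError(f"use recorded in unavailable habitats: {impossible}")
    habs = sorted(h for h in pi if pi[h] > 0)
    ov = np.array([o.get(h, 0.0) for h in habs], dtype=float)
    pv = np.array([pi[h] for h in habs], dtype=float)
    return habs, ov / ov.sum(), pv / pv.sum()


def selection_ratios(
    o: dict[int, float],
    pi: dict[int, float],
    n_fixes: int | None = None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Single-animal selection-ratio table.

    ``n_fixes`` enables the count-based binomial SE o(1-o)/(n pi^2);
    without it, ratios are reported with no CI (continuous masses admit
    no per-animal variance).  The CI is the normal approximation
    w +/- z * SE, Bonferroni-adjusted across habitats on request.
    """
    habs, ov, pv = _align(o, pi)
    w = ov / pv
    k = len(habs)
    z = stats.norm.ppf(1 - (alpha / (2 * k) if bonferroni else alpha / 2))
    if n_fixes is not None:
        se = np.sqrt(ov * (1 - ov) / (n_fixes * pv**2))
    else:
        se = np.full(k, np.nan)
    lo, hi = w - z * se, w + z * se
    sig = (lo > 1.0) | (hi < 1.0)
    return pd.DataFrame(
        {
            "habitat": habs, "use": ov, "availability": pv, "w": w, "se": se,
            "ci_low": lo, "ci_high": hi, "significant": np.where(
                np.isnan(se), False, sig
            ),
            "direction": np.where(w > 1, "selection", np.where(w < 1, "avoidance", "none")),
        }
    )


def group_selection_ratios(
    tables: list[pd.DataFrame], alpha: float = 0.05, bonferroni: bool = False
) -> pd.DataFrame:
    """Season-level ratio table over animals (one CI per habitat).

    ``tables`` are per-animal outputs of :func:`selection_ratios`.  The
    ratio is the across-animal mean of w and its SE the between-animal
    sample SE; habitats missing for an animal are excluded from that
    animal's contribution (design III df bookkeeping happens in the
    chi-square test, not here).
    """
    stacked = pd.concat(
        [t[["habitat", "w"]] for t in tables], keys=range(len(tables)),
        names=["animal", None],
    ).reset_index(level="animal")
    rows = []
    for hab, grp in stacked.groupby("habitat"):
        wbar = grp["w"].mean()
        n = len(grp)
        se = grp["w"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        k = stacked["habitat"].nunique()
        z = stats.norm.ppf(1 - (alpha / (2 * k) if bonferroni else alpha / 2))
        lo, hi = wbar - z * se, wbar + z * se
        rows.append(
            {
                "habitat": hab, "w": wbar, "se": se, "n_animals": n,
                "ci_low": lo, "ci_high": hi,
                "significant": bool((lo > 1) or (hi < 1)) if np.isfinite(se) else False,
                "direction": "selection" if wbar > 1 else (
                    "avoidance" if wbar < 1 else "none"
                ),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Overall chi-square
# --------------------------------------------------------------------------


def overall_chi2(
    use_counts: list[dict[int, float]], availabilities: list[dict[int, float]]
) -> tuple[float, int, float]:
    """Log-likelihood chi-square of use vs availability across animals.

    X2 = 2 sum_a sum_h u_ah ln(u_ah / (n_a pi_ah)) with 0 ln 0 := 0;
    df = sum_a (I_a - 1) where I_a counts habitats available to animal a
    (habitats absent from an individual's range reduce its df).
    """
    if not use_counts or len(use_counts) != len(availabilities):
        raise ValueError("need matching non-empty use and availability lists")
    x2 = 0.0
    df = 0
    for u, pi in zip(use_counts, availabilities):
        habs = [h for h in pi if pi[h] > 0]
        n_a = sum(u.get(h, 0.0) for h in habs)
        for h in habs:
            u_ah = u.get(h, 0.0)
            if u_ah > 0:
                x2 += 2.0 * u_ah * np.log(u_ah / (n_a * pi[h]))
        df += len(habs) - 1
    return float(x2), int(df), float(stats.chi2.sf(x2, df))


# --------------------------------------------------------------------------
# MANOVA (Pillai's trace) with follow-up ANOVAs
# --------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    """One-way MANOVA comparison of ratio (or ilr) matrices between groups."""

    contrast: str
    pillai: float
    F: float
    df: tuple[float, float]
    p: float
    per_variable: pd.DataFrame  # variable, F, df1, df2, p
    mahalanobis: np.ndarray = field(default=None)


def pillai_trace(groups: list[np.ndarray]) -> tuple[float, float, tuple[float, float], float]:
    """Pillai's trace V and its standard F approximation for a one-way design.

    V = tr[H (H + E)^-1] from the between (H) and within (E) cross-product
    matrices.  Robust to departures from multivariate normality, which is
    why it is the default statistic here.
    """
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 groups")
    X = np.vstack(groups)
    N, p_dim = X.shape
    grand = X.mean(axis=0)
    H = np.zeros((p_dim, p_dim))
    E = np.zeros((p_dim, p_dim))
    for grp in groups:
        mean_g = grp.mean(axis=0)
        d = (mean_g - grand)[:, None]
        H += len(grp) * (d @ d.T)
        C = grp - mean_g
        E += C.T @ C
    try:
        V = float(np.trace(H @ np.linalg.inv(H + E)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular within-group covariance; drop collinear "
                         "variables") from exc
    s = min(p_dim, g - 1)
    m = (abs(p_dim - g + 1) - 1) / 2.0
    n_ = (N - g - p_dim - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_ + s + 1)
    if df2 <= 0 or V >= s:
        raise ValueError("too few observations for the Pillai F approximation")
    F = (df2 / df1) * (V / s) / (1 - V / s)
    p_val = float(stats.f.sf(F, df1, df2))
    return V, float(F), (float(df1), float(df2)), p_val


def mahalanobis_distances(groups: list[np.ndarray]) -> np.ndarray:
    """Distance of each observation from its group centroid, pooled covariance."""
    X = np.vstack(groups)
    N, p_dim = X.shape
    g = len(groups)
    E = np.zeros((p_dim, p_dim))
    for grp in groups:
        C = grp - grp.mean(axis=0)
        E += C.T @ C
    S = E / (N - g)
    Sinv = np.linalg.pinv(S)
    out = []
    for grp in groups:
        d = grp - grp.mean(axis=0)
        out.append(np.sqrt(np.einsum("ij,jk,ik->i", d, Sinv, d)))
    return np.concatenate(out)


def compare_groups(
    matrix: pd.DataFrame, grouping: pd.Series | np.ndarray, contrast: str = ""
) -> ComparisonResult:
    """Pillai MANOVA plus per-variable ANOVAs on a ratio matrix.

    Rows are animal-seasons, columns habitats (or ilr coordinates);
    ``grouping`` assigns each row to a season/year group.  Columns with
    any missing value are dropped listwise.
    """
    grouping = np.asarray(grouping)
    mat = matrix.dropna(axis=1)
    levels = pd.unique(grouping)
    groups = [mat.loc[grouping == lev].to_numpy(dtype=float) for lev in levels]
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    N, p_dim = mat.shape
    if N - len(levels) <= p_dim:
        raise ValueError(
            f"need more observations ({N}) than variables ({p_dim}) plus groups"
        )
    V, F, dfs, p_val = pillai_trace(groups)
    rows = []
    for col in mat.columns:
        samples = [mat.loc[grouping == lev, col].to_numpy(dtype=float)
                   for lev in levels]
        f, pv = stats.f_oneway(*samples)
        rows.append({"variable": col, "F": float(f),
                     "df1": len(levels) - 1, "df2": N - len(levels), "p": float(pv)})
    return ComparisonResult(
        contrast=contrast, pillai=V, F=F, df=dfs, p=p_val,
        per_variable=pd.DataFrame(rows),
        mahalanobis=mahalanobis_distances(groups),
    )
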