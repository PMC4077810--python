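"""Movement-state segmentation, time budgets and daily distance.

Hourly steps split into resting (displacement <= MDT) and active fixes;
active fixes are clustered on (step length, turning angle) by k-means
into three states operating at increasing spatial scale — grazing within
a patch, walking between patches, relocating between ranges.  Per-animal
time budgets over the four behaviours are compositional data and are
compared between groups after an isometric log-ratio transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.composition import ilr, ilr_inv, multi_replace
from sklearn.cluster import KMeans

from .selection import ComparisonResult, compare_groups

ACTIVE_STATES = ("graze", "walk", "relocate")
ALL_STATES = ("rest",) + ACTIVE_STATES


def step_metrics(traj: pd.DataFrame) -> pd.DataFrame:
    """Step lengths (m) and absolute turning angles (deg) per fix.

    The angle at step i is the absolute angle between displacement
    vectors i-1 -> i and i -> i+1... reported against the *arriving* fix,
    so the first step has no angle.  Zero-length displacements yield NaN
    angles (heading undefined).
    """
    ts = pd.to_datetime(traj["timestamp"]).to_numpy()
    if len(np.unique(ts)) != len(ts):
        raise ValueError("duplicate timestamps")
    x = traj["x"].to_numpy(dtype=float)
    y = traj["y"].to_numpy(dtype=float)
    dx, dy = np.diff(x), np.diff(y)
    dist = np.hypot(dx, dy)
    heading = np.arctan2(dy, dx)
    turn = np.full(len(dist), np.nan)
    if len(dist) >= 2:
        dh = np.diff(heading)
        turn[1:] = np.degrees(np.abs((dh + np.pi) % (2 * np.pi) - np.pi))
        turn[1:][(dist[1:] == 0) | (dist[:-1] == 0)] = np.nan
    dt_h = np.diff(ts).astype("timedelta64[s]").astype(float) / 3600.0
    return pd.DataFrame(
        {"end_index": np.arange(1, len(x)), "dt_h": dt_h,
         "distance_m": dist, "turning_angle_deg": turn}
    )


@dataclass
class StateLabeling:
    """Per-fix behaviour labels plus per-cluster summaries."""

    labels: pd.Series  # aligned to step end fixes: rest/graze/walk/relocate
    cluster_summary: pd.DataFrame  # state, n, dist mean/sd, angle mean/sd
    inertia: float


def kmeans_states(
    active_steps: pd.DataFrame,
    k: int = 3,
    n_restarts: int = 20,
    seed: int = 0,
    standardise: bool = False,
) -> StateLabeling:
    """Cluster active steps on (distance, turning angle) into k movement states.

    Clustering is on raw features by default: the states are defined by
    the spatial scale of movement, and step length carries essentially
    all of that signal, while turning angles are broad and weakly
    informative for every state.  Z-scoring (``standardise=True``) gives
    the angle dimension equal weight and lets k-means carve clusters on
    angle noise instead of movement scale.  Clusters are relabelled
    graze < walk < relocate by ascending mean raw distance, so the
    output does not depend on k-means' internal cluster order.
    """
    feats = active_steps[["distance_m", "turning_angle_deg"]].dropna()
    if len(feats) < k * 10:
        raise ValueError(f"need at least {k * 10} active steps with angles")
    X = feats.to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate features: no variation to cluster")
    Z = (X - X.mean(axis=0)) / X.std(axis=0) if standardise else X
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(Z)
    order = np.argsort(
        [X[km.labels_ == c, 0].mean() for c in range(k)]
    )
    name_of = {c: ACTIVE_STATES[rank] for rank, c in enumerate(order)}
    names = pd.Series(
        [name_of[c] for c in km.labels_], index=feats.index, name="state"
    )
    rows = []
    for state in ACTIVE_STATES[:k]:
        sub = X[names.to_numpy() == state]
        rows.append(
            {
                "state": state, "n": len(sub),
                "dist_mean": sub[:, 0].mean(), "dist_sd": sub[:, 0].std(ddof=1),
                "angle_mean": sub[:, 1].mean(), "angle_sd": sub[:, 1].std(ddof=1),
            }
        )
    return StateLabeling(
        labels=names, cluster_summary=pd.DataFrame(rows),
        inertia=float(km.inertia_),
    )


def label_trajectory(
    traj: pd.DataFrame, mdt: float, k: int = 3, n_restarts: int = 20, seed: int = 0
) -> pd.DataFrame:
    """Steps with rest/graze/walk/relocate labels for one trajectory.

    Rest classification (displacement <= MDT) precedes clustering; only
    active fixes enter k-means, as angle structure below the collar-error
    scale is noise.
    """
    steps = step_metrics(traj)
    steps["behaviour"] = np.where(steps["distance_m"] <= mdt, "rest", None)
    active = steps.loc[steps["behaviour"].isna()]
    lab = kmeans_states(active, k=k, n_restarts=n_restarts, seed=seed)
    steps.loc[lab.labels.index, "behaviour"] = lab.labels
    # active steps without an angle (first step / zero-length neighbour):
    # nearest cluster by distance alone
    missing = steps["behaviour"].isna()
    if missing.any():
        centres = lab.cluster_summary.set_index("state")["dist_mean"]
        for i in steps.index[missing]:
            steps.loc[i, "behaviour"] = (
                (centres - steps.loc[i, "distance_m"]).abs().idxmin()
            )
    return steps


def time_budget(behaviours: pd.Series) -> dict[str, float]:
    """Proportion of fixes in each of the four behaviours (sums to 1)."""
    counts = behaviours.value_counts()
    total = counts.sum()
    return {s: float(counts.get(s, 0)) / total for s in ALL_STATES}


def ilr_budgets(budgets: pd.DataFrame, delta: float | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates of behaviour budgets.

    Zeros are handled by multiplicative replacement with
    delta = 0.65 / (total fixes) by default — ilr is undefined at zero.
    The basis is scikit-bio's fixed Helmert-type contrast, so coordinates
    are comparable across calls.
    """
    comp = budgets[list(ALL_STATES)].to_numpy(dtype=float)
    if (comp == 0).any():
        if delta is None:
            n_fixes = budgets["n_fixes"].to_numpy(dtype=float) if (
                "n_fixes" in budgets
            ) else np.full(len(comp), 1000.0)
            deltas = 0.65 / n_fixes
        else:
            deltas = np.full(len(comp), delta)
        comp = np.vstack(
            [
                multi_replace(row[None, :], delta=d)[0]
                if (row == 0).any()
                else row
                for row, d in zip(comp, deltas)
            ]
        )
    return ilr(comp)


def inverse_ilr(coords: np.ndarray) -> np.ndarray:
    """Back-transform ilr coordinates to compositions (rows sum to 1)."""
    return ilr_inv(np.asarray(coords, dtype=float))


def compositional_compare(
    budgets: pd.DataFrame, grouping, contrast: str = ""
) -> ComparisonResult:
    """MANOVA on ilr-transformed behaviour budgets between groups."""
    coords = ilr_budgets(budgets)
    mat = pd.DataFrame(
        coords, columns=[f"ilr_{i + 1}" for i in range(coords.shape[1])]
    )
    return compare_groups(mat, grouping, contrast=contrast)


def daily_distance(
    traj: pd.DataFrame, utc_offset_h: int = 2, min_fixes: int = 20
) -> pd.DataFrame:
    """Total distance per calendar day (local midnight at ``utc_offset_h``).

    Steps are attributed to the day of their end fix; days with fewer
    than ``min_fixes`` steps are flagged incomplete.
    """
    df = traj.sort_values("timestamp")
    ts = pd.to_datetime(df["timestamp"]) + pd.Timedelta(hours=utc_offset_h)
    dist = np.hypot(df["x"].diff(), df["y"].diff())
    day = ts.dt.date
    out = (
        pd.DataFrame({"day": day.to_numpy()[1:], "step": dist.to_numpy()[1:]})
        .groupby("day")
        .agg(distance_m=("step", "sum"), n_steps=("step", "size"))
        .reset_index()
    )
    out["complete"] = out["n_steps"] >= min_fixes
    return out
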