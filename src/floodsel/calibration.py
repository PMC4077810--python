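"""Collar positional-error calibration.

Before deployment each GPS collar is left stationary and its fixes
recorded.  The mean fix position serves as the reference, and the radius
of the 95% circular error probability — the circle around the reference
containing 95% of the fixes — becomes that collar's minimum distance
threshold (MDT): displacements below it cannot be distinguished from
positional error and are treated as resting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CollarModel:
    collar_id: str
    mdt_m: float
    n_fixes: int
    reference_xy: tuple[float, float]

    def __post_init__(self) -> None:
        if self.mdt_m < 0:
            raise ValueError("MDT must be non-negative")


def reference_position(calib) -> tuple[float, float]:
    """Arithmetic mean of the stationary-test fix coordinates."""
    fixes = np.asarray(calib.fixes, dtype=float)
    if fixes.size == 0:
        raise ValueError("calibration set is empty")
    return float(fixes[:, 0].mean()), float(fixes[:, 1].mean())


def circular_error_radius(calib, coverage: float = 0.95) -> float:
    """Radius of the circle around the reference containing ``coverage`` of fixes.

    The quantile of fix-to-reference distances uses the empirical
    distribution with linear interpolation between order statistics.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    fixes = np.asarray(calib.fixes, dtype=float)
    if len(fixes) < 2:
        raise ValueError("at least 2 calibration fixes required")
    if len(fixes) < 100:
        warnings.warn(
            f"only {len(fixes)} calibration fixes (< 100 recommended)", stacklevel=2
        )
    ref = np.asarray(reference_position(calib))
    dists = np.hypot(*(fixes - ref).T)
    return float(np.quantile(dists, coverage, method="linear"))


def calibrate(calib, coverage: float = 0.95, round_to: float | None = None) -> CollarModel:
    """Full calibration of one collar: reference position and MDT."""
    ref = reference_position(calib)
    mdt = circular_error_radius(calib, coverage)
    if round_to:
        mdt = round_to * round(mdt / round_to)
    return CollarModel(
        collar_id=calib.collar_id, mdt_m=mdt, n_fixes=len(calib.fixes),
        reference_xy=ref,
    )


def summarise_mdt(collar_table: pd.DataFrame, column: str = "mdt_m") -> tuple[float, float]:
    """Mean and sample SD (n-1) of the MDT column over buffalo-season rows."""
    vals = np.asarray(collar_table[column], dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 rows to summarise")
    return float(vals.mean()), float(vals.std(ddof=1))
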