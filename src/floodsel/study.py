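"""Bundled reference tables from the Okavango buffalo collaring study.

These small CSVs carry the published per-collar deployment parameters,
per-animal movement-state summaries, seasonal time budgets and biomass
site counts.  They parameterise the synthetic-data generator and provide
the fixed inputs for the summary statistics the package recomputes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

SEASONS = ("rainy", "early_flood", "late_flood")

#: Collar mass and the mass of the smallest collared cow, kg.
COLLAR_MASS_KG = 1.8
SMALLEST_COW_KG = 450.0

#: Demographic ratio summaries (mean, sd, n herds) by year.
DEMOGRAPHY_SUMMARIES = {
    "young_per_adult_female": {2008: (0.478, 0.183, 18), 2009: (0.535, 0.154, 15)},
    "calf_per_adult_female": {2008: (0.197, 0.130, 18), 2009: (0.156, 0.107, 15)},
    "adult_male_per_adult_female": {2008: (0.434, 0.298, 18), 2009: (0.368, 0.252, 15)},
}


def _load(name: str) -> pd.DataFrame:
    with resources.files("floodsel.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def collar_deployments() -> pd.DataFrame:
    """Per buffalo-season deployment rows: MDT, time threshold, fix count."""
    return _load("collar_deployments.csv")


def movement_state_summaries() -> pd.DataFrame:
    """Per-animal mean/SD of step length and turning angle for the four states."""
    return _load("movement_state_summaries.csv")


def biomass_site_counts() -> pd.DataFrame:
    """Number of biomass sampling sites per habitat and year."""
    return _load("biomass_site_counts.csv")


def time_budgets() -> pd.DataFrame:
    """Mean percentage of time in each behaviour per late-flood year."""
    return _load("time_budgets.csv")


def collar_burden_percent() -> float:
    """Collar mass as a percentage of the smallest collared cow's mass."""
    return 100.0 * COLLAR_MASS_KG / SMALLEST_COW_KG


def pooled_state_parameters() -> dict[str, dict[str, float]]:
    """Across-animal means of the per-state step/angle summaries.

    Returns a mapping ``state -> {step_mean, step_sd, angle_mean, angle_sd}``
    with steps in metres per hour and angles in degrees.
    """
    df = movement_state_summaries()
    out = {}
    for state in ("rest", "graze", "walk", "relocate"):
        out[state] = {
            "step_mean": df[f"dist_{state}_mean"].mean(),
            "step_sd": df[f"dist_{state}_sd"].mean(),
            "angle_mean": df[f"angle_{state}_mean"].mean(),
            "angle_sd": df[f"angle_{state}_sd"].mean(),
        }
    return out
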