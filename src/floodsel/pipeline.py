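"""End-to-end orchestration: simulate -> calibrate -> ranges -> UD -> selection
-> movement states -> field statistics.

A single YAML-able config drives the run; every stage writes plain-text
artefacts (CSV / ESRI ASCII / GeoJSON) into the run directory, and a
manifest records the seed, config, stage outputs and their checksums so
a rerun with the same config is bit-identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, field_stats, home_range, mkde, movement, selection, simulate

DEFAULT_CONFIG = {
    "seed": 0,
    "landscape": {"n_rows": 100, "n_cols": 100, "pixel_size": 50.0,
                  "channel_axis_spec": "west"},
    "animals": 4,
    "n_hours": 24 * 110,
    "start_time": "2008-08-05T00:00:00",
    "preference_weights": {1: 2.0, 2: 2.5, 3: 1.0, 4: 1.2, 5: 0.6, 6: 0.5},
    "collar_error_sd_m": 25.0,
    "coverage": 0.95,
    "trim_days": 14,
    "cap_h": 10.0,
    "n_substeps": 10,
    "alpha": 0.05,
    "bonferroni": False,
    "kmeans_restarts": 20,
    "flood_levels_by_year": {2008: 0.35, 2009: 0.8},
    "n_herds": 18,
    "n_sites_per_habitat": 20,
}


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    import yaml

    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    cfg = _merge(cfg, overrides)
    if not 0.0 < cfg["alpha"] < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return cfg


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Run the full pipeline and return the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "config": {k: str(v) for k, v in config.items()},
                      "stages": {}}

    # 1. landscape -----------------------------------------------------------
    land_cfg = config["landscape"]
    raster = simulate.generate_landscape(seed=seed, **land_cfg)
    raster.write_ascii(out / "landscape.asc")
    manifest["stages"]["landscape"] = {"path": "landscape.asc",
                                       "sha": _sha(out / "landscape.asc")}

    # 2. collar calibration --------------------------------------------------
    collars = []
    for a in range(int(config["animals"])):
        calib = simulate.simulate_calibration_fixes(
            (1000.0, 1000.0), config["collar_error_sd_m"], n=120,
            seed=int(rng.integers(2**31)), collar_id=f"A{a + 1}",
        )
        collars.append(calibration.calibrate(calib, coverage=config["coverage"]))
    collar_df = pd.DataFrame(
        [{"collar_id": c.collar_id, "n": c.n_fixes, "mdt_m": c.mdt_m}
         for c in collars]
    )
    collar_df.to_csv(out / "collars.csv", index=False)
    manifest["stages"]["calibration"] = {"path": "collars.csv",
                                         "sha": _sha(out / "collars.csv")}

    # 3. trajectories --------------------------------------------------------
    spec = simulate.MovementStateSpec.from_study()
    trajs = []
    for a, collar in enumerate(collars):
        traj = simulate.simulate_trajectory(
            raster, spec, config["preference_weights"],
            n_hours=int(config["n_hours"]),
            seed=int(rng.integers(2**31)), animal_id=collar.collar_id,
            start_time=config["start_time"],
        )
        noisy = traj.copy()
        err = np.random.default_rng(seed + 7000 + a).normal(
            0, config["collar_error_sd_m"], size=(len(traj), 2)
        )
        noisy[["x", "y"]] += err
        trajs.append(noisy)
    all_traj = pd.concat(trajs, ignore_index=True)
    all_traj.to_csv(out / "trajectories.csv", index=False)
    manifest["stages"]["trajectories"] = {"path": "trajectories.csv",
                                          "sha": _sha(out / "trajectories.csv")}

    # 4. seasonal ranges and UD parameters ----------------------------------
    blocks = home_range.season_split(all_traj, trim_days=int(config["trim_days"]))
    blocks = {k: v for k, v in blocks.items() if len(v) >= 72}
    pop = home_range.population_range(blocks)
    mdt_of = {c.collar_id: c.mdt_m for c in collars}
    rows, uds, second_tables, third_tables = [], {}, [], []
    use_counts, avails = [], []
    for (animal, season, year), block in blocks.items():
        ind = home_range.mcp(block[["x", "y"]].to_numpy(), owner=animal,
                             season=season, year=year)
        med = home_range.median_hourly_distance(block)
        t_max = home_range.time_threshold(ind.diameter_m, med,
                                          cap_h=config["cap_h"])
        params = home_range.RangeParams(
            mdt_m=mdt_of[animal], t_max_h=t_max,
            h_min_m=home_range.smoothing_parameter(mdt_of[animal]),
        )
        steps = mkde.classify_activity(block, params.mdt_m, t_max=params.t_max_h)
        D = mkde.estimate_diffusion(steps)
        udg = mkde.ud(block, raster, params, D,
                      boundary=raster.boundary_line(),
                      n_substeps=int(config["n_substeps"]))
        uds[(animal, season, year)] = udg
        rows.append({"animal": animal, "season": season, "year": year,
                     "n_fixes": len(block), "mdt_m": params.mdt_m,
                     "diameter_m": ind.diameter_m, "t_max_h": t_max,
                     "h_min_m": params.h_min_m, "D_m2_h": D})
        # selection inputs
        o2, pi2 = selection.second_order_inputs(
            ind.polygon, pop[(season, year)].polygon, raster
        )
        second_tables.append(selection.selection_ratios(o2, pi2,
                                                        alpha=config["alpha"]))
        pi3 = selection.availability(raster, ind.polygon)
        o3 = mkde.ud_weighted_use(udg, raster)
        o3 = {h: o3.get(h, 0.0) for h in pi3}
        tot = sum(o3.values())
        o3 = {h: v / tot for h, v in o3.items()}
        third_tables.append(
            selection.selection_ratios(o3, pi3, n_fixes=len(block),
                                       alpha=config["alpha"])
        )
        codes = raster.class_at(block["x"].to_numpy(), block["y"].to_numpy())
        cnt = pd.Series(codes).value_counts().to_dict()
        use_counts.append({h: float(cnt.get(h, 0)) for h in pi3})
        avails.append(pi3)
    pd.DataFrame(rows).to_csv(out / "range_params.csv", index=False)
    manifest["stages"]["ranges"] = {"path": "range_params.csv",
                                    "sha": _sha(out / "range_params.csv")}

    second = selection.group_selection_ratios(second_tables,
                                              alpha=config["alpha"],
                                              bonferroni=config["bonferroni"])
    third = selection.group_selection_ratios(third_tables,
                                             alpha=config["alpha"],
                                             bonferroni=config["bonferroni"])
    second.to_csv(out / "selection_second_order.csv", index=False)
    third.to_csv(out / "selection_third_order.csv", index=False)
    x2, dfree, p = selection.overall_chi2(use_counts, avails)
    (out / "selection_overall.json").write_text(
        json.dumps({"X2": x2, "df": dfree, "p": p})
    )
    manifest["stages"]["selection"] = {
        "paths": ["selection_second_order.csv", "selection_third_order.csv",
                  "selection_overall.json"],
        "sha": _sha(out / "selection_second_order.csv"),
    }

    # 5. movement states -----------------------------------------------------
    budgets = []
    labelled = []
    for (animal, season, year), block in blocks.items():
        steps = movement.label_trajectory(
            block, mdt_of[animal], n_restarts=int(config["kmeans_restarts"]),
            seed=seed,
        )
        steps.insert(0, "animal", animal)
        labelled.append(steps)
        tb = movement.time_budget(steps["behaviour"])
        budgets.append({"animal": animal, "season": season, "year": year,
                        "n_fixes": len(steps), **tb})
    pd.concat(labelled, ignore_index=True).to_csv(out / "behaviours.csv",
                                                  index=False)
    pd.DataFrame(budgets).to_csv(out / "time_budgets.csv", index=False)
    manifest["stages"]["states"] = {"path": "time_budgets.csv",
                                    "sha": _sha(out / "time_budgets.csv")}

    # 6. field records and statistics ---------------------------------------
    records = simulate.simulate_field_records(
        raster, {int(k): float(v) for k, v in
                 config["flood_levels_by_year"].items()},
        n_herds=int(config["n_herds"]),
        n_sites_per_habitat=int(config["n_sites_per_habitat"]),
        seed=seed + 1,
    )
    biomass = field_stats.biomass_table(records)
    biomass.to_csv(out / "biomass.csv", index=False)
    model = field_stats.biomass_year_model(biomass)
    per_herd, summary = field_stats.demographic_ratios(records.herds)
    summary.to_csv(out / "demography_summary.csv", index=False)
    calf_test = field_stats.ratio_year_test(
        records.herds["calf"], records.herds["adult_female"],
        records.herds["year"], family="binomial",
    )
    bcs_model = field_stats.bcs_ordinal_fit(records.bcs)
    (out / "field_stats.json").write_text(json.dumps({
        "biomass_interaction_F": model["interaction_F"],
        "biomass_interaction_p": model["interaction_p"],
        "calf_ratio_effect": calf_test["effect"],
        "calf_ratio_p": calf_test["p"],
        "bcs_year_LR": bcs_model.lr_tests["year"][0],
        "bcs_year_p": bcs_model.lr_tests["year"][2],
    }, indent=2))
    manifest["stages"]["field_stats"] = {"path": "field_stats.json",
                                         "sha": _sha(out / "field_stats.json")}
    manifest["stages"]["biomass"] = {"path": "biomass.csv",
                                     "sha": _sha(out / "biomass.csv")}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
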