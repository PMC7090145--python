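"""End-to-end study orchestration.

``run_study`` chains the whole workflow on synthetic data — render & measure
leaf scenes, simulate & fit growth trajectories, simulate diel traces and
detect CAM onset, simulate stomata and detect inversion, compute physiology
indices and per-day group comparisons — and writes every intermediate
artifact plus a machine-readable study report under one directory.  The
report's headline is the C₃→CAM transition window: [min, max] of the
stomatal-inversion day and the gas-exchange onset day.

Re-running with the same config reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import pandas as pd

from . import __version__
from .diel import (aperture_stats, detect_cam_onset, detect_inversion,
                   phase_summaries)
from .growth import GrowthModel, PRINTED_CONTROL, PRINTED_SALT, compare_groups, \
    fit_control, fit_salt
from .leaf_area import batch_measure
from .physio import index_series
from .stats import NO_CORRECTION_NOTE, comparison_table, daily_comparison
from .synthetic import (DielSimParams, SimConfig, StomataSimParams,
                        render_leaf_scene, simulate_diel_trace,
                        simulate_growth, simulate_physio, simulate_stomata)

__all__ = ["run_study", "validate_config", "ConfigError", "StageError",
           "DEFAULTS"]

logger = logging.getLogger(__name__)

_CSV_FMT = "%.10g"

DEFAULTS: dict = {
    "seed": 42,
    "n_days": 14,
    "samples_per_day": 2880,
    "groups": "control,salt",
    # diel
    "day_peak": 10.5,
    "day_floor": 6.5,
    "night_level": -1.0,
    "noise_sd": 0.3,
    "onset_ramp_start_day": 6,
    "night_zero_day": 8,
    "inversion_spikes_from_day": 9,
    "spike_amplitude": 2.5,
    "onset_threshold": -0.1,
    # stomata
    "inversion_day": 7,
    "open_threshold": 1.4,
    "n_stomata_per_timepoint": 150,
    # growth
    "growth_noise_sd": 0.0,
    "growth_day_min": -21,
    "growth_day_max": 14,
    "divergence_threshold": 0.05,
    # scenes
    "scene_px_per_cm": 40,
    # physio / stats
    "rwc_formula": "printed",
    "ttest_variant": "pooled",
}

_INT_KEYS = {"seed", "n_days", "samples_per_day", "onset_ramp_start_day",
             "night_zero_day", "inversion_spikes_from_day", "inversion_day",
             "n_stomata_per_timepoint", "growth_day_min", "growth_day_max",
             "scene_px_per_cm"}
_FLOAT_KEYS = {"day_peak", "day_floor", "night_level", "noise_sd",
               "spike_amplitude", "onset_threshold", "open_threshold",
               "growth_noise_sd", "divergence_threshold"}


class ConfigError(ValueError):
    """Configuration is invalid; message lists every problem found."""


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage."""


def validate_config(config: dict | None) -> tuple[dict, list[str]]:
    """Fill defaults, coerce types and check cross-key consistency.

    Returns (normalized config, warnings).  Unknown keys produce warnings,
    contradictions raise ``ConfigError`` naming every offending key.
    """
    config = dict(config or {})
    warnings: list[str] = []
    errors: list[str] = []
    out = dict(DEFAULTS)
    for key, val in config.items():
        if key not in DEFAULTS:
            warnings.append(f"unknown config key {key!r} ignored")
            continue
        try:
            if key in _INT_KEYS:
                val = int(val)
            elif key in _FLOAT_KEYS:
                val = float(val)
        except (TypeError, ValueError):
            errors.append(f"{key}: cannot coerce {val!r}")
            continue
        out[key] = val

    groups = [g.strip() for g in str(out["groups"]).split(",") if g.strip()]
    if not set(groups) <= {"control", "salt"}:
        errors.append(f"groups: unknown group in {out['groups']!r}")
    out["groups"] = groups

    if out["inversion_day"] > out["n_days"]:
        errors.append(
            f"inversion_day ({out['inversion_day']}) exceeds n_days ({out['n_days']})"
        )
    if out["onset_ramp_start_day"] >= out["night_zero_day"]:
        errors.append(
            f"onset_ramp_start_day ({out['onset_ramp_start_day']}) must precede "
            f"night_zero_day ({out['night_zero_day']})"
        )
    if out["night_zero_day"] > out["n_days"]:
        errors.append(
            f"night_zero_day ({out['night_zero_day']}) exceeds n_days ({out['n_days']})"
        )
    if out["rwc_formula"] not in ("printed", "standard"):
        errors.append(f"rwc_formula: {out['rwc_formula']!r} not printed|standard")
    if errors:
        raise ConfigError("; ".join(errors))
    for w in warnings:
        logger.warning("%s", w)
    return out, warnings


def load_config_file(path) -> dict:
    """Read a flat key=value config file (``#`` comments, [sections] flattened)."""
    out: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line or (line.startswith("[") and line.endswith("]")):
            continue
        if "=" not in line:
            raise ConfigError(f"cannot parse config line {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = val
    return out


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FMT)


def run_study(config: dict | None = None, out_dir="study_out") -> dict:
    """Run the full synthetic study and return the report dict.

    All artifacts (PNG scenes, CSV tables, JSON fits and the report itself)
    land under ``out_dir``; the report references them by relative path.  Any
    stage failure raises ``StageError`` naming the stage; artifacts written
    up to that point are retained for debugging.
    """
    cfg, _ = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"] % (2 ** 31)
    report: dict = {
        "provenance": {
            "seed": seed,
            "config": {k: v for k, v in cfg.items()},
            "config_hash": _config_hash(cfg),
            "phenokit_version": __version__,
        },
        "artifacts": {},
        "note": NO_CORRECTION_NOTE,
    }
    groups = cfg["groups"]

    stage = "leaf_scenes"
    try:
        scene_dir = out / "scenes"
        scene_dir.mkdir(exist_ok=True)
        scene_specs = [("p1", 1, [1.0]), ("p2", 2, [2.5, 0.7]),
                       ("p3", 3, [4.0, 1.5, 0.8])]
        paths, truths = [], {}
        for i, (plant, day, areas) in enumerate(scene_specs):
            scene = render_leaf_scene(areas, px_per_cm=cfg["scene_px_per_cm"],
                                      seed=seed + 100 + i)
            path = scene_dir / f"{plant}_control_day{day}.png"
            iio.imwrite(path, scene.image)
            paths.append(path)
            truths[path.name] = scene.truth["area_cm2"]
        table = batch_measure(paths)
        table["true_area_cm2"] = [truths[Path(p).name] for p in
                                  (p.name for p in paths)]
        _write_csv(table, out / "leaf_areas.csv")
        report["artifacts"]["leaf_areas"] = "leaf_areas.csv"
        report["leaf_area_max_rel_error"] = float(
            (abs(table["area_cm2"] - table["true_area_cm2"])
             / table["true_area_cm2"]).max()
        )

        stage = "growth"
        control_model = GrowthModel(*PRINTED_CONTROL)
        salt_model = GrowthModel(*PRINTED_CONTROL, *PRINTED_SALT)
        drange = (cfg["growth_day_min"], cfg["growth_day_max"])
        tab_c = simulate_growth(control_model, drange,
                                cfg["growth_noise_sd"], seed + 200)
        fit_c = fit_control(tab_c)
        _write_csv(tab_c, out / "growth_control.csv")
        (out / "growth_fit_control.json").write_text(fit_c.to_json() + "\n")
        report["growth"] = {"control": fit_c.params,
                            "control_rss": fit_c.rss}
        if "salt" in groups:
            tab_s = simulate_growth(salt_model, drange,
                                    cfg["growth_noise_sd"], seed + 201)
            fit_s = fit_salt(tab_s, control_params=(fit_c.model.a1,
                                                    fit_c.model.r1))
            _write_csv(tab_s, out / "growth_salt.csv")
            (out / "growth_fit_salt.json").write_text(fit_s.to_json() + "\n")
            report["growth"]["salt"] = fit_s.params
            report["growth"]["salt_rss"] = fit_s.rss
            report["divergence_day"] = compare_groups(
                fit_c, fit_s, threshold=cfg["divergence_threshold"],
                day_range=(1, cfg["n_days"]))
        else:
            report["divergence_day"] = None
        report["artifacts"]["growth"] = ["growth_control.csv",
                                         "growth_fit_control.json"]

        stage = "diel"
        diel_params = DielSimParams(
            day_peak=cfg["day_peak"], day_floor=cfg["day_floor"],
            night_level=cfg["night_level"], noise_sd=cfg["noise_sd"],
            onset_ramp_start_day=cfg["onset_ramp_start_day"],
            night_zero_day=cfg["night_zero_day"],
            inversion_spikes_from_day=cfg["inversion_spikes_from_day"],
            spike_amplitude=cfg["spike_amplitude"])
        onset = {}
        for group in groups:
            gseed = seed if group == "salt" else seed + 1
            sim = SimConfig(seed=gseed, n_days=cfg["n_days"],
                            samples_per_day=cfg["samples_per_day"], group=group)
            trace = simulate_diel_trace(sim, diel_params)
            summaries = phase_summaries(trace)
            rep = detect_cam_onset(summaries, threshold=cfg["onset_threshold"])
            onset[group] = rep.onset_day
            sdf = pd.DataFrame([asdict(s) for s in summaries])
            _write_csv(sdf, out / f"diel_summaries_{group}.csv")
            _write_json(out / f"cam_onset_{group}.json",
                        {"onset_day": rep.onset_day,
                         "threshold": rep.threshold,
                         "nightly_means": {str(k): v for k, v in
                                           rep.nightly_means.items()}})
        report["cam_onset_day"] = onset.get("salt")
        report["cam_onset_control"] = onset.get("control")

        stage = "stomata"
        st_params = StomataSimParams(
            inversion_day=cfg["inversion_day"],
            n_stomata_per_timepoint=cfg["n_stomata_per_timepoint"])
        inv = {}
        for group in groups:
            gseed = seed + 10 if group == "salt" else seed + 11
            sim = SimConfig(seed=gseed, n_days=cfg["n_days"], group=group)
            table = simulate_stomata(sim, st_params)
            stats_df = aperture_stats(table, open_threshold=cfg["open_threshold"])
            inv[group] = detect_inversion(stats_df)
            _write_csv(stats_df, out / f"stomata_stats_{group}.csv")
        report["stomatal_inversion_day"] = inv.get("salt")
        report["stomatal_inversion_control"] = inv.get("control")

        days = [d for d in (report["cam_onset_day"],
                            report["stomatal_inversion_day"]) if d is not None]
        if days:
            lo, hi = min(days), max(days)
            report["transition_window"] = {"start_day": lo, "end_day": hi,
                                           "length_days": hi - lo + 1}
        else:
            report["transition_window"] = None

        stage = "physio"
        sim = SimConfig(seed=seed + 20, n_days=cfg["n_days"])
        samples = simulate_physio(sim)
        _write_csv(samples, out / "physio_samples.csv")
        indices = index_series(samples, rwc_formula=cfg["rwc_formula"])
        _write_csv(indices, out / "physio_indices.csv")
        report["artifacts"]["physio"] = ["physio_samples.csv",
                                         "physio_indices.csv"]

        stage = "group_stats"
        if set(groups) == {"control", "salt"}:
            comparisons = {}
            for index_name, sub in indices.groupby("index"):
                raw = samples.copy()
                # recompute per-replicate values for the comparison
                from .physio import mda_concentration, mda_per_gram, rwc, succulence
                if index_name == "rwc_pct":
                    raw["value"] = [rwc(r.fw_g, r.dw_g, r.tw_g,
                                        formula=cfg["rwc_formula"])
                                    for r in raw.itertuples()]
                elif index_name == "succulence_g_cm2":
                    raw["value"] = [succulence(r.fw_g, r.area_cm2)
                                    for r in raw.itertuples()]
                else:
                    raw["value"] = [mda_per_gram(
                        mda_concentration(r.od532, r.od450),
                        tissue_mass=r.tissue_g) for r in raw.itertuples()]
                results = daily_comparison(raw[["day", "group", "value"]],
                                           variant=cfg["ttest_variant"])
                ctable = comparison_table(results)
                _write_csv(ctable, out / f"compare_{index_name}.csv")
                comparisons[index_name] = {
                    "starred_days": [int(r.day_index) for r in results
                                     if r.stars],
                    "table": f"compare_{index_name}.csv",
                }
            report["comparisons"] = comparisons
    except Exception as exc:
        if isinstance(exc, StageError):
            raise
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    _write_json(out / "study_report.json", report)
    return report
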