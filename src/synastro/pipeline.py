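"""End-to-end orchestration: simulate -> analyze -> statistics -> report.

A run is described by a plain-text (YAML) config with per-stage
sections; every stochastic step derives its seed from the config seed,
each stage writes CSV/JSON outputs, and a run manifest lists every
output file with a content hash so a completed run is reproducible from
config + manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, ephys_events, fepsp, stats, synthio, tonic

STAGES = ("events", "tonic", "plasticity", "behavior")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _subseed(seed: int, stage: str, group: str, k: int) -> int:
    digest = hashlib.sha256(f"{seed}/{stage}/{group}/{k}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "seed" not in cfg:
        raise ValueError("config must be a mapping with at least a 'seed' key")
    return cfg


def demo_config() -> dict:
    """Small two-group synthetic experiment that runs in well under a
    minute on one CPU."""
    return {
        "seed": 7,
        "stages": ["events", "tonic", "plasticity", "behavior"],
        "events": {
            "n_per_group": 5,
            "duration_s": 60.0,
            "rate_hz": {"control": 0.56, "case": 0.27},
            "amp_mean_pA": {"control": 21.71, "case": 19.65},
            "amp_sd_pA": 1.5,
            "noise_sd_pA": 2.0,
        },
        "tonic": {
            "n_per_group": 5,
            "duration_s": 300.0,
            "shift_pA": {"control": 39.83, "case": 103.8},
            "drug_onset_s": 120.0,
            "settle_tau_s": 20.0,
            "noise_sd_pA": 5.0,
        },
        "plasticity": {
            "n_per_group": 5,
            "early_factor": {"control": 1.70, "case": 1.51},
            "late_factor": {"control": 1.519, "case": 1.23},
            "noise_cv": 0.05,
        },
        "behavior": {
            "n_per_group": 12,
            "offset_sd_units": 0.42,
        },
    }


def _stage_events(cfg: dict, seed: int, out: Path) -> dict:
    rows = []
    for group in cfg["rate_hz"]:
        for k in range(cfg["n_per_group"]):
            s = _subseed(seed, "events", group, k)
            trace, _ = synthio.gen_event_trace(
                duration_s=cfg["duration_s"],
                rate_hz=cfg["rate_hz"][group],
                amp_mean_pA=cfg["amp_mean_pA"][group],
                amp_sd_pA=cfg["amp_sd_pA"],
                noise_sd_pA=cfg["noise_sd_pA"],
                seed=s,
            )
            template = ephys_events.EventTemplate.from_kinetics(
                synthio.EventKinetics(), trace.sampling_rate
            )
            evs = ephys_events.detect_events(
                trace, template, analysis_window_s=cfg["duration_s"]
            )
            st = ephys_events.event_statistics(evs, cfg["duration_s"])
            rows.append(
                {
                    "group": group,
                    "replicate": k,
                    "seed": s,
                    "frequency_hz": st.frequency_hz,
                    "mean_amplitude_pA": st.mean_amplitude_pA,
                    "n_events": st.n_events,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "events_per_cell.csv", index=False)
    groups = list(cfg["rate_hz"])
    decision = stats.two_group(
        df.loc[df.group == groups[0], "frequency_hz"],
        df.loc[df.group == groups[1], "frequency_hz"],
    )
    return {"comparison": "mEPSC frequency", "decision": decision.to_dict()}


def _stage_tonic(cfg: dict, seed: int, out: Path) -> dict:
    rows = []
    for group in cfg["shift_pA"]:
        for k in range(cfg["n_per_group"]):
            s = _subseed(seed, "tonic", group, k)
            trace, _ = synthio.gen_tonic_trace(
                duration_s=cfg["duration_s"],
                baseline_pA=-100.0,
                shift_pA=cfg["shift_pA"][group],
                drug_onset_s=cfg["drug_onset_s"],
                settle_tau_s=cfg["settle_tau_s"],
                noise_sd_pA=cfg["noise_sd_pA"],
                seed=s,
            )
            res = tonic.measure_tonic(trace, cfg["drug_onset_s"])
            rows.append(
                {
                    "group": group,
                    "replicate": k,
                    "seed": s,
                    "tonic_pA": res.tonic_current_pA,
                    "post_window_start_s": res.post_window[0],
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "tonic_per_cell.csv", index=False)
    groups = list(cfg["shift_pA"])
    decision = stats.two_group(
        df.loc[df.group == groups[0], "tonic_pA"],
        df.loc[df.group == groups[1], "tonic_pA"],
    )
    return {"comparison": "tonic GABA current", "decision": decision.to_dict()}


def _stage_plasticity(cfg: dict, seed: int, out: Path) -> dict:
    rows = []
    for group in cfg["early_factor"]:
        for k in range(cfg["n_per_group"]):
            s = _subseed(seed, "plasticity", group, k)
            series, _ = synthio.gen_fepsp_series(
                n_baseline_sweeps=30,
                n_post_sweeps=180,
                early_factor=cfg["early_factor"][group],
                late_factor=cfg["late_factor"][group],
                noise_cv=cfg["noise_cv"],
                seed=s,
            )
            result = fepsp.normalize_series(series)
            win = fepsp.window_summary(result)
            rows.append(
                {
                    "group": group,
                    "replicate": k,
                    "seed": s,
                    "early_0_5": win[(0.0, 5.0)],
                    "late_55_60": win[(55.0, 60.0)],
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "plasticity_windows.csv", index=False)
    groups = list(cfg["early_factor"])
    decision = stats.two_group(
        df.loc[df.group == groups[0], "late_55_60"],
        df.loc[df.group == groups[1], "late_55_60"],
    )
    return {"comparison": "late LTP window (55-60 min)", "decision": decision.to_dict()}


def _stage_behavior(cfg: dict, seed: int, out: Path) -> dict:
    s = _subseed(seed, "behavior", "cohort", 0)
    table = synthio.gen_behavior_table(
        n_per_group=cfg["n_per_group"],
        group_offsets_sd_units=cfg["offset_sd_units"],
        seed=s,
    )
    table.to_csv(out / "behavior_table.csv", index=False)
    specs = [g.spec for g in synthio.default_generation_battery()]
    scores = behavior.emotionality_scores(table, specs, control_group="control")
    emo = scores.emotionality.reset_index()
    emo["group"] = emo["animal_id"].map(scores.group_of)
    emo.to_csv(out / "emotionality_scores.csv", index=False)
    decision = stats.two_group(
        emo.loc[emo.group == "control", "emotionality_z"],
        emo.loc[emo.group == "case", "emotionality_z"],
    )
    return {"comparison": "emotionality z-score", "decision": decision.to_dict()}


_RUNNERS = {
    "events": _stage_events,
    "tonic": _stage_tonic,
    "plasticity": _stage_plasticity,
    "behavior": _stage_behavior,
}


def run_experiment(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the configured stages and write a hashed run manifest.

    Returns the report dict (also written to ``report.json``).  Stage
    failures abort the run with the offending stage named; outputs of
    completed stages are preserved.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config["seed"])
    stages = config.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for st in stages:
        if st not in config:
            raise ValueError(f"stage '{st}' requested but not configured")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=True))

    report = {"seed": seed, "stages": {}}
    for st in stages:
        try:
            report["stages"][st] = _RUNNERS[st](config[st], seed, out)
        except Exception as exc:
            report["stages"][st] = {"error": str(exc)}
            _write_report(report, out)
            raise RuntimeError(f"stage '{st}' failed: {exc}") from exc
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    manifest = {
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        }
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
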