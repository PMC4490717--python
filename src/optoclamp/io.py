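"""Configuration handling and on-disk trial records.

A run is described by a YAML config with ``controller``, ``plant``,
``schedule``, ``timing`` blocks plus ``seed``/``duration`` scalars; unknown
keys are rejected so typos fail loudly.  A completed trial persists as a
directory of delimited text files plus a JSON manifest:

    spikes.csv    time_s,unit_id            (1 us time resolution)
    rate.csv      t_s,f_hz_per_unit,target_hz_per_unit
    control.csv   t_s,u,U_C,U_H
    optical.csv   t_s,blue_mW_mm2,yellow_mW_mm2
    whisker.csv   t_s,angle_deg             (only when present)
    manifest.json seed, timing, resolved controller/plant config, annotations

The manifest makes a record self-describing: a saved record can be re-read
and replayed without the original config file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .controllers import TargetSchedule
from .engine import ConfigurationError, LoopTiming, TrialRecord, make_controller
from .metrics import SpikeEventList
from .plants import (
    DRUG_CONDITIONS,
    DrugCondition,
    NetworkPlant,
    NetworkPlantParams,
    TCUPlant,
    TCUPlantParams,
    apply_drug,
)

__all__ = [
    "load_config", "build_plant", "build_plant_from_snapshot",
    "build_controller_from_config", "build_schedule", "build_timing",
    "save_record", "load_record", "config_hash",
]

_TOP_KEYS = {"controller", "plant", "schedule", "timing", "seed", "duration",
             "pre_pulse", "success_rms"}
_CONTROLLER_KEYS = {"type", "K", "Ti", "Ts", "tau", "delta1", "delta2", "G",
                    "waveform", "i_bound"}
_PLANT_KEYS = ({"kind", "drug"}
               | {f.name for f in dataclasses.fields(NetworkPlantParams)}
               | {f.name for f in dataclasses.fields(TCUPlantParams)})
_SCHEDULE_KEYS = {"target", "segments"}
_TIMING_KEYS = {f.name for f in dataclasses.fields(LoopTiming)}


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {where}; "
            f"allowed: {sorted(allowed)}")


def load_config(path: str | Path) -> dict:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a mapping")
    _reject_unknown(cfg, _TOP_KEYS, "config")
    _reject_unknown(cfg.get("controller", {}), _CONTROLLER_KEYS, "controller block")
    _reject_unknown(cfg.get("plant", {}), _PLANT_KEYS, "plant block")
    _reject_unknown(cfg.get("schedule", {}), _SCHEDULE_KEYS, "schedule block")
    _reject_unknown(cfg.get("timing", {}), _TIMING_KEYS, "timing block")
    return cfg


def build_plant(block: dict, seed: int = 0):
    """Instantiate a plant from its config block."""
    block = dict(block or {})
    kind = block.pop("kind", "network")
    drug = block.pop("drug", None)
    if kind == "network":
        fields = {f.name for f in dataclasses.fields(NetworkPlantParams)}
        params = NetworkPlantParams(**{k: v for k, v in block.items() if k in fields})
        if drug:
            params = apply_drug(params, drug)
        return NetworkPlant(params, seed=seed)
    if kind == "tcu":
        fields = {f.name for f in dataclasses.fields(TCUPlantParams)}
        params = TCUPlantParams(**{k: v for k, v in block.items() if k in fields})
        return TCUPlant(params, seed=seed)
    raise ConfigurationError(f"unknown plant kind: {kind!r}")


def build_plant_from_snapshot(plant_config: dict, seed: int = 0):
    """Rebuild a plant from a record manifest's resolved parameter snapshot."""
    cfg = dict(plant_config)
    if "n_units" in cfg:  # network plant snapshot
        drug = cfg.pop("drug", None)
        params = NetworkPlantParams(
            **{k: v for k, v in cfg.items()
               if k in {f.name for f in dataclasses.fields(NetworkPlantParams)}
               and k != "drug"},
            drug=DrugCondition(**drug) if isinstance(drug, dict)
            else DRUG_CONDITIONS["none"],
        )
        return NetworkPlant(params, seed=seed)
    params = TCUPlantParams(
        **{k: v for k, v in cfg.items()
           if k in {f.name for f in dataclasses.fields(TCUPlantParams)}})
    return TCUPlant(params, seed=seed)


def build_schedule(block: dict | float) -> TargetSchedule:
    if isinstance(block, (int, float)):
        return TargetSchedule.constant(float(block))
    block = dict(block or {})
    if "segments" in block:
        return TargetSchedule(segments=[tuple(s) for s in block["segments"]])
    return TargetSchedule.constant(float(block.get("target", 4.0)))


def build_timing(block: dict) -> LoopTiming:
    return LoopTiming(**(block or {}))


def build_controller_from_config(block: dict):
    block = dict(block or {})
    kind = block.pop("type", "pi")
    return make_controller(kind, **block)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Record persistence
# ---------------------------------------------------------------------------


def _write_csv(path: Path, header: str, columns: list[np.ndarray],
               fmts: list[str]) -> None:
    data = np.column_stack(columns) if columns[0].size else np.empty((0, len(columns)))
    np.savetxt(path, data, fmt=fmts, delimiter=",", header=header, comments="")


def save_record(record: TrialRecord, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = record.spikes
    _write_csv(out / "spikes.csv", "time_s,unit_id",
               [sp.times, sp.units.astype(float)], ["%.6f", "%d"])
    _write_csv(out / "rate.csv", "t_s,f_hz_per_unit,target_hz_per_unit",
               [record.f_times, record.f, record.target],
               ["%.6f", "%.17g", "%.17g"])
    _write_csv(out / "control.csv", "t_s,u,U_C,U_H",
               [record.u_times, record.u, record.U_C, record.U_H],
               ["%.6f", "%.17g", "%.17g", "%.17g"])
    _write_csv(out / "optical.csv", "t_s,blue_mW_mm2,yellow_mW_mm2",
               [record.light_times, record.blue, record.yellow],
               ["%.6f", "%.17g", "%.17g"])
    if record.whisker is not None:
        _write_csv(out / "whisker.csv", "t_s,angle_deg",
                   [record.light_times[: record.whisker.size], record.whisker],
                   ["%.6f", "%.17g"])
    manifest = {
        "seed": record.seed,
        "duration": record.duration,
        "pre_roll": record.pre_roll,
        "n_units": sp.n_units,
        "timing": dataclasses.asdict(record.timing),
        "controller": record.controller_config,
        "plant": record.plant_config,
        "annotations": record.annotations,
        "config_hash": config_hash({"controller": record.controller_config,
                                    "plant": record.plant_config}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _read_csv(path: Path, ncols: int) -> list[np.ndarray]:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.size == 0:
        return [np.array([]) for _ in range(ncols)]
    return [data[:, k] for k in range(ncols)]


def load_record(rec_dir: str | Path) -> TrialRecord:
    rec_dir = Path(rec_dir)
    if not (rec_dir / "manifest.json").exists():
        raise FileNotFoundError(f"no manifest.json in {rec_dir}")
    manifest = json.loads((rec_dir / "manifest.json").read_text())
    times, units = _read_csv(rec_dir / "spikes.csv", 2)
    f_t, f, tgt = _read_csv(rec_dir / "rate.csv", 3)
    u_t, u, uc, uh = _read_csv(rec_dir / "control.csv", 4)
    _, blue, yellow = _read_csv(rec_dir / "optical.csv", 3)
    whisker = None
    if (rec_dir / "whisker.csv").exists():
        _, whisker = _read_csv(rec_dir / "whisker.csv", 2)
    pre_roll = manifest["pre_roll"]
    spikes = SpikeEventList(
        times=times, units=units.astype(int), t_start=-pre_roll,
        t_end=manifest["duration"], n_units=manifest["n_units"])
    return TrialRecord(
        seed=manifest["seed"], duration=manifest["duration"], pre_roll=pre_roll,
        timing=LoopTiming(**manifest["timing"]), spikes=spikes,
        f_times=f_t, f=f, target=tgt,
        u_times=u_t, u=u, U_C=uc, U_H=uh,
        blue=blue, yellow=yellow, whisker=whisker,
        controller_config=manifest["controller"],
        plant_config=manifest["plant"],
        annotations=manifest["annotations"],
    )
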