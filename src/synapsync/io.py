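"""Plain-text serialization: traces, ring tables, scenarios, reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import RingTable
from .synthetic import DriveParams, KernelParams, PairScenario
from .trace import Trace


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    """Two-column CSV: time_ms, current_pA."""
    df = pd.DataFrame({"time_ms": trace.times, "current_pA": trace.samples})
    df.to_csv(path, index=False, float_format="%.6g")


def read_trace_csv(path: str | Path, label: str | None = None) -> Trace:
    df = pd.read_csv(path)
    if not {"time_ms", "current_pA"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_ms, current_pA")
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = float(np.median(np.diff(t)))
    return Trace(df["current_pA"].to_numpy(dtype=float), dt,
                 label=label or Path(path).stem)


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_ring_table(table: RingTable, path: str | Path) -> None:
    """CSV with columns (r_um, n_r, p_shared) plus a YAML metadata sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"r_um": table.r, "n_r": table.n_r, "p_shared": table.p_shared}
    ).to_csv(path, index=False)
    meta = {
        "r0": float(table.r0),
        "gamma": float(table.gamma),
        "delta_r": float(table.delta_r),
        "preparation": table.preparation,
    }
    _meta_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_ring_table(path: str | Path) -> RingTable:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"r_um", "n_r", "p_shared"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns r_um, n_r, p_shared")
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = yaml.safe_load(mp.read_text()) or {}
    return RingTable(
        r=df["r_um"].to_numpy(dtype=float),
        n_r=df["n_r"].to_numpy(dtype=float),
        p_shared=df["p_shared"].to_numpy(dtype=float),
        r0=float(meta.get("r0", 40.0)),
        gamma=float(meta.get("gamma", 32.3)),
        delta_r=float(meta.get("delta_r", 20.0)),
        preparation=str(meta.get("preparation", "slice")),
    )


def scenario_to_dict(scenario: PairScenario) -> dict:
    """Fully explicit plain dict (every field, defaults resolved)."""
    t = scenario.ring_table
    return {
        "ring_table": {
            "r": [float(v) for v in t.r],
            "n_r": [float(v) for v in t.n_r],
            "p_shared": [float(v) for v in t.p_shared],
            "r0": float(t.r0),
            "gamma": float(t.gamma),
            "delta_r": float(t.delta_r),
            "preparation": t.preparation,
        },
        "drive": dataclasses.asdict(scenario.drive),
        "kernel": dataclasses.asdict(scenario.kernel),
        "noise_sd": float(scenario.noise_sd),
        "duration": float(scenario.duration),
        "dt": float(scenario.dt),
        "seed": int(scenario.seed),
        "target_css": None if scenario.target_css is None else float(scenario.target_css),
    }


def scenario_from_dict(d: dict) -> PairScenario:
    kwargs = {}
    if "ring_table" in d:
        kwargs["ring_table"] = RingTable(
            r=np.asarray(d["ring_table"]["r"], dtype=float),
            n_r=np.asarray(d["ring_table"]["n_r"], dtype=float),
            p_shared=np.asarray(d["ring_table"]["p_shared"], dtype=float),
            r0=float(d["ring_table"].get("r0", 40.0)),
            gamma=float(d["ring_table"].get("gamma", 32.3)),
            delta_r=float(d["ring_table"].get("delta_r", 20.0)),
            preparation=str(d["ring_table"].get("preparation", "slice")),
        )
    if "drive" in d:
        kwargs["drive"] = DriveParams(**d["drive"])
    if "kernel" in d:
        kwargs["kernel"] = KernelParams(**d["kernel"])
    for key in ("noise_sd", "duration", "dt", "seed", "target_css"):
        if key in d:
            kwargs[key] = d[key]
    return PairScenario(**kwargs)


def write_scenario_yaml(scenario: PairScenario, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=True))


def read_scenario_yaml(path: str | Path) -> PairScenario:
    return scenario_from_dict(yaml.safe_load(Path(path).read_text()))


def write_ground_truth(path: str | Path, **values) -> None:
    """Sidecar JSON echoing generator ground truth next to written traces."""
    Path(path).write_text(json.dumps(values, indent=2, sort_keys=True))
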