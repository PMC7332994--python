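"""Plain-text persistence: long-format trace tables, JSON sidecars, YAML configs.

Traces are stored as delimited text with columns (embryo_id, time_h,
channel, stage, intensity); numeric values use Python repr formatting so a
write/read cycle is bit-identical. Ground truth travels as a structured
JSON sidecar and scenarios as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mrna import MrnaInterpolant, MrnaSeries
from .synthetic import GroundTruthRecord, SyntheticScenario
from .traces import FluorescenceTrace

TRACE_COLUMNS = ["embryo_id", "time_h", "channel", "stage", "intensity"]


def traces_to_frame(traces: list[FluorescenceTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({
            "embryo_id": tr.embryo_id,
            "time_h": tr.time_h,
            "channel": tr.channel,
            "stage": tr.stage,
            "intensity": tr.intensity,
        }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=TRACE_COLUMNS)


def FLOAT_FORMAT(x) -> str:
    """17-significant-digit formatting: written files re-read bit-identically."""
    return format(float(x), ".17g")


def write_traces(traces: list[FluorescenceTrace], path) -> None:
    """Write traces as long-format CSV (round-trip-precision floats)."""
    traces_to_frame(traces).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_traces(path) -> list[FluorescenceTrace]:
    """Read a long-format CSV back into one trace per (embryo_id, channel)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table {path} lacks columns {sorted(missing)}")
    traces = []
    for (eid, channel), grp in df.groupby(["embryo_id", "channel"], sort=False):
        grp = grp.sort_values("time_h")
        stage = grp["stage"].iloc[0]
        traces.append(FluorescenceTrace(
            embryo_id=str(eid), time_h=grp["time_h"].to_numpy(),
            intensity=grp["intensity"].to_numpy(),
            stage=str(stage), channel=str(channel),
        ))
    return traces


def write_mrna_series(series: MrnaSeries, path) -> None:
    pd.DataFrame({"label": series.labels, "value": series.M}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def read_mrna_series(path) -> MrnaSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"label", "value"} <= set(df.columns):
        raise ValueError(f"mRNA table {path} needs 'label' and 'value' columns")
    return MrnaSeries.from_labels([str(x) for x in df["label"]], df["value"].to_numpy())


def _pyfloats(d: dict) -> dict:
    """Coerce numpy scalars to plain python numbers (JSON/YAML-safe)."""
    out = {}
    for k, v in d.items():
        if isinstance(v, np.floating):
            v = float(v)
        elif isinstance(v, np.integer):
            v = int(v)
        elif isinstance(v, dict):
            v = _pyfloats(v)
        out[k] = v
    return out


def interpolant_to_dict(interp: MrnaInterpolant) -> dict:
    return _pyfloats(dataclasses.asdict(interp))


def write_interpolant(interp: MrnaInterpolant, path) -> None:
    Path(path).write_text(json.dumps(interpolant_to_dict(interp), indent=2) + "\n")


def read_interpolant(path) -> MrnaInterpolant:
    return MrnaInterpolant(**json.loads(Path(path).read_text()))


def _scenario_dict(scenario: SyntheticScenario) -> dict:
    d = _pyfloats(dataclasses.asdict(scenario))
    if isinstance(scenario.mrna_program, MrnaInterpolant):
        d["mrna_program"] = interpolant_to_dict(scenario.mrna_program)
    return d


def write_scenario(scenario: SyntheticScenario, path) -> None:
    Path(path).write_text(yaml.safe_dump(_scenario_dict(scenario), sort_keys=False))


def read_scenario(path) -> SyntheticScenario:
    d = yaml.safe_load(Path(path).read_text())
    return scenario_from_dict(d)


def scenario_from_dict(d: dict) -> SyntheticScenario:
    d = dict(d)
    prog = d.get("mrna_program")
    if isinstance(prog, dict):
        d["mrna_program"] = MrnaInterpolant(**prog)
    return SyntheticScenario(**d)


def write_ground_truth(record: GroundTruthRecord, path) -> None:
    payload = {
        "scenario": _scenario_dict(record.scenario),
        "t": np.asarray(record.t).tolist(),
        "noise_free_curve": np.asarray(record.noise_free_curve).tolist(),
        "plateau": record.plateau,
        "per_embryo_params": record.per_embryo_params,
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def read_ground_truth(path) -> GroundTruthRecord:
    d = json.loads(Path(path).read_text())
    return GroundTruthRecord(
        scenario=scenario_from_dict(d["scenario"]),
        t=np.asarray(d["t"], dtype=float),
        noise_free_curve=np.asarray(d["noise_free_curve"], dtype=float),
        plateau=float(d["plateau"]),
        per_embryo_params=d["per_embryo_params"],
    )
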