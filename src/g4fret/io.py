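"""Plain-text readers and writers for traces, models and results.

Trace files are CSV with a 1-based ``frame`` index and channel columns
``F_DD, F_AD, F_AA``; synthetic traces add ``truth_state`` and ``truth_E``.
A manifest CSV (``file, timepoint_s, seed``) ties a directory of trace
files to a time-course experiment.  Kinetic models and generator configs
are flat JSON/YAML key-value files mirroring the dataclass field names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .fret import FretHistogram
from .kinetics import KineticModel, TimeCourse
from .simulate import GeneratorConfig, RawTrace, TraceTruth

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_manifest",
    "read_manifest",
    "load_kinetic_model",
    "save_kinetic_model",
    "load_generator_config",
    "save_generator_config",
    "write_histogram_csv",
    "write_fractions_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_distances",
]


def write_trace_csv(raw: RawTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(1, raw.n_frames + 1),
            "F_DD": raw.f_dd,
            "F_AD": raw.f_ad,
            "F_AA": raw.f_aa,
        }
    )
    if raw.truth is not None:
        df["truth_state"] = raw.truth.state
        df["truth_E"] = raw.truth.efficiency
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path, frame_time: float) -> RawTrace:
    df = pd.read_csv(path)
    required = {"frame", "F_DD", "F_AD", "F_AA"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} missing columns: {sorted(missing)}")
    truth = None
    if {"truth_state", "truth_E"} <= set(df.columns):
        truth = TraceTruth(
            state=df["truth_state"].to_numpy(dtype=object),
            efficiency=df["truth_E"].to_numpy(dtype=float),
            donor_bleach_frame=None,
            acceptor_bleach_frame=None,
            donor_bleach_time=None,
            acceptor_bleach_time=None,
        )
    frames = df[["F_DD", "F_AD", "F_AA"]].to_numpy(dtype=float)
    return RawTrace(frames=frames, frame_time=frame_time, truth=truth)


def write_manifest(entries: Sequence[tuple[str, float, int]], path: str | Path) -> None:
    pd.DataFrame(entries, columns=["file", "timepoint_s", "seed"]).to_csv(
        path, index=False
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _load_keyvalue(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_kinetic_model(path: str | Path) -> KineticModel:
    data = _load_keyvalue(path)
    if "on_path" in data:
        data["on_path"] = tuple(data["on_path"])
    if "nucleation_weights" in data:
        data["nucleation_weights"] = tuple(data["nucleation_weights"])
    return KineticModel(**data)


def save_kinetic_model(model: KineticModel, path: str | Path) -> None:
    data = dataclasses.asdict(model)
    data["on_path"] = list(data["on_path"])
    data["nucleation_weights"] = list(data["nucleation_weights"])
    _dump_keyvalue(data, path)


def load_generator_config(path: str | Path) -> GeneratorConfig:
    data = _load_keyvalue(path)
    if "background" in data and not np.isscalar(data["background"]):
        data["background"] = tuple(data["background"])
    if "state_emission" in data:
        data["state_emission"] = {
            k: tuple(v) for k, v in data["state_emission"].items()
        }
    return GeneratorConfig(**data)


def save_generator_config(cfg: GeneratorConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    data["background"] = list(data["background"])
    data["state_emission"] = {k: list(v) for k, v in data["state_emission"].items()}
    _dump_keyvalue(data, path)


def _dump_keyvalue(data: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def write_histogram_csv(hist: FretHistogram, path: str | Path) -> None:
    pd.DataFrame(
        {
            "bin_left": hist.bin_edges[:-1],
            "bin_right": hist.bin_edges[1:],
            "count": hist.counts,
        }
    ).to_csv(path, index=False)


def write_fractions_csv(
    rows: Sequence[tuple[str, float, float, int, int]], path: str | Path
) -> None:
    pd.DataFrame(
        rows, columns=["label", "mean", "sd", "n_traces", "n_frames"]
    ).to_csv(path, index=False)


def read_timecourse_csv(path: str | Path) -> TimeCourse:
    df = pd.read_csv(path)
    required = {"time_s", "fraction"}
    if not required <= set(df.columns):
        raise ValueError(f"time-course file {path} needs columns {sorted(required)}")
    sd = df["sd"].to_numpy(float) if "sd" in df.columns else None
    return TimeCourse(
        times=df["time_s"].to_numpy(float),
        folded_fraction=df["fraction"].to_numpy(float),
        uncertainty=sd,
    )


def write_timecourse_csv(tc: TimeCourse, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": tc.times, "fraction": tc.folded_fraction})
    if tc.uncertainty is not None:
        df["sd"] = tc.uncertainty
    df.to_csv(path, index=False)


def read_distances(path: str | Path) -> np.ndarray:
    """One-column distance file (Å); header optional, comments with #."""
    vals = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip().rstrip(",")
        if not line:
            continue
        try:
            vals.append(float(line))
        except ValueError:
            continue  # header line
    if not vals:
        raise ValueError(f"no numeric distances found in {path}")
    return np.asarray(vals)
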