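"""Plain-text readers and writers for the pipeline's file formats.

All formats are simple delimited text so runs are diffable and portable:
RR series as CSV (beat_index, rr_ms), waveforms as CSV (time_s, voltage_mv),
cohort manifests as CSV, feature tables as TSV, models and validation
reports as JSON, run configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import LinearModel, ParameterSubset
from .series import PhaseLabel, RRSeries, Waveform

#: Stable float formatting for byte-identical re-runs.
FLOAT_FMT = "%.10g"


def write_rr(rr: RRSeries, path) -> None:
    df = pd.DataFrame({"beat_index": np.arange(len(rr)), "rr_ms": rr.rr})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_rr(path, subject_id: str = "", phase=None) -> RRSeries:
    df = pd.read_csv(path)
    return RRSeries(df["rr_ms"].to_numpy(dtype=float), subject_id=subject_id, phase=phase)


def write_waveform(w: Waveform, path) -> None:
    df = pd.DataFrame({"time_s": w.times, "voltage_mv": w.samples})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_waveform(path, sampling_rate: float | None = None) -> Waveform:
    """Read a (time_s, voltage_mv) CSV; the rate is inferred from the time
    column unless given explicitly."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(t)))
    return Waveform(df["voltage_mv"].to_numpy(dtype=float), sampling_rate, start_time=float(t[0]))


def write_manifest(rows: list[dict], path) -> None:
    pd.DataFrame(rows, columns=["subject_id", "arm", "phase", "rr_file"]).to_csv(
        path, index=False
    )


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_rr_from_manifest(path) -> list[RRSeries]:
    """Load every tachogram referenced by a manifest (paths relative to it)."""
    manifest = read_manifest(path)
    base = Path(path).parent
    return [
        read_rr(base / row.rr_file, subject_id=row.subject_id, phase=PhaseLabel(row.phase))
        for row in manifest.itertuples()
    ]


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_model(model: LinearModel, path) -> None:
    payload = {
        "parameters": list(model.subset.indices),
        "parameter_names": list(model.subset.names),
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model(path) -> LinearModel:
    payload = json.loads(Path(path).read_text())
    idx = tuple(payload["parameters"])
    return LinearModel(
        subset=ParameterSubset(idx, 0.0),
        weights=np.array(payload["weights"], dtype=float),
        bias=float(payload["bias"]),
        center=np.array(payload["center"], dtype=float),
        scale=np.array(payload["scale"], dtype=float),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
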