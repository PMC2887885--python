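"""Disk formats: WAV recordings, CSV labels/feature matrices, JSON sidecars.

Recordings are written as single-channel 32-bit-float WAV at the recording
sampling rate; stimulus labels as CSV with columns onset_s, offset_s,
class_id; the generator config (with its hash) as a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import SchemaError
from .features import FeatureMatrix
from .synthetic import GeneratorConfig
from .types import LabeledRecording, StimulusLabel

LABEL_COLUMNS = ["onset_s", "offset_s", "class_id"]


def write_recording(rec: LabeledRecording, basepath: str | Path) -> dict[str, Path]:
    """Write <base>.wav, <base>.labels.csv and <base>.json; return the paths."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    wav = base.with_suffix(".wav")
    labels = base.with_suffix(".labels.csv")
    sidecar = base.with_suffix(".json")

    wavfile.write(wav, int(rec.sampling_rate), rec.samples.astype(np.float32))
    pd.DataFrame(
        [(l.onset_s, l.offset_s, l.class_id) for l in rec.labels], columns=LABEL_COLUMNS
    ).to_csv(labels, index=False)
    sidecar.write_text(
        json.dumps(
            {"sampling_rate": rec.sampling_rate, "metadata": _jsonable(rec.metadata)},
            indent=2,
        )
    )
    return {"wav": wav, "labels": labels, "sidecar": sidecar}


def read_recording(basepath: str | Path) -> LabeledRecording:
    """Inverse of :func:`write_recording` (samples come back as float64)."""
    base = Path(basepath)
    fs, samples = wavfile.read(base.with_suffix(".wav"))
    df = pd.read_csv(base.with_suffix(".labels.csv"))
    if list(df.columns) != LABEL_COLUMNS:
        raise SchemaError(f"label CSV must have columns {LABEL_COLUMNS}, got {list(df.columns)}")
    labels = [
        StimulusLabel(class_id=row.class_id, onset_s=row.onset_s, offset_s=row.offset_s)
        for row in df.itertuples()
    ]
    metadata = {}
    sidecar = base.with_suffix(".json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text()).get("metadata", {})
    return LabeledRecording(
        samples=np.asarray(samples, dtype=np.float64),
        sampling_rate=float(fs),
        labels=labels,
        metadata=metadata,
    )


def write_generator_config(config: GeneratorConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["class_params"] = {c: vars(p) if not isinstance(p, dict) else p for c, p in d["class_params"].items()}
    d["config_hash"] = config.config_hash()
    Path(path).write_text(json.dumps(_jsonable(d), indent=2, sort_keys=True))


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """CSV with window time, label, then one column per feature."""
    df = pd.DataFrame(fm.values, columns=list(fm.feature_names))
    df.insert(0, "label", fm.window_labels)
    df.insert(0, "time_s", fm.window_times)
    df.to_csv(path, index=False)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    if df.columns[0] != "time_s" or df.columns[1] != "label":
        raise SchemaError("feature CSV must start with time_s,label columns")
    return FeatureMatrix(
        values=df.iloc[:, 2:].to_numpy(dtype=np.float64),
        feature_names=tuple(df.columns[2:]),
        window_labels=df["label"].to_numpy(dtype=object),
        window_times=df["time_s"].to_numpy(dtype=np.float64),
    )


def write_report(report, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(report.to_dict()), indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
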