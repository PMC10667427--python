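"""Plain-text persistence: recording CSVs, dataset manifests, feature tables.

Conventions: time in milliseconds from acquisition start, 0-based sample
indexing, half-open windows [start, end), voltages written with 6 decimal
digits (below the sensor noise floor).  Readers validate rather than
silently coerce.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import EnvelopeRecording, N_CHANNELS, FULL_SCALE_V

RECORDING_COLUMNS = ["time_ms"] + [f"emg{i}" for i in range(1, N_CHANNELS + 1)]
FEATURE_KINDS = ("sequence12", "ets", "ess")


class FormatError(ValueError):
    """Malformed on-disk data."""


def save_recording(rec: EnvelopeRecording, path) -> None:
    df = pd.DataFrame(rec.samples, columns=RECORDING_COLUMNS[1:])
    df.insert(0, "time_ms", rec.times_ms)
    df.to_csv(path, index=False, float_format="%.6f")


def load_recording(path, label: str = "", subject_id: str = "S0",
                   rest_duration_ms: float = 500.0,
                   truth: dict | None = None) -> EnvelopeRecording:
    df = pd.read_csv(path)
    if list(df.columns) != RECORDING_COLUMNS:
        raise FormatError(f"{path}: expected columns {RECORDING_COLUMNS}, "
                          f"found {list(df.columns)}")
    t = df["time_ms"].to_numpy(float)
    if t.size < 2:
        raise FormatError(f"{path}: too few samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise FormatError(f"{path}: non-monotone time axis at row {row}")
    samples = df[RECORDING_COLUMNS[1:]].to_numpy(float)
    bad = ~((samples >= 0.0) & (samples <= FULL_SCALE_V))
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise FormatError(f"{path}: voltage outside 0-{FULL_SCALE_V} V at row {row}")
    fs = 1000.0 / float(np.median(dt))
    return EnvelopeRecording(samples=samples, label=label, fs=fs,
                             subject_id=subject_id,
                             rest_duration_ms=rest_duration_ms, truth=truth,
                             recording_id=Path(path).stem)


def _truth_to_json(truth: dict | None) -> dict | None:
    if truth is None:
        return None
    out = dict(truth)
    for key in ("order", "active_channels"):
        if key in out and out[key] is not None:
            out[key] = list(out[key])
    if out.get("starts_ms"):
        out["starts_ms"] = {str(k): v for k, v in out["starts_ms"].items()}
    return out


def _truth_from_json(truth: dict | None) -> dict | None:
    if truth is None:
        return None
    out = dict(truth)
    for key in ("order", "active_channels"):
        if key in out and out[key] is not None:
            out[key] = tuple(int(c) for c in out[key])
    if out.get("starts_ms"):
        out["starts_ms"] = {int(k): float(v) for k, v in out["starts_ms"].items()}
    return out


def save_dataset(recordings: Sequence[EnvelopeRecording], directory,
                 seed: int | None = None) -> Path:
    """Write recordings as CSVs plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(recordings):
        name = rec.recording_id or f"rec_{i:04d}"
        save_recording(rec, directory / f"{name}.csv")
        entries.append({"path": f"{name}.csv", "label": rec.label,
                        "truth": _truth_to_json(rec.truth)})
    manifest = {
        "subject_id": recordings[0].subject_id if recordings else "S0",
        "fs": recordings[0].fs if recordings else 1000.0,
        "rest_duration_ms": recordings[0].rest_duration_ms if recordings else 500.0,
        "created_with_seed": seed,
        "recordings": entries,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_dataset(directory) -> list[EnvelopeRecording]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    out = []
    for entry in manifest["recordings"]:
        path = directory / entry["path"]
        if not path.exists():
            raise FormatError(f"manifest references missing file {path}")
        rec = load_recording(path, label=entry["label"],
                             subject_id=manifest["subject_id"],
                             rest_duration_ms=manifest.get("rest_duration_ms", 500.0),
                             truth=_truth_from_json(entry.get("truth")))
        out.append(rec)
    return out


@dataclass
class FeatureTable:
    """Per-acquisition feature rows of a single kind.

    sequence12 rows are 12 integers in 0..6; ess rows are 6 non-negative
    MAVs; ets rows share one dimensionality per table.
    """

    ids: list[str]
    labels: list[str]
    X: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            self.X = self.X.reshape(len(self.ids), -1)
        if not (len(self.ids) == len(self.labels) == self.X.shape[0]):
            raise ValueError("ids, labels and X must have equal length")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.X.shape[0]:
            if self.kind == "sequence12":
                if self.X.shape[1] != 12:
                    raise ValueError("sequence12 rows must have 12 entries")
                if not np.array_equal(self.X, np.round(self.X)) or \
                        self.X.min() < 0 or self.X.max() > 6:
                    raise ValueError("sequence12 entries must be integers in 0..6")
            elif self.kind == "ess":
                if self.X.shape[1] != 6 or self.X.min() < 0:
                    raise ValueError("ess rows must be 6 non-negative MAVs")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(ids=[self.ids[i] for i in idx],
                            labels=[self.labels[i] for i in idx],
                            X=self.X[idx], kind=self.kind)


def save_feature_table(table: FeatureTable, path) -> None:
    cols = [f"f{i}" for i in range(table.n_features)]
    df = pd.DataFrame(table.X, columns=cols)
    if table.kind == "sequence12":
        df = df.astype(int)
    df.insert(0, "feature_kind", table.kind)
    df.insert(0, "label", table.labels)
    df.insert(0, "recording_id", table.ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t")
    meta = ["recording_id", "label", "feature_kind"]
    if list(df.columns[:3]) != meta:
        raise FormatError(f"{path}: expected leading columns {meta}")
    kinds = df["feature_kind"].unique().tolist() if len(df) else []
    if len(kinds) > 1:
        raise FormatError(f"{path}: mixed feature kinds {kinds}")
    kind = kinds[0] if kinds else "sequence12"
    X = df[df.columns[3:]].to_numpy(float) if len(df) else \
        np.empty((0, len(df.columns) - 3))
    return FeatureTable(ids=df["recording_id"].astype(str).tolist(),
                        labels=df["label"].astype(str).tolist(),
                        X=X, kind=kind)
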