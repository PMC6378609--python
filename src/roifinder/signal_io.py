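"""Data model and file I/O for multichannel unipolar recordings.

A recording bundle on disk is a directory with:

* ``meta.json`` — sampling rate, stage, recording/patient ids and the full
  electrode-array geometry (sorted keys, byte-stable);
* ``signals.csv`` — one column per electrode id (header row), one row per
  sample, voltages in mV at 9 decimal places.

Plain CSV+JSON is deliberate: proprietary electroanatomic-system exports are
out of scope, and the text pair diffs and version-controls cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import ElectrodeArray

__all__ = ["UnipolarRecording", "BundleError", "load_bundle", "save_bundle"]

MIN_SAMPLING_RATE_HZ = 500.0
DEFAULT_DURATION_S = 30.0
STAGES = ("pre_pvi", "post_pvi", "n/a")

_FLOAT_FMT = "%.9f"  # 1e-9 mV round-trip fidelity


class BundleError(ValueError):
    """Recording-bundle validation failure with a machine-readable code."""

    def __init__(self, code: str, message: str):
        super().__init__(f"{code}: {message}")
        self.code = code


@dataclass
class UnipolarRecording:
    """Per-electrode unipolar voltage traces (mV) plus geometry and metadata.

    ``traces`` is a DataFrame with one column per electrode id; all columns
    share the sample index. ``short`` flags recordings under the nominal 30 s.
    """

    sampling_rate: float
    traces: pd.DataFrame
    array: ElectrodeArray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.meta.setdefault("recording_id", "rec")
        self.meta.setdefault("stage", "n/a")
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.traces)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def short(self) -> bool:
        return self.duration_s < DEFAULT_DURATION_S - 1e-9

    def channel(self, electrode_id: str) -> np.ndarray:
        return self.traces[electrode_id].to_numpy()

    def validate(self) -> None:
        if self.sampling_rate < MIN_SAMPLING_RATE_HZ:
            raise BundleError(
                "sampling_rate", f"sampling_rate {self.sampling_rate} < {MIN_SAMPLING_RATE_HZ} Hz"
            )
        if self.meta.get("stage") not in STAGES:
            raise BundleError("stage", f"stage must be one of {STAGES}")
        known = set(self.array.ids)
        for col in self.traces.columns:
            if col not in known:
                raise BundleError("unknown_electrode", f"trace column {col!r} not in array")
        if not np.all(np.isfinite(self.traces.to_numpy())):
            raise BundleError("non_numeric", "traces contain non-finite values")

    def with_traces(self, traces: pd.DataFrame) -> "UnipolarRecording":
        return UnipolarRecording(self.sampling_rate, traces, self.array, dict(self.meta))


def save_bundle(recording: UnipolarRecording, path: str | Path) -> Path:
    """Write a recording bundle; identical recordings produce identical bytes."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "sampling_rate": recording.sampling_rate,
        "n_samples": recording.n_samples,
        "electrodes": list(recording.traces.columns),
        "geometry": json.loads(recording.array.to_json()),
        **{k: recording.meta[k] for k in sorted(recording.meta)},
    }
    (path / "meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    recording.traces.to_csv(
        path / "signals.csv", index=False, float_format=_FLOAT_FMT, lineterminator="\n"
    )
    return path


def load_bundle(path: str | Path) -> UnipolarRecording:
    """Load and cross-validate a recording bundle written by :func:`save_bundle`."""
    path = Path(path)
    meta_path, sig_path = path / "meta.json", path / "signals.csv"
    if not meta_path.exists() or not sig_path.exists():
        raise BundleError("missing_file", f"bundle at {path} needs meta.json and signals.csv")
    meta = json.loads(meta_path.read_text())
    if "geometry" not in meta:
        raise BundleError("missing_geometry", "meta.json has no geometry document")
    array = ElectrodeArray.from_json(json.dumps(meta["geometry"]))
    try:
        traces = pd.read_csv(sig_path, dtype=float)
    except ValueError as exc:
        raise BundleError("non_numeric", f"signals.csv has non-numeric cells ({exc})") from exc
    if list(traces.columns) != list(meta["electrodes"]):
        raise BundleError("header_mismatch", "signals.csv header differs from metadata")
    if len(traces) != int(meta["n_samples"]):
        raise BundleError("shape_mismatch", "sample count differs from metadata")
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("sampling_rate", "n_samples", "electrodes", "geometry")
    }
    return UnipolarRecording(float(meta["sampling_rate"]), traces, array, extra)


def recording_from_channels(
    sampling_rate: float,
    channels: Mapping[str, np.ndarray],
    array: ElectrodeArray,
    **meta,
) -> UnipolarRecording:
    """Convenience constructor from a mapping electrode_id -> trace."""
    traces = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in channels.items()})
    return UnipolarRecording(sampling_rate, traces, array, dict(meta))
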