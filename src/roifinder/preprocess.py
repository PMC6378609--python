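"""Signal conditioning for unipolar electrograms.

The clinical chain is a 2–240 Hz band-pass with a 60 Hz mains notch and
nothing else. Corner frequencies are all that is specified, so the filter
family is this package's choice: a 4th-order Butterworth band-pass plus a
second-order notch (quality 30), both applied forward–backward so local
activation times are not delayed or skewed by filter phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .signal_io import UnipolarRecording

__all__ = ["FilterSpec", "filter_unipolar", "filter_traces"]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass corners plus mains notch (all Hz). ``notch=None`` disables it."""

    band_low: float = 2.0
    band_high: float = 240.0
    notch: float | None = 60.0
    notch_quality: float = 30.0
    order: int = 4

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not (0.0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if self.band_high >= nyq:
            raise ValueError(
                f"band_high {self.band_high} Hz >= Nyquist {nyq} Hz; "
                "lower band_high below half the sampling rate"
            )
        if self.notch is not None and not (self.band_low < self.notch < self.band_high):
            raise ValueError("notch frequency must lie inside the pass band")

    def sos(self, sampling_rate: float) -> np.ndarray:
        """Cascaded second-order sections for the full chain."""
        self.validate(sampling_rate)
        sos = signal.butter(
            self.order,
            [self.band_low, self.band_high],
            btype="bandpass",
            fs=sampling_rate,
            output="sos",
        )
        if self.notch is not None:
            b, a = signal.iirnotch(self.notch, self.notch_quality, fs=sampling_rate)
            sos = np.vstack([sos, signal.tf2sos(b, a)])
        return sos


def filter_traces(x: np.ndarray, sampling_rate: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase filtering of one trace (1-D) or a sample x channel matrix."""
    spec = spec or FilterSpec()
    sos = spec.sos(sampling_rate)
    x = np.asarray(x, dtype=float)
    return signal.sosfiltfilt(sos, x, axis=0)


def filter_unipolar(recording: UnipolarRecording, spec: FilterSpec | None = None) -> UnipolarRecording:
    """Return a new recording with every channel filtered (zero phase)."""
    spec = spec or FilterSpec()
    filt = filter_traces(recording.traces.to_numpy(), recording.sampling_rate, spec)
    traces = recording.traces.copy()
    traces.iloc[:, :] = filt
    out = recording.with_traces(traces)
    out.meta["filter"] = {
        "band_low": spec.band_low,
        "band_high": spec.band_high,
        "notch": spec.notch,
        "notch_quality": spec.notch_quality,
        "order": spec.order,
    }
    return out
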