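"""Local activation time annotation, channel quality gating and unipolar
morphology classification.

The annotator is the standard unipolar convention: an activation is a local
maximum of the negative slope (-dV/dt) above a threshold, with a blanking
period so one deflection yields one event. It stands in for the clinical
system's proprietary wavelet annotator and is isolated behind this module so
an alternative can be swapped in.

Morphology: a unipolar deflection is **QS** when it has no significant
initial positivity. We measure the maximal positive deflection (R) in the
window before the activation and the maximal negative deflection (S) around
it, subtract a robust per-channel noise floor from each so that noise bumps
do not masquerade as R waves, and call the event QS when
``R / (R + S) <= qs_threshold`` (default 0.10).

Channels that cannot be annotated reliably (too few beats, poor SNR, low
amplitude, dominant frequency outside the atrial band) are gated out: they
keep their quality report but contribute no timings downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

__all__ = [
    "AnnotationParams",
    "QualityThresholds",
    "ActivationEvent",
    "ChannelAnnotation",
    "detect_activations",
    "classify_morphology",
    "quality_gate",
    "annotate_recording",
]

QS = "QS"
NON_QS = "non_QS"


@dataclass(frozen=True)
class AnnotationParams:
    """Tunables of the slope annotator.

    blanking_ms
        Refractory period between events (one deflection, one event).
    min_slope
        Floor of the negative-slope threshold, mV/ms. The working threshold
        adapts to the channel: ``max(min_slope, slope_k * sigma_slope)`` where
        ``sigma_slope`` is the robust (MAD) noise level of the smoothed
        derivative, so a noisier channel needs a steeper downstroke.
    slope_k
        Multiplier on the derivative noise level for the adaptive threshold.
    window_ms
        Morphology window: R measured in the half-window before the LAT,
        S in the full window around it.
    smooth_ms
        Gaussian smoothing (std, ms) applied before differentiation; trades
        derivative noise against timing sharpness.
    qs_threshold
        R/(R+S) at or below which an event is QS.
    noise_floor_k
        Amplitudes are reduced by ``k`` times the robust channel noise sigma
        before the R/S ratio is formed.
    """

    blanking_ms: float = 60.0
    min_slope: float = 0.01
    slope_k: float = 4.0
    window_ms: float = 40.0
    smooth_ms: float = 3.0
    qs_threshold: float = 0.10
    noise_floor_k: float = 2.0


@dataclass(frozen=True)
class QualityThresholds:
    """Channel gating thresholds. ``min_beats`` is per nominal 30 s and is
    scaled to the actual recording duration."""

    min_beats: int = 15
    min_snr: float = 3.0
    min_p2p_mV: float = 0.05
    freq_band_Hz: tuple[float, float] = (3.0, 12.0)


@dataclass(frozen=True)
class ActivationEvent:
    """One annotated atrial activation on one electrode."""

    electrode_id: str
    lat: float  # ms from recording start
    neg_slope: float  # |dV/dt| at lat, mV/ms
    r_amp: float  # mV, noise-floored max positive deflection before lat
    s_amp: float  # mV, noise-floored |max negative deflection|
    r_fraction: float | None  # r/(r+s); None when both lobes are at the floor
    morphology: str = NON_QS
    degenerate: bool = False


@dataclass
class ChannelAnnotation:
    """Per-channel annotation outcome: events plus the quality report."""

    electrode_id: str
    events: list[ActivationEvent]
    passed: bool
    reasons: frozenset[str] = frozenset()
    snr: float = 0.0
    beat_count: int = 0
    dominant_frequency: float = float("nan")
    p2p_mV: float = 0.0


def _robust_sigma(x: np.ndarray) -> float:
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def classify_morphology(
    r_amp: float, s_amp: float, qs_threshold: float = 0.10
) -> tuple[str, float | None, bool]:
    """Label a deflection from its R and S amplitudes.

    Returns ``(label, r_fraction, degenerate)``; a deflection with no energy
    in either lobe is non-QS with the degenerate flag set.
    """
    total = r_amp + s_amp
    if total <= 0:
        return NON_QS, None, True
    rf = r_amp / total
    return (QS if rf <= qs_threshold else NON_QS), rf, False


def detect_activations(
    trace: np.ndarray,
    sampling_rate: float,
    params: AnnotationParams | None = None,
    electrode_id: str = "?",
) -> list[ActivationEvent]:
    """Annotate one filtered unipolar trace.

    Events are local maxima of the negative smoothed slope above
    ``min_slope``, at least ``blanking_ms`` apart; each event carries R/S
    amplitudes measured in ``window_ms`` about the LAT and a morphology label.
    A flat or empty trace yields an empty list.
    """
    params = params or AnnotationParams()
    x = np.asarray(trace, dtype=float)
    if x.size == 0 or np.ptp(x) == 0:
        return []
    dt_ms = 1000.0 / sampling_rate
    sigma = max(params.smooth_ms / dt_ms, 0.5)
    sm = gaussian_filter1d(x, sigma)
    slope = np.gradient(sm) / dt_ms  # mV/ms
    thr = max(params.min_slope, params.slope_k * _robust_sigma(slope))
    distance = max(int(round(params.blanking_ms / dt_ms)), 1)
    idx, _ = find_peaks(-slope, height=thr, distance=distance)
    if idx.size == 0:
        return []

    floor = params.noise_floor_k * _robust_sigma(sm)
    half = max(int(round(params.window_ms / 2.0 / dt_ms)), 1)
    events: list[ActivationEvent] = []
    for i in idx:
        lo, hi = max(0, i - half), min(len(sm), i + half + 1)
        r_raw = max(0.0, float(np.max(sm[lo : i + 1])))
        s_raw = max(0.0, float(-np.min(sm[lo:hi])))
        r_amp = max(0.0, r_raw - floor)
        s_amp = max(0.0, s_raw - floor)
        label, rf, degen = classify_morphology(r_amp, s_amp, params.qs_threshold)
        events.append(
            ActivationEvent(
                electrode_id=electrode_id,
                lat=float(i * dt_ms),
                neg_slope=float(-slope[i]),
                r_amp=r_amp,
                s_amp=s_amp,
                r_fraction=rf,
                morphology=label,
                degenerate=degen,
            )
        )
    return events


def _dominant_frequency(x: np.ndarray, sampling_rate: float) -> float:
    """Spectral peak (Hz) of the rectified, low-pass-smoothed trace."""
    env = gaussian_filter1d(np.abs(x), max(10.0 * sampling_rate / 1000.0, 1.0))
    env = env - np.mean(env)
    n = len(env)
    if n < 16:
        return float("nan")
    spec = np.abs(np.fft.rfft(env))
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    band = (freqs >= 0.5) & (freqs <= 25.0)
    if not np.any(band):
        return float("nan")
    return float(freqs[band][np.argmax(spec[band])])


def quality_gate(
    trace: np.ndarray,
    sampling_rate: float,
    events: Sequence[ActivationEvent],
    thresholds: QualityThresholds | None = None,
    electrode_id: str = "?",
    smooth_ms: float = 3.0,
) -> ChannelAnnotation:
    """Label a channel usable or not; never raises.

    A failing channel keeps its quality report but its event list is emptied
    so no timing from it reaches the detector.
    """
    thr = thresholds or QualityThresholds()
    x = np.asarray(trace, dtype=float)
    dt_ms = 1000.0 / sampling_rate
    sm = gaussian_filter1d(x, max(smooth_ms / dt_ms, 0.5)) if x.size else x
    duration_s = x.size / sampling_rate if x.size else 0.0
    required_beats = max(2, int(np.ceil(thr.min_beats * duration_s / 30.0)))

    beat_count = len(events)
    p2p = float(np.ptp(sm)) if x.size else 0.0
    sigma = _robust_sigma(sm) if x.size else 0.0
    if events and sigma > 0:
        amp = float(np.median([e.r_amp + e.s_amp for e in events]))
        snr = amp / sigma
    else:
        snr = 0.0
    domfreq = _dominant_frequency(x, sampling_rate) if x.size else float("nan")

    reasons: set[str] = set()
    if beat_count < required_beats:
        reasons.add("too_few_beats")
    if snr < thr.min_snr:
        reasons.add("low_snr")
    if p2p < thr.min_p2p_mV:
        reasons.add("low_amplitude")
    lo, hi = thr.freq_band_Hz
    if not (np.isfinite(domfreq) and lo <= domfreq <= hi):
        reasons.add("off_band_frequency")

    passed = not reasons
    return ChannelAnnotation(
        electrode_id=electrode_id,
        events=list(events) if passed else [],
        passed=passed,
        reasons=frozenset(reasons),
        snr=snr,
        beat_count=beat_count,
        dominant_frequency=domfreq,
        p2p_mV=p2p,
    )


def annotate_recording(
    recording,
    params: AnnotationParams | None = None,
    thresholds: QualityThresholds | None = None,
) -> dict[str, ChannelAnnotation]:
    """Annotate and gate every channel of a (filtered) recording."""
    params = params or AnnotationParams()
    out: dict[str, ChannelAnnotation] = {}
    for eid in recording.traces.columns:
        trace = recording.channel(eid)
        events = detect_activations(trace, recording.sampling_rate, params, electrode_id=eid)
        out[eid] = quality_gate(
            trace,
            recording.sampling_rate,
            events,
            thresholds,
            electrode_id=eid,
            smooth_ms=params.smooth_ms,
        )
    return out


def events_to_rows(annotations: dict[str, ChannelAnnotation]) -> list[dict]:
    """Flatten annotations for CSV export."""
    rows = []
    for eid in sorted(annotations):
        for e in annotations[eid].events:
            rows.append(
                {
                    "electrode_id": eid,
                    "lat_ms": round(e.lat, 3),
                    "r_amp": round(e.r_amp, 6),
                    "s_amp": round(e.s_amp, 6),
                    "r_fraction": None if e.r_fraction is None else round(e.r_fraction, 4),
                    "morphology": e.morphology,
                }
            )
    return rows
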