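"""Synthetic activation patterns and unipolar electrograms with ground truth.

The generator is kinematic (eikonal-style), not reaction–diffusion: a source
schedule defines *when and where* wavefronts start, activation times at each
electrode follow from surface (geodesic) distance divided by a conduction
velocity, and each activation stamps a template deflection into the trace.
That is exactly the structure — timing plus unipolar morphology — that the
ROI detector consumes; tissue-level electrophysiology is out of scope.

Scenarios mirror the validation arms of driver mapping studies:

* ``focal_at`` — a regular focal tachycardia (cycle length 200–300 ms) firing
  from one surface site for the whole recording;
* ``reentrant_at`` — a macro-/micro-reentrant circuit (radius 5–25 mm)
  rotating at a fixed period, with no centrifugal origin anywhere;
* ``af_with_driver`` — disorganized planar background wavelets (cycle length
  jittered around 145 ms) interrupted by a focal driver firing in runs:
  by default about 11 occurrences per 30 s of about 3 consecutive beats each;
* ``af_no_driver`` — background wavelets only;
* ``planar`` — regular planar sweeps (a detector null case).

Morphology model: an activation renders QS (no initial positivity) at
electrodes within ``qs_radius_mm`` of its originating point and RS
(r-fraction ~0.3–0.6) elsewhere; planar and reentrant wavefronts have no
origin, so they render RS everywhere. Amplitude attenuates with distance
from the origin. White noise plus a 60 Hz mains component are injected
*before* filtering so the preprocessing chain is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import AtrialSurface, ElectrodeArray, make_basket_array
from .signal_io import UnipolarRecording

__all__ = [
    "SourceSchedule",
    "AFDriverProfile",
    "MorphologyModel",
    "NoiseModel",
    "Activation",
    "SimulationTruth",
    "SimulationResult",
    "propagate",
    "render_egm",
    "wave_template",
    "simulate_recording",
    "sample_driver_runs",
    "save_truth",
    "load_truth",
]

SCENARIOS = ("focal_at", "reentrant_at", "af_with_driver", "af_no_driver", "planar")

#: conduction velocity default, mm/ms (atrial myocardium ~0.5–1.0)
DEFAULT_CV = 0.9
#: AF background cycle length, ms (left atrial appendage scale in persistent AF)
AF_BASE_CL_MS = 145.0


@dataclass(frozen=True)
class SourceSchedule:
    """When and where wavefronts start.

    ``focal``: ``origin`` fires at each of ``firing_times``.
    ``planar``: a plane wave with unit ``direction`` sweeps at each firing time.
    ``macro_reentry`` / ``micro_reentry``: continuous rotation around a circuit
    (``origin`` = center, ``circuit_radius_mm``) with the given ``period_ms``.
    """

    source_type: str
    origin: tuple[float, float, float] | None = None
    firing_times: tuple[float, ...] = ()
    direction: tuple[float, float, float] | None = None
    period_ms: float | None = None
    circuit_radius_mm: float | None = None
    conduction_velocity: float = DEFAULT_CV

    def __post_init__(self) -> None:
        if not (0.2 <= self.conduction_velocity <= 2.0):
            raise ValueError("conduction_velocity must be in [0.2, 2.0] mm/ms")
        if list(self.firing_times) != sorted(self.firing_times):
            raise ValueError("firing_times must be increasing")
        if self.source_type in ("macro_reentry", "micro_reentry"):
            if self.period_ms is None or self.period_ms < 100.0:
                raise ValueError("reentry period must be >= 100 ms")


@dataclass(frozen=True)
class AFDriverProfile:
    """Statistical profile of an intermittent focal driver in AF."""

    recurrence_per_30s: float = 11.0
    run_length_mean: float = 3.0
    base_cycle_length: float = AF_BASE_CL_MS
    background: str = "disorganized"  # or "quiescent"

    def __post_init__(self) -> None:
        if self.recurrence_per_30s < 0:
            raise ValueError("recurrence must be >= 0")
        if self.run_length_mean < 2:
            raise ValueError("driver-positive scenarios need run_length_mean >= 2")
        if not (100.0 <= self.base_cycle_length <= 300.0):
            raise ValueError("base cycle length must be in [100, 300] ms")


@dataclass(frozen=True)
class MorphologyModel:
    """Unipolar template parameters.

    Unipolar amplitude is dominated by the wavefront passing locally under
    each electrode, so distance from the *source* attenuates it only mildly:
    the relative amplitude decays from 1 toward ``amp_floor`` with scale
    ``atten_mm``. Distance governs morphology instead: QS within
    ``qs_radius_mm`` of the origin, RS (r-fraction ``rs_fraction``) beyond.
    """

    qs_radius_mm: float = 5.0  # QS within this distance of the origin
    amp_mV: float = 1.0  # S-lobe amplitude at the origin
    width_ms: float = 24.0  # full template width (~6 sigma)
    atten_mm: float = 25.0  # decay scale of the far-field component
    amp_floor: float = 0.6  # relative amplitude far from the origin
    rs_fraction: float = 0.45  # target r-fraction away from the origin


@dataclass(frozen=True)
class NoiseModel:
    """Additive pre-filter noise. ``snr`` = template amplitude / white RMS."""

    snr: float = 10.0
    mains_hz: float = 60.0
    mains_mV: float = 0.1


@dataclass(frozen=True)
class Activation:
    """One wavefront arrival at one electrode."""

    time_ms: float
    origin: tuple[float, float, float] | None  # None for origin-less wavefronts


@dataclass
class SimulationTruth:
    """Ground truth: schedules, per-electrode arrival times, driver sites."""

    scenario: str
    seed: int
    drivers: list[dict]  # {"xyz": [...], "firing_times": [...], "runs": [...]}
    per_electrode_times: dict[str, list[float]]
    cycle_length_ms: float | None = None


@dataclass
class SimulationResult:
    recording: UnipolarRecording
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


def _tangent_frame(surface: AtrialSurface, point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    normal = (point - np.asarray(surface.center)) / np.asarray(surface.semi_axes) ** 2
    normal = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def propagate(
    schedule: SourceSchedule,
    surface: AtrialSurface,
    positions: dict[str, np.ndarray],
    duration_ms: float,
) -> dict[str, list[Activation]]:
    """Per-electrode wavefront arrival times for one schedule.

    Electrodes farther from the surface than its diameter are a geometry
    mismatch and are rejected.
    """
    out: dict[str, list[Activation]] = {eid: [] for eid in positions}
    pos_items = sorted(positions.items())
    for eid, p in pos_items:
        if abs(surface.surface_residual(np.asarray(p))) > surface.diameter_mm:
            raise ValueError(f"electrode {eid} is farther than the surface diameter")

    cv = schedule.conduction_velocity
    if schedule.source_type == "focal":
        origin = np.asarray(schedule.origin, dtype=float)
        for eid, p in pos_items:
            d = surface.geodesic_mm(origin, np.asarray(p))
            for t in schedule.firing_times:
                at = t + d / cv
                if at <= duration_ms:
                    out[eid].append(Activation(at, tuple(origin)))
    elif schedule.source_type == "planar":
        n = np.asarray(schedule.direction, dtype=float)
        n = n / np.linalg.norm(n)
        proj = {eid: float(np.dot(np.asarray(p), n)) for eid, p in pos_items}
        base = min(proj.values())
        for eid, p in pos_items:
            delay = (proj[eid] - base) / cv
            for t in schedule.firing_times:
                at = t + delay
                if at <= duration_ms:
                    out[eid].append(Activation(at, None))
    elif schedule.source_type in ("macro_reentry", "micro_reentry"):
        center = surface.project(np.asarray(schedule.origin, dtype=float))
        rho = schedule.circuit_radius_mm or 10.0
        T = float(schedule.period_ms)
        u, v = _tangent_frame(surface, center)
        for eid, p in pos_items:
            rel = np.asarray(p) - center
            angle = float(np.arctan2(np.dot(rel, v), np.dot(rel, u))) % (2 * np.pi)
            d = surface.geodesic_mm(center, np.asarray(p))
            radial_delay = max(0.0, d - rho) / cv
            t0 = (angle / (2 * np.pi)) * T + radial_delay
            n_turns = int(np.ceil((duration_ms - t0) / T)) + 1
            for k in range(max(n_turns, 0)):
                at = t0 + k * T
                if 0.0 <= at <= duration_ms:
                    out[eid].append(Activation(at, None))
    else:
        raise ValueError(f"unknown source_type {schedule.source_type!r}")
    for eid in out:
        out[eid].sort(key=lambda a: a.time_ms)
    return out


# ---------------------------------------------------------------------------
# electrogram rendering
# ---------------------------------------------------------------------------


def wave_template(
    t_ms: np.ndarray, t0: float, r_amp: float, s_amp: float, sigma_ms: float
) -> np.ndarray:
    """Unipolar deflection with steepest negative slope exactly at ``t0``.

    Positive lobe centered ``sigma`` before ``t0`` and negative lobe
    ``sigma`` after it: both Gaussians place their maximal downslope at
    ``t0``, so the annotated LAT is morphology-independent.
    """
    g1 = np.exp(-((t_ms - (t0 - sigma_ms)) ** 2) / (2 * sigma_ms**2))
    g2 = np.exp(-((t_ms - (t0 + sigma_ms)) ** 2) / (2 * sigma_ms**2))
    return r_amp * g1 - s_amp * g2


def render_egm(
    activations: Sequence[Activation],
    electrode_pos: np.ndarray,
    morph: MorphologyModel,
    duration_ms: float,
    sampling_rate: float,
) -> np.ndarray:
    """Render one electrode's trace by linear superposition of templates."""
    n = int(round(duration_ms * sampling_rate / 1000.0))
    trace = np.zeros(n)
    dt_ms = 1000.0 / sampling_rate
    sigma = morph.width_ms / 6.0
    support = int(np.ceil(5 * sigma / dt_ms))
    p = np.asarray(electrode_pos, dtype=float)
    for a in activations:
        if a.origin is None:
            amp = morph.amp_mV * 0.8  # local wavefront, no source nearby
            f = morph.rs_fraction
        else:
            d = float(np.linalg.norm(p - np.asarray(a.origin)))
            rel = morph.amp_floor + (1.0 - morph.amp_floor) * np.exp(-d / morph.atten_mm)
            amp = morph.amp_mV * rel
            f = 0.0 if d <= morph.qs_radius_mm else morph.rs_fraction
        s_amp = amp
        r_amp = amp * f / (1.0 - f) if f > 0 else 0.0
        i0 = int(round(a.time_ms / dt_ms))
        lo, hi = max(0, i0 - support), min(n, i0 + support + 1)
        if lo >= hi:
            continue
        tt = np.arange(lo, hi) * dt_ms
        trace[lo:hi] += wave_template(tt, a.time_ms, r_amp, s_amp, sigma)
    return trace


def _add_noise(
    traces: np.ndarray, sampling_rate: float, noise: NoiseModel, morph: MorphologyModel, rng
) -> np.ndarray:
    if not np.isfinite(noise.snr) and noise.mains_mV == 0:
        return traces
    n = traces.shape[0]
    t_s = np.arange(n) / sampling_rate
    out = traces.copy()
    if np.isfinite(noise.snr) and noise.snr > 0:
        out += rng.normal(0.0, morph.amp_mV / noise.snr, size=traces.shape)
    if noise.mains_mV > 0:
        phase = rng.uniform(0, 2 * np.pi, size=traces.shape[1])
        out += noise.mains_mV * np.sin(
            2 * np.pi * noise.mains_hz * t_s[:, None] + phase[None, :]
        )
    return out


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------


def sample_driver_runs(
    profile: AFDriverProfile, duration_ms: float, rng: np.random.Generator
) -> list[list[float]]:
    """Sample an intermittent driver's firing times, grouped by run.

    The number of occurrences is Poisson around ``recurrence_per_30s``
    (scaled to the duration); run lengths are ``2 + Poisson(mean - 2)``;
    runs are laid out without overlap using Dirichlet-distributed gaps.
    """
    lam = profile.recurrence_per_30s * duration_ms / 30000.0
    n_runs = int(rng.poisson(lam))
    if n_runs == 0:
        return []
    cl = profile.base_cycle_length
    lengths = 2 + rng.poisson(max(profile.run_length_mean - 2.0, 0.0), size=n_runs)
    margin = 300.0
    while True:
        total = float(np.sum(lengths) * cl)
        free = duration_ms - 2 * margin - total
        if free > 0 or n_runs == 0:
            break
        n_runs -= 1
        lengths = lengths[:n_runs]
    if n_runs == 0:
        return []
    gaps = free * rng.dirichlet(np.ones(n_runs + 1))
    runs: list[list[float]] = []
    t = margin
    for i in range(n_runs):
        t += gaps[i]
        jitter = rng.normal(0.0, 2.0, size=int(lengths[i]))
        times = [t + k * cl + jitter[k] for k in range(int(lengths[i]))]
        runs.append(sorted(times))
        t = times[-1] + cl
    return runs


def _background_wavefronts(
    duration_ms: float,
    exclude: list[tuple[float, float]],
    base_cl: float,
    rng: np.random.Generator,
) -> list[SourceSchedule]:
    """Random-direction planar wavelets with jittered cycle length, avoiding
    driver-run windows (the driver entrains the chamber during a run)."""
    schedules = []
    t = float(rng.uniform(0, base_cl))
    while t < duration_ms:
        if not any(lo <= t <= hi for lo, hi in exclude):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            schedules.append(
                SourceSchedule("planar", direction=tuple(d), firing_times=(t,))
            )
        t += max(60.0, rng.normal(base_cl, 15.0))
    return schedules


def _merge_activations(
    parts: list[dict[str, list[Activation]]]
) -> dict[str, list[Activation]]:
    out: dict[str, list[Activation]] = {}
    for part in parts:
        for eid, acts in part.items():
            out.setdefault(eid, []).extend(acts)
    for eid in out:
        out[eid].sort(key=lambda a: a.time_ms)
    return out


def _pick_source(
    array: ElectrodeArray,
    surface: AtrialSurface,
    rng: np.random.Generator,
    offset_mm: float = 2.5,
    electrode_id: str | None = None,
) -> np.ndarray:
    """A surface point a small tangential offset away from an electrode.

    Detection is defined at electrode resolution, so sources sit where the
    array actually has coverage (the situation the validation arm describes).
    """
    if electrode_id is None:
        electrode_id = array.ids[int(rng.integers(len(array)))]
    p = surface.project(array.position_of(electrode_id))
    u, v = _tangent_frame(surface, p)
    phi = rng.uniform(0, 2 * np.pi)
    return surface.project(p + offset_mm * (np.cos(phi) * u + np.sin(phi) * v))


def simulate_recording(
    scenario: str,
    array: ElectrodeArray | None = None,
    surface: AtrialSurface | None = None,
    seed: int = 0,
    duration_s: float = 30.0,
    sampling_rate: float = 1000.0,
    cycle_length_ms: float | None = None,
    source_electrode: str | None = None,
    circuit_radius_mm: float | None = None,
    profile: AFDriverProfile | None = None,
    morphology: MorphologyModel | None = None,
    noise: NoiseModel | None = None,
    stage: str = "n/a",
) -> SimulationResult:
    """Generate one recording plus its ground truth. Bit-reproducible per seed."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    array = array or make_basket_array()
    surface = surface or AtrialSurface()
    morph = morphology or MorphologyModel()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    duration_ms = duration_s * 1000.0
    positions = {eid: np.asarray(p) for eid, p in array.positions().items()}

    drivers: list[dict] = []
    schedules: list[SourceSchedule] = []
    truth_cl: float | None = None

    if scenario == "focal_at":
        cl = cycle_length_ms if cycle_length_ms is not None else float(rng.uniform(200, 300))
        truth_cl = cl
        origin = _pick_source(array, surface, rng, electrode_id=source_electrode)
        times = tuple(np.arange(100.0, duration_ms, cl))
        schedules.append(SourceSchedule("focal", origin=tuple(origin), firing_times=times))
        drivers.append(
            {"xyz": [float(x) for x in origin], "firing_times": list(times), "runs": [len(times)]}
        )
    elif scenario == "reentrant_at":
        rho = circuit_radius_mm if circuit_radius_mm is not None else float(rng.uniform(5, 25))
        period = cycle_length_ms if cycle_length_ms is not None else float(rng.uniform(200, 300))
        truth_cl = period
        center = _pick_source(array, surface, rng, offset_mm=0.0)
        kind = "micro_reentry" if rho < 12.0 else "macro_reentry"
        schedules.append(
            SourceSchedule(kind, origin=tuple(center), period_ms=period, circuit_radius_mm=rho)
        )
    elif scenario == "planar":
        cl = cycle_length_ms if cycle_length_ms is not None else 250.0
        truth_cl = cl
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        times = tuple(np.arange(100.0, duration_ms, cl))
        schedules.append(SourceSchedule("planar", direction=tuple(d), firing_times=times))
    else:  # AF scenarios
        prof = profile or AFDriverProfile()
        truth_cl = prof.base_cycle_length
        exclude: list[tuple[float, float]] = []
        if scenario == "af_with_driver":
            origin = _pick_source(array, surface, rng, electrode_id=source_electrode)
            runs = sample_driver_runs(prof, duration_ms, rng)
            all_times: list[float] = []
            for run in runs:
                schedules.append(
                    SourceSchedule("focal", origin=tuple(origin), firing_times=tuple(run))
                )
                # margin before a run: wavelets launched earlier still travel
                exclude.append((run[0] - 120.0, run[-1] + 40.0))
                all_times.extend(run)
            if runs:
                drivers.append(
                    {
                        "xyz": [float(x) for x in origin],
                        "firing_times": all_times,
                        "runs": [len(r) for r in runs],
                    }
                )
        if prof.background == "disorganized":
            schedules.extend(
                _background_wavefronts(duration_ms, exclude, prof.base_cycle_length, rng)
            )

    parts = [propagate(s, surface, positions, duration_ms) for s in schedules]
    activations = _merge_activations(parts)

    traces = np.column_stack(
        [
            render_egm(activations[eid], positions[eid], morph, duration_ms, sampling_rate)
            for eid in array.ids
        ]
    )
    traces = _add_noise(traces, sampling_rate, noise, morph, rng)

    recording = UnipolarRecording(
        sampling_rate,
        pd.DataFrame(traces, columns=array.ids),
        array,
        {"recording_id": f"{scenario}-{seed}", "stage": stage, "scenario": scenario, "seed": seed},
    )
    truth = SimulationTruth(
        scenario=scenario,
        seed=seed,
        drivers=drivers,
        per_electrode_times={
            eid: [round(a.time_ms, 6) for a in activations[eid]] for eid in array.ids
        },
        cycle_length_ms=truth_cl,
    )
    return SimulationResult(recording, truth)


# ---------------------------------------------------------------------------
# truth sidecar I/O
# ---------------------------------------------------------------------------


def save_truth(truth: SimulationTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "scenario": truth.scenario,
        "seed": truth.seed,
        "drivers": truth.drivers,
        "cycle_length_ms": truth.cycle_length_ms,
        "per_electrode_times": truth.per_electrode_times,
    }
    path.write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")
    return path


def load_truth(path: str | Path) -> SimulationTruth:
    doc = json.loads(Path(path).read_text())
    return SimulationTruth(
        scenario=doc["scenario"],
        seed=doc["seed"],
        drivers=doc["drivers"],
        per_electrode_times=doc["per_electrode_times"],
        cycle_length_ms=doc.get("cycle_length_ms"),
    )
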