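"""Driver characterization metrics and diagnostic-accuracy statistics.

Drivers are characterized by three quantities, each over 30-second maps:

* **consistency** — fraction of maps showing the driver's focal activation;
* **temporal stability** — mean length of its consecutive-repetition runs;
* **recurrence rate** — how often per map it met the driver definition.

Detection accuracy versus a reference driver list uses the strict <10 mm
center-to-center correlation rule; rates carry exact (Clopper–Pearson)
two-sided confidence intervals, with Wilson intervals as an option. The
2x2 association between detection and ablation response uses Fisher's exact
test. Ancillary clinical rules kept here: AF cycle length over 30 cycles,
the >=30 ms cycle-length-slowing response criterion, and the <0.5 mV
low-voltage-zone cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from .geometry import correlate_sites
from .roi import ROISite

__all__ = [
    "DriverMetrics",
    "RateEstimate",
    "EvaluationResult",
    "driver_metrics",
    "cycle_length",
    "ablation_response",
    "lvz_classify",
    "evaluate_detection",
    "binomial_ci_exact",
    "binomial_ci_wilson",
    "fisher_exact",
    "percent",
]

CL_SLOWING_MS = 30.0  # significant AF cycle-length prolongation
LVZ_THRESHOLD_MV = 0.5  # bipolar voltage below which a site is low-voltage


def percent(x: float) -> int:
    """Proportion -> integer percent, rounded half-up (presentation rule)."""
    return int(Decimal(100 * x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DriverMetrics:
    consistency: float  # fraction of covered maps showing the driver
    temporal_stability: float  # mean consecutive repetitions per occurrence
    recurrence_rate: float  # mean occurrences per 30-s map where present
    maps_present: int
    maps_covered: int


def driver_metrics(
    per_map_sites: Sequence[Sequence[ROISite] | None],
    driver_position: Sequence[float],
    threshold_mm: float = 10.0,
) -> DriverMetrics:
    """Characterize one driver across maps.

    ``per_map_sites`` holds the detected sites of each map, or ``None`` for a
    map whose coverage did not include the driver site (excluded from the
    consistency denominator only).
    """
    if len(per_map_sites) == 0:
        raise ValueError("driver_metrics requires at least one map")
    covered = [m for m in per_map_sites if m is not None]
    matched_runs: list[int] = []
    per_map_occurrences: list[int] = []
    present = 0
    for sites in covered:
        matches = [s for s in sites if correlate_sites(s.position, driver_position, threshold_mm)[0]]
        if matches:
            present += 1
            runs = [r for s in matches for r in s.runs]
            matched_runs.extend(runs)
            per_map_occurrences.append(sum(s.occurrences for s in matches))
    consistency = present / len(covered) if covered else 0.0
    stability = float(np.mean(matched_runs)) if matched_runs else 0.0
    recurrence = float(np.mean(per_map_occurrences)) if per_map_occurrences else 0.0
    return DriverMetrics(consistency, stability, recurrence, present, len(covered))


def cycle_length(activation_times_ms: Sequence[float], n_cycles: int = 30) -> float:
    """Mean cycle length (ms) over the first ``n_cycles`` intervals."""
    lats = np.asarray(sorted(activation_times_ms), dtype=float)
    if lats.size < n_cycles + 1:
        raise ValueError(
            f"need at least {n_cycles + 1} annotated activations, got {lats.size}"
        )
    return float(np.mean(np.diff(lats[: n_cycles + 1])))


def ablation_response(pre_cl_ms: float, post_cl_ms: float, terminated: bool) -> str:
    """Classify the ablation response at a driver site."""
    if terminated:
        return "termination"
    if post_cl_ms - pre_cl_ms >= CL_SLOWING_MS:
        return "cl_slowing"
    return "none"


def lvz_classify(bipolar_voltage_mV: float) -> bool:
    """Low-voltage zone: bipolar voltage strictly below 0.5 mV."""
    if bipolar_voltage_mV < 0:
        raise ValueError("bipolar voltage must be non-negative")
    return bipolar_voltage_mV < LVZ_THRESHOLD_MV


# ---------------------------------------------------------------------------
# accuracy statistics
# ---------------------------------------------------------------------------


def binomial_ci_exact(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) two-sided binomial confidence interval."""
    k, n = int(successes), int(trials)
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"invalid counts ({successes}, {trials})")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def binomial_ci_wilson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval (optional alternative to the exact interval)."""
    k, n = int(successes), int(trials)
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"invalid counts ({successes}, {trials})")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table ((a, b), (c, d)).

    Sums hypergeometric probabilities of all margin-fixed tables no more
    probable than the observed one.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cells must be non-negative integers")
    if a + b + c + d < 1:
        raise ValueError("table total must be >= 1")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass(frozen=True)
class RateEstimate:
    """A proportion with a two-sided 95% confidence interval."""

    successes: int
    trials: int
    point: float
    ci_low: float
    ci_high: float

    def as_printed(self) -> str:
        """e.g. '73 (54-88)' — integer percent, half-up."""
        return f"{percent(self.point)} ({percent(self.ci_low)}-{percent(self.ci_high)})"


def _rate(successes: int, trials: int, method: str = "exact") -> RateEstimate:
    ci = binomial_ci_exact if method == "exact" else binomial_ci_wilson
    lo, hi = ci(successes, trials)
    return RateEstimate(successes, trials, successes / trials, lo, hi)


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion counts and rates of detected sites vs reference drivers."""

    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: RateEstimate | None
    specificity: RateEstimate | None
    ppv: RateEstimate | None
    npv: RateEstimate | None
    sensitivity_undefined: bool = False

    def to_dict(self) -> dict:
        def rd(r: RateEstimate | None):
            if r is None:
                return None
            return {
                "successes": r.successes,
                "trials": r.trials,
                "point": round(r.point, 6),
                "ci": [round(r.ci_low, 6), round(r.ci_high, 6)],
                "printed": r.as_printed(),
            }

        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "sensitivity": rd(self.sensitivity),
            "specificity": rd(self.specificity),
            "ppv": rd(self.ppv),
            "npv": rd(self.npv),
            "sensitivity_undefined": self.sensitivity_undefined,
        }


def evaluate_detection(
    roi_sites: Sequence[Sequence[float]],
    reference_drivers: Sequence[Sequence[float]],
    control_sites: Sequence[Sequence[float]],
    threshold_mm: float = 10.0,
    ci_method: str = "exact",
) -> EvaluationResult:
    """Score detected sites against reference driver sites.

    True negatives are explicit control sites (the study never defines them);
    controls must be at least twice the correlation threshold away from every
    reference so the two classes cannot overlap.
    """
    refs = [np.asarray(r, dtype=float).reshape(3) for r in reference_drivers]
    rois = [np.asarray(r, dtype=float).reshape(3) for r in roi_sites]
    ctrls = [np.asarray(c, dtype=float).reshape(3) for c in control_sites]
    for c in ctrls:
        for r in refs:
            if np.linalg.norm(c - r) < 2.0 * threshold_mm:
                raise ValueError(
                    "control sites must be >= 2x threshold from every reference"
                )

    def hit(a, bs) -> bool:
        return any(correlate_sites(a, b, threshold_mm)[0] for b in bs)

    tp = sum(hit(r, rois) for r in refs)
    fn = len(refs) - tp
    fp = sum(not hit(s, refs) for s in rois)
    tn = sum(not hit(c, rois) for c in ctrls)

    sens = _rate(tp, len(refs), ci_method) if refs else None
    spec = _rate(tn, len(ctrls), ci_method) if ctrls else None
    ppv = _rate(tp, tp + fp, ci_method) if (tp + fp) > 0 else None
    npv = _rate(tn, tn + fn, ci_method) if (tn + fn) > 0 else None
    return EvaluationResult(
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        sensitivity_undefined=not refs,
    )
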