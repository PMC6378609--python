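"""The ROI algorithm: repetitive focal activation detection.

A site is a "region of interest" when one electrode shows, at least twice in
a row, an activation that (1) has QS unipolar morphology and (2) is earlier
than all of its neighboring electrodes. Per electrode the detector walks the
annotated events in time, tests each against both criteria within its local
cycle context, counts maximal runs of consecutive focal activations, and
emits a site when any run reaches ``min_consecutive`` (default 2). Nearby
sites are merged at the 10 mm scale used for site correlation, and sites from
sequential regional recordings are pooled by greedy centroid clustering at
the same radius.

A radial-spread check verifies the wavefront geometry of a candidate cycle:
all first-ring neighbors must activate after the source, and the second ring
on average later than the first (monotone outward timing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotate import QS, ActivationEvent, ChannelAnnotation

__all__ = [
    "ROIParams",
    "CycleContext",
    "FocalActivation",
    "ROISite",
    "WavefrontCheck",
    "associate_cycle",
    "focal_test",
    "detect_roi",
    "radial_spread_test",
    "aggregate_sequential",
    "roi_sites_to_rows",
]


@dataclass(frozen=True)
class ROIParams:
    """Detector tunables.

    min_consecutive
        Repetitions required before a run counts as an ROI occurrence.
    assoc_window_ms / pre_window_ms
        A neighbor's event is bound to a candidate at time t when it lies in
        ``(t - pre_window_ms, t + assoc_window_ms]``; the backward part lets a
        neighbor that fired just *before* the candidate veto "leading".
    lead_tol_ms
        Leading is strict: every bound neighbor offset must exceed this.
    min_valid_neighbors
        Candidates with fewer bound, quality-passed neighbors are ineligible.
    gap_factor
        Two focal activations continue one run when separated by at most
        ``gap_factor`` times the electrode's median cycle length.
    merge_radius_mm
        Sites closer than this merge into the one with most occurrences.
    """

    min_consecutive: int = 2
    assoc_window_ms: float = 50.0
    pre_window_ms: float = 20.0
    lead_tol_ms: float = 0.0
    min_valid_neighbors: int = 3
    gap_factor: float = 1.5
    merge_radius_mm: float = 10.0


@dataclass(frozen=True)
class CycleContext:
    """A candidate activation and its neighbors' bound activation times."""

    electrode_id: str
    lat: float
    neighbor_lats: dict[str, float]  # neighbor id -> bound lat (ms)

    @property
    def valid_neighbor_count(self) -> int:
        return len(self.neighbor_lats)

    @property
    def offsets_ms(self) -> dict[str, float]:
        return {k: v - self.lat for k, v in self.neighbor_lats.items()}


FOCAL = "focal"
NOT_FOCAL = "not_focal"
INELIGIBLE = "ineligible"


@dataclass(frozen=True)
class FocalActivation:
    """Outcome of the per-cycle focal test for one candidate event."""

    electrode_id: str
    lat: float
    qs: bool
    leading: bool
    status: str  # focal | not_focal | ineligible

    @property
    def is_focal(self) -> bool:
        return self.status == FOCAL


@dataclass
class ROISite:
    """A detected repetitive focal activation site (electrode resolution)."""

    electrode_id: str
    position: np.ndarray
    runs: list[int]  # counted consecutive-repetition run lengths
    first_lat: float
    last_lat: float

    @property
    def occurrences(self) -> int:
        return len(self.runs)

    @property
    def max_run(self) -> int:
        return max(self.runs) if self.runs else 0


@dataclass(frozen=True)
class WavefrontCheck:
    """Radial-spread verification around a source electrode for one cycle."""

    source: str
    ring1_offsets_ms: dict[str, float]
    ring2_offsets_ms: dict[str, float]
    radial: bool
    insufficient_coverage: bool = False


def _bind_neighbor(
    events: Sequence[ActivationEvent], t: float, pre_ms: float, assoc_ms: float
) -> float | None:
    """Earliest neighbor LAT in ``(t - pre_ms, t + assoc_ms]``, else None."""
    for e in events:  # events are time-ordered
        if e.lat > t + assoc_ms:
            return None
        if e.lat > t - pre_ms:
            return e.lat
    return None


def associate_cycle(
    annotations: Mapping[str, ChannelAnnotation],
    graph: Mapping[str, frozenset[str]],
    event: ActivationEvent,
    params: ROIParams | None = None,
) -> CycleContext:
    """Bind each quality-passed neighbor's activation for one candidate cycle."""
    params = params or ROIParams()
    bound: dict[str, float] = {}
    for nbr in sorted(graph.get(event.electrode_id, frozenset())):
        ann = annotations.get(nbr)
        if ann is None or not ann.passed:
            continue
        lat = _bind_neighbor(ann.events, event.lat, params.pre_window_ms, params.assoc_window_ms)
        if lat is not None:
            bound[nbr] = lat
    return CycleContext(event.electrode_id, event.lat, bound)


def focal_test(
    context: CycleContext, event: ActivationEvent, params: ROIParams | None = None
) -> FocalActivation:
    """Apply the two ROI criteria (QS morphology; strictly leading) to one cycle."""
    params = params or ROIParams()
    qs = event.morphology == QS
    if context.valid_neighbor_count < params.min_valid_neighbors:
        return FocalActivation(event.electrode_id, event.lat, qs, False, INELIGIBLE)
    leading = all(off > params.lead_tol_ms for off in context.offsets_ms.values())
    status = FOCAL if (qs and leading) else NOT_FOCAL
    return FocalActivation(event.electrode_id, event.lat, qs, leading, status)


def _electrode_runs(
    ann: ChannelAnnotation,
    annotations: Mapping[str, ChannelAnnotation],
    graph: Mapping[str, frozenset[str]],
    params: ROIParams,
) -> list[tuple[int, float, float]]:
    """Maximal focal runs on one electrode: (length, first_lat, last_lat)."""
    events = ann.events
    if len(events) < 2:
        return []
    intervals = np.diff([e.lat for e in events])
    median_cl = float(np.median(intervals))
    max_gap = params.gap_factor * median_cl

    runs: list[tuple[int, float, float]] = []
    run_len, run_start, prev_lat = 0, 0.0, None
    for e in events:
        fa = focal_test(associate_cycle(annotations, graph, e, params), e, params)
        if fa.is_focal and run_len > 0 and prev_lat is not None and e.lat - prev_lat <= max_gap:
            run_len += 1
        elif fa.is_focal:
            if run_len:
                runs.append((run_len, run_start, prev_lat))
            run_len, run_start = 1, e.lat
        else:
            if run_len:
                runs.append((run_len, run_start, prev_lat))
            run_len = 0
        if fa.is_focal:
            prev_lat = e.lat
    if run_len:
        runs.append((run_len, run_start, prev_lat))
    return runs


def detect_roi(
    annotations: Mapping[str, ChannelAnnotation],
    graph: Mapping[str, frozenset[str]],
    positions: Mapping[str, np.ndarray],
    params: ROIParams | None = None,
) -> list[ROISite]:
    """Detect ROI sites on one recording.

    Returns merged sites sorted by descending occurrences then electrode id.
    Recordings too short to contain two cycles yield an empty list.
    """
    params = params or ROIParams()
    sites: list[ROISite] = []
    for eid in sorted(annotations):
        ann = annotations[eid]
        if not ann.passed:
            continue
        runs = _electrode_runs(ann, annotations, graph, params)
        counted = [r for r in runs if r[0] >= params.min_consecutive]
        if not counted:
            continue
        sites.append(
            ROISite(
                electrode_id=eid,
                position=np.asarray(positions[eid], dtype=float),
                runs=[r[0] for r in counted],
                first_lat=min(r[1] for r in counted),
                last_lat=max(r[2] for r in counted),
            )
        )
    return _merge_sites(sites, params.merge_radius_mm)


def _merge_sites(sites: list[ROISite], merge_radius_mm: float) -> list[ROISite]:
    """Greedy merge: strongest site absorbs anything within the radius."""
    order = sorted(sites, key=lambda s: (-s.occurrences, -sum(s.runs), s.electrode_id))
    kept: list[ROISite] = []
    for s in order:
        for k in kept:
            if np.linalg.norm(s.position - k.position) < merge_radius_mm:
                k.runs = sorted(k.runs + s.runs, reverse=True)
                k.first_lat = min(k.first_lat, s.first_lat)
                k.last_lat = max(k.last_lat, s.last_lat)
                break
        else:
            kept.append(
                ROISite(s.electrode_id, s.position.copy(), list(s.runs), s.first_lat, s.last_lat)
            )
    return sorted(kept, key=lambda s: (-s.occurrences, s.electrode_id))


def radial_spread_test(
    annotations: Mapping[str, ChannelAnnotation],
    graph: Mapping[str, frozenset[str]],
    source: str,
    lat: float,
    params: ROIParams | None = None,
) -> WavefrontCheck:
    """Verify monotone outward timing around ``source`` for the cycle at ``lat``."""
    params = params or ROIParams()
    ring1 = {
        n
        for n in graph.get(source, frozenset())
        if n in annotations and annotations[n].passed
    }
    ring2 = set()
    for n in ring1:
        ring2 |= set(graph.get(n, frozenset()))
    ring2 -= ring1 | {source}
    ring2 = {n for n in ring2 if n in annotations and annotations[n].passed}

    def offsets(ring: set[str]) -> dict[str, float]:
        out = {}
        for n in sorted(ring):
            t = _bind_neighbor(
                annotations[n].events, lat, params.pre_window_ms, params.assoc_window_ms * 2
            )
            if t is not None:
                out[n] = t - lat
        return out

    o1, o2 = offsets(ring1), offsets(ring2)
    if len(o1) < params.min_valid_neighbors or not o2:
        return WavefrontCheck(source, o1, o2, radial=False, insufficient_coverage=True)
    radial = all(v > 0 for v in o1.values()) and (
        float(np.mean(list(o2.values()))) > float(np.mean(list(o1.values())))
    )
    return WavefrontCheck(source, o1, o2, radial=radial)


def aggregate_sequential(
    sites: Sequence[ROISite], merge_radius_mm: float = 10.0
) -> list[ROISite]:
    """Pool per-recording sites from sequential maps by centroid clustering.

    Sites join the nearest existing cluster whose centroid is within
    ``merge_radius_mm``; clusters keep pooled runs and the member centroid.
    """
    order = sorted(sites, key=lambda s: (-s.occurrences, s.electrode_id, s.first_lat))
    clusters: list[dict] = []
    for s in order:
        best, best_d = None, np.inf
        for c in clusters:
            d = float(np.linalg.norm(s.position - c["centroid"]))
            if d < merge_radius_mm and d < best_d:
                best, best_d = c, d
        if best is None:
            clusters.append(
                {
                    "members": [s],
                    "centroid": s.position.astype(float).copy(),
                    "electrode_id": s.electrode_id,
                }
            )
        else:
            best["members"].append(s)
            pts = np.array([m.position for m in best["members"]])
            best["centroid"] = pts.mean(axis=0)
    out = []
    for c in clusters:
        members = c["members"]
        runs = sorted((r for m in members for r in m.runs), reverse=True)
        out.append(
            ROISite(
                electrode_id=c["electrode_id"],
                position=c["centroid"],
                runs=runs,
                first_lat=min(m.first_lat for m in members),
                last_lat=max(m.last_lat for m in members),
            )
        )
    return sorted(out, key=lambda s: (-s.occurrences, s.electrode_id))


def roi_sites_to_rows(sites: Sequence[ROISite]) -> list[dict]:
    """Flatten sites for CSV/JSON export (deterministic field order)."""
    rows = []
    for i, s in enumerate(sites):
        rows.append(
            {
                "site_id": i,
                "electrode_id": s.electrode_id,
                "x": round(float(s.position[0]), 3),
                "y": round(float(s.position[1]), 3),
                "z": round(float(s.position[2]), 3),
                "occurrences": s.occurrences,
                "max_run": s.max_run,
                "runs": ";".join(str(r) for r in s.runs),
                "first_ms": round(s.first_lat, 3),
                "last_ms": round(s.last_lat, 3),
            }
        )
    return rows
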