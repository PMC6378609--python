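import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from roifinder import make_basket_array, simulate_recording, run_roi_pipeline
from roifinder.annotate import ActivationEvent, ChannelAnnotation, classify_morphology
from roifinder.geometry import AtrialSurface

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def basket():
    return make_basket_array()


@pytest.fixture(scope="session")
def sphere():
    return AtrialSurface()


@pytest.fixture(scope="session")
def focal_sim():
    """One focal tachycardia recording (cycle length 250 ms) reused suite-wide."""
    return simulate_recording("focal_at", seed=1, cycle_length_ms=250.0)


@pytest.fixture(scope="session")
def focal_pipeline(focal_sim):
    return run_roi_pipeline(focal_sim.recording)


def make_annotation(
    electrode_id: str, lats, morphology: str = "non_QS", passed: bool = True
) -> ChannelAnnotation:
    """Fabricate a gated channel annotation for detector unit tests."""
    morphs = [morphology] * len(lats) if isinstance(morphology, str) else list(morphology)
    events = []
    for lat, m in zip(sorted(lats), morphs):
        r, s = (0.0, 1.0) if m == "QS" else (0.4, 0.6)
        label, rf, _ = classify_morphology(r, s)
        assert label == m
        events.append(
            ActivationEvent(electrode_id, float(lat), 0.2, r, s, rf, morphology=label)
        )
    return ChannelAnnotation(
        electrode_id=electrode_id,
        events=events if passed else [],
        passed=passed,
        reasons=frozenset() if passed else frozenset({"low_snr"}),
        snr=20.0,
        beat_count=len(lats),
        dominant_frequency=5.0,
    )


def grid_positions():
    """3x3 electrode grid, 8 mm pitch, center electrode 'e5'."""
    ids = [f"e{i}" for i in range(1, 10)]
    pos = {}
    for i, eid in enumerate(ids):
        r, c = divmod(i, 3)
        pos[eid] = np.array([8.0 * c, 8.0 * r, 0.0])
    graph = {eid: set() for eid in ids}
    for i, a in enumerate(ids):
        ra, ca = divmod(i, 3)
        for j, b in enumerate(ids):
            rb, cb = divmod(j, 3)
            if abs(ra - rb) + abs(ca - cb) == 1:
                graph[a].add(b)
    return ids, pos, {k: frozenset(v) for k, v in graph.items()}
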