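"""End-to-end convenience: filter -> annotate -> gate -> detect ROI."""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import AnnotationParams, ChannelAnnotation, QualityThresholds, annotate_recording
from .geometry import neighbor_graph
from .preprocess import FilterSpec, filter_unipolar
from .roi import ROIParams, ROISite, detect_roi
from .signal_io import UnipolarRecording

__all__ = ["PipelineConfig", "PipelineResult", "run_roi_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the detection pipeline in one document."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    quality: QualityThresholds = field(default_factory=QualityThresholds)
    roi: ROIParams = field(default_factory=ROIParams)
    neighbor_mode: str = "structural"
    neighbor_radius_mm: float | None = None


@dataclass
class PipelineResult:
    annotations: dict[str, ChannelAnnotation]
    sites: list[ROISite]


def run_roi_pipeline(
    recording: UnipolarRecording, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the full detection chain on one raw recording."""
    config = config or PipelineConfig()
    filtered = filter_unipolar(recording, config.filter)
    annotations = annotate_recording(filtered, config.annotation, config.quality)
    graph = neighbor_graph(recording.array, config.neighbor_mode, config.neighbor_radius_mm)
    sites = detect_roi(annotations, graph, recording.array.positions(), config.roi)
    return PipelineResult(annotations, sites)
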