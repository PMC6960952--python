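"""End-to-end detection pipeline: denoise → gravity removal → segmentation →
double integration + detrend → trough-based event determination."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

from .config import PipelineConfig, default_config
from .denoise import denoise_recording
from .events import detect_all
from .integration import acceleration_to_displacement
from .segmentation import segment_recording
from .signal_io import AccelerometerRecording, GaitEventSequence

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    events: GaitEventSequence
    heel_trace: object
    toe_trace: object
    heel_seg: object
    toe_seg: object
    timings_s: dict


def detect_events(
    heel: AccelerometerRecording,
    toe: AccelerometerRecording,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on a heel and a toe recording."""
    cfg = config or default_config()
    timings = {}

    tic = time.perf_counter()
    heel_dn = denoise_recording(heel, cfg.denoise)
    toe_dn = denoise_recording(toe, cfg.denoise)
    timings["denoise"] = time.perf_counter() - tic

    tic = time.perf_counter()
    heel_seg = segment_recording(heel_dn, cfg.segmentation)
    toe_seg = segment_recording(toe_dn, cfg.segmentation)
    timings["segmentation"] = time.perf_counter() - tic
    for site, seg in (("heel", heel_seg), ("toe", toe_seg)):
        logger.info(
            "%s segmentation: threshold=%.4g, %d flat / %d non-flat intervals",
            site, seg.threshold_used, len(seg.flat_intervals), len(seg.nonflat_intervals),
        )

    tic = time.perf_counter()
    # vertical axes were already denoised above; integrate them directly
    heel_trace = acceleration_to_displacement(heel_dn, cfg.integration)
    toe_trace = acceleration_to_displacement(toe_dn, cfg.integration)
    timings["integration"] = time.perf_counter() - tic

    tic = time.perf_counter()
    events = detect_all(heel_trace, toe_trace, heel_seg, toe_seg, cfg.events)
    timings["events"] = time.perf_counter() - tic
    logger.info("detected %d events (%d cycles)", len(events), len(events) // 4)

    return PipelineResult(
        events=events,
        heel_trace=heel_trace,
        toe_trace=toe_trace,
        heel_seg=heel_seg,
        toe_seg=toe_seg,
        timings_s=timings,
    )
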