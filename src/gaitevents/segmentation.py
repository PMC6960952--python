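"""Flat/non-flat phase segmentation from the jerk magnitude.

While the foot is flat on the ground the sensor is nearly static and the
comprehensive change rate of acceleration (the Euclidean norm of the per-axis
first differences — a discrete jerk magnitude) is small; during swing and at
the impact/lift-off transients it is large.  Smoothing that rate with a short
trailing window and thresholding at a fraction ``r`` of its maximum yields a
binary flat(0)/non-flat(1) function whose runs are the candidate stance and
swing intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateSignalError, ParameterError, ShapeError

__all__ = [
    "PhaseSegmentation",
    "jerk_magnitude",
    "smooth",
    "binarize",
    "filter_short_segments",
    "segment_recording",
]


@dataclass
class PhaseSegmentation:
    """Binary phase function and its run-length intervals.

    ``binary`` has one entry per jerk sample (N-1 for an N-sample recording);
    ``flat_intervals`` / ``nonflat_intervals`` are half-open [start, end)
    index pairs that tile [0, len(binary)) without overlap.
    """

    binary: np.ndarray
    threshold_used: float
    r: float
    flat_intervals: list = field(default_factory=list)
    nonflat_intervals: list = field(default_factory=list)

    def __post_init__(self):
        self.binary = np.asarray(self.binary, dtype=np.int8)
        if not self.flat_intervals and not self.nonflat_intervals:
            self.flat_intervals, self.nonflat_intervals = _intervals(self.binary)

    @property
    def n(self) -> int:
        return len(self.binary)

    @property
    def flat_fraction(self) -> float:
        return float(np.mean(self.binary == 0))


def _intervals(binary):
    """Run-length encode a binary sequence into flat/non-flat intervals."""
    flat, nonflat = [], []
    n = len(binary)
    start = 0
    for i in range(1, n + 1):
        if i == n or binary[i] != binary[start]:
            (flat if binary[start] == 0 else nonflat).append((start, i))
            start = i
    return flat, nonflat


def jerk_magnitude(ax, ay, az) -> np.ndarray:
    """Comprehensive change rate of acceleration: per-sample forward
    differences combined across the three axes, ``len(out) == N - 1``."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (len(ax) == len(ay) == len(az)):
        raise ShapeError("axis sequences differ in length")
    if len(ax) < 2:
        raise ShapeError("need at least 2 samples to difference")
    return np.sqrt(np.diff(ax) ** 2 + np.diff(ay) ** 2 + np.diff(az) ** 2)


def smooth(ja, fs: float, window_ms: float = 30.0) -> np.ndarray:
    """Trailing moving average over ``window_ms``; the leading samples use
    the truncated available window so the output keeps full length."""
    ja = np.asarray(ja, dtype=float)
    if window_ms <= 0:
        raise ParameterError(f"window_ms must be positive, got {window_ms}")
    w = max(1, int(round(window_ms * fs / 1000.0)))
    c = np.concatenate(([0.0], np.cumsum(ja)))
    idx = np.arange(len(ja))
    lo = np.maximum(idx - w + 1, 0)
    return (c[idx + 1] - c[lo]) / (idx + 1 - lo)


def binarize(ja, r: float) -> PhaseSegmentation:
    """Threshold the smoothed jerk at ``r * max(ja)``; a sample is non-flat
    iff it strictly exceeds the threshold."""
    ja = np.asarray(ja, dtype=float)
    if not 0 < r < 1:
        raise ParameterError(f"r must lie in (0, 1), got {r}")
    if ja.size == 0:
        raise DegenerateSignalError("empty jerk sequence")
    mx = float(np.max(ja))
    if mx <= 0:
        raise DegenerateSignalError(
            "all-zero jerk signal: threshold r*max would be 0"
        )
    thresh = r * mx
    binary = (ja > thresh).astype(np.int8)
    return PhaseSegmentation(binary=binary, threshold_used=thresh, r=r)


def filter_short_segments(seg: PhaseSegmentation, min_ms: float, fs: float) -> PhaseSegmentation:
    """Absorb interior runs shorter than ``min_ms`` into their neighbours.

    The first and last runs are left untouched (they may be genuine partial
    phases at the record boundary).  Runs are merged shortest-first until no
    interior run is below the minimum, preserving the tiling invariant.
    """
    if min_ms < 0:
        raise ParameterError("min_ms must be >= 0")
    min_samples = int(round(min_ms * fs / 1000.0))
    binary = np.array(seg.binary, dtype=np.int8)
    while True:
        flat, nonflat = _intervals(binary)
        runs = sorted(flat + nonflat)
        interior = [
            (e - s, s, e)
            for (s, e) in runs[1:-1]
            if e - s < min_samples
        ]
        if not interior:
            break
        _, s, e = min(interior)
        binary[s:e] = 1 - binary[s]
    return PhaseSegmentation(binary=binary, threshold_used=seg.threshold_used, r=seg.r)


def segment_recording(rec, cfg) -> PhaseSegmentation:
    """jerk -> smooth -> binarize -> short-run filtering for one recording."""
    ja = jerk_magnitude(rec.ax, rec.ay, rec.az)
    js = smooth(ja, rec.fs, window_ms=cfg.window_ms)
    seg = binarize(js, r=cfg.r)
    return filter_short_segments(seg, min_ms=cfg.min_segment_ms, fs=rec.fs)
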