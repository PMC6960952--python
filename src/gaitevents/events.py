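"""Gait-event determination from displacement troughs.

Within each flat (foot-on-ground) interval of the jerk segmentation — widened
by a small search margin, because the displacement minimum at impact slightly
precedes the jerk-quiet region — the detector examines the strict local
minima of the detrended vertical displacement:

* the strike event (HS for the heel sensor, TS for the toe) is the first
  trough into which the displacement *drops sharply* (mean slope over the
  preceding window at or below ``-drop_slope_thresh``);
* the off event (HO / TO) is the first trough after the strike out of which
  the displacement *rises sharply* (mean slope over the following window at
  or above ``+rise_slope_thresh``).

"Sharply" is quantified as a mean slope over ``slope_window_ms`` because the
qualitative criterion needs a number; both the window and the thresholds are
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DetectionError, IntervalError, ParameterError
from .signal_io import GaitEvent, GaitEventSequence

logger = logging.getLogger(__name__)

__all__ = [
    "TroughCandidate",
    "find_troughs",
    "detect_strike",
    "detect_off",
    "detect_all",
]


@dataclass(frozen=True)
class TroughCandidate:
    """A strict local displacement minimum with its flanking mean slopes."""

    sample_index: int
    value: float
    pre_slope: float   # m/s over the preceding window
    post_slope: float  # m/s over the following window


def find_troughs(d, interval, slope_window_ms: float, fs: float):
    """All strict local minima of ``d`` inside half-open ``interval``,
    annotated with mean slopes over ``slope_window_ms`` on each side."""
    d = np.asarray(d, dtype=float)
    if slope_window_ms <= 0:
        raise ParameterError("slope_window_ms must be positive")
    start, end = int(interval[0]), int(interval[1])
    if start < 0 or end > len(d):
        raise IntervalError(f"interval {interval} outside signal bounds")
    if end - start < 3:
        raise IntervalError(f"interval {interval} shorter than 3 samples")
    w = max(1, int(round(slope_window_ms * fs / 1000.0)))
    seg = d[start:end]
    rel = np.where((seg[1:-1] < seg[:-2]) & (seg[1:-1] < seg[2:]))[0] + 1
    out = []
    for i in rel + start:
        lo = max(0, i - w)
        hi = min(len(d) - 1, i + w)
        pre = (d[i] - d[lo]) / ((i - lo) / fs) if i > lo else 0.0
        post = (d[hi] - d[i]) / ((hi - i) / fs) if hi > i else 0.0
        out.append(TroughCandidate(int(i), float(d[i]), float(pre), float(post)))
    return out


def _make_event(label, index, fs, t0):
    return GaitEvent(label=label, time=t0 + index / fs, sample_index=int(index))


def detect_strike(candidates, drop_slope_thresh: float, label: str, fs: float, t0: float = 0.0) -> GaitEvent:
    """First trough whose preceding slope is at or below the drop threshold."""
    if not candidates:
        raise DetectionError("no trough candidates", candidates)
    for c in candidates:
        if c.pre_slope <= -drop_slope_thresh:
            return _make_event(label, c.sample_index, fs, t0)
    raise DetectionError(
        f"no candidate drops sharply enough for {label} "
        f"(threshold {drop_slope_thresh} m/s)",
        candidates,
    )


def detect_off(candidates, rise_slope_thresh: float, label: str, fs: float,
               after_index: int = -1, t0: float = 0.0) -> GaitEvent:
    """First trough after ``after_index`` whose following slope is at or
    above the rise threshold."""
    if not candidates:
        raise DetectionError("no trough candidates", candidates)
    for c in candidates:
        if c.sample_index <= after_index:
            continue
        if c.post_slope >= rise_slope_thresh:
            return _make_event(label, c.sample_index, fs, t0)
    raise DetectionError(
        f"no candidate rises sharply enough for {label} "
        f"(threshold {rise_slope_thresh} m/s)",
        candidates,
    )


def _site_events(trace, seg, cfg, strike_label, off_label):
    """Per flat interval: one strike and one off event for a single site."""
    fs = trace.fs
    margin = int(round(cfg.search_margin_ms * fs / 1000.0))
    d = trace.detrended
    n = len(d)
    pairs = []
    for (s, e) in seg.flat_intervals:
        if s <= 0 or e >= seg.n:  # partial boundary interval
            continue
        lo = max(0, s - margin)
        hi = min(n, e + margin)
        try:
            cands = find_troughs(d, (lo, hi), cfg.slope_window_ms, fs)
            strike = detect_strike(
                cands, cfg.drop_slope_thresh, strike_label, fs, t0=0.0
            )
            off = detect_off(
                cands,
                cfg.rise_slope_thresh,
                off_label,
                fs,
                after_index=strike.sample_index,
                t0=0.0,
            )
        except (DetectionError, IntervalError) as exc:
            logger.warning(
                "skipping flat interval [%d, %d) of %s: %s", s, e, trace.site, exc
            )
            continue
        pairs.append((strike, off))
    return pairs


def detect_all(heel_trace, toe_trace, heel_seg, toe_seg, cfg) -> GaitEventSequence:
    """Assemble HS/TS/HO/TO cycles from heel and toe traces.

    Heel flat intervals yield (HS, HO); toe flat intervals yield (TS, TO).
    A cycle is the heel pair plus the first toe pair starting at or after the
    HS and before the next HS; cycles violating HS <= TS <= HO <= TO are
    discarded with a warning, as are incomplete boundary cycles.
    """
    if heel_trace.fs != toe_trace.fs:
        raise ParameterError("heel and toe traces must share the sampling rate")
    heel_pairs = _site_events(heel_trace, heel_seg, cfg, "HS", "HO")
    toe_pairs = _site_events(toe_trace, toe_seg, cfg, "TS", "TO")
    if not heel_pairs and not toe_pairs:
        logger.warning("no flat intervals yielded events; empty sequence")
        return GaitEventSequence([])

    events = []
    heel_pairs.sort(key=lambda p: p[0].time)
    toe_pairs.sort(key=lambda p: p[0].time)
    for k, (hs, ho) in enumerate(heel_pairs):
        upper = heel_pairs[k + 1][0].time if k + 1 < len(heel_pairs) else np.inf
        toe_in_cycle = [
            (ts, to) for ts, to in toe_pairs if hs.time <= ts.time < upper
        ]
        if not toe_in_cycle:
            logger.warning("cycle at HS=%.3f s has no toe events; dropped", hs.time)
            continue
        ts, to = toe_in_cycle[0]
        if not (hs.time <= ts.time <= ho.time <= to.time):
            logger.warning(
                "cycle at HS=%.3f s violates HS<=TS<=HO<=TO "
                "(TS=%.3f HO=%.3f TO=%.3f); dropped",
                hs.time, ts.time, ho.time, to.time,
            )
            continue
        events.extend([hs, ts, ho, to])
    return GaitEventSequence(events)
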