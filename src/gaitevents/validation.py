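"""Agreement between detected and reference gait events.

Pairs events per label by greedy nearest-time matching, summarises the
per-event time differences, and runs the Bland–Altman consistency analysis
(mean difference and 95 % limits of agreement, mean ± 1.96 SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SampleSizeError
from .signal_io import EVENT_LABELS

__all__ = [
    "BlandAltmanResult",
    "match_events",
    "bland_altman",
    "summarize_errors",
    "validation_report",
]


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    outside_count: int
    outside_fraction: float


@dataclass
class MatchResult:
    """Per-label matched (detected, reference) pairs plus leftovers."""

    pairs: dict          # label -> list of (detected GaitEvent, reference GaitEvent)
    unmatched_detected: dict
    unmatched_reference: dict

    def diffs(self, label=None) -> np.ndarray:
        """Detected-minus-reference time differences in seconds."""
        labels = EVENT_LABELS if label is None else (label,)
        out = []
        for lab in labels:
            out.extend(d.time - r.time for d, r in self.pairs.get(lab, []))
        return np.asarray(out, dtype=float)

    @property
    def n_matched(self) -> int:
        return sum(len(v) for v in self.pairs.values())


def match_events(detected, reference, max_gap_ms: float = 100.0) -> MatchResult:
    """Greedy nearest-time 1:1 matching within each label.

    Candidate pairs are taken closest-first; each event is used at most once
    and pairs farther apart than ``max_gap_ms`` are never formed.
    """
    max_gap = max_gap_ms / 1000.0
    pairs, un_det, un_ref = {}, {}, {}
    for lab in EVENT_LABELS:
        det = detected.with_label(lab)
        ref = reference.with_label(lab)
        cand = sorted(
            (abs(d.time - r.time), i, j)
            for i, d in enumerate(det)
            for j, r in enumerate(ref)
            if abs(d.time - r.time) <= max_gap
        )
        used_d, used_r = set(), set()
        matched = []
        for _, i, j in cand:
            if i in used_d or j in used_r:
                continue
            used_d.add(i)
            used_r.add(j)
            matched.append((det[i], ref[j]))
        matched.sort(key=lambda p: p[0].time)
        if matched:
            pairs[lab] = matched
        left_d = [d for i, d in enumerate(det) if i not in used_d]
        left_r = [r for j, r in enumerate(ref) if j not in used_r]
        if left_d:
            un_det[lab] = left_d
        if left_r:
            un_ref[lab] = left_r
    return MatchResult(pairs=pairs, unmatched_detected=un_det, unmatched_reference=un_ref)


def bland_altman(diffs) -> BlandAltmanResult:
    """Bland–Altman statistics of a difference sample (n-1 SD, 95 % limits)."""
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    if n < 2:
        raise SampleSizeError(f"need at least 2 differences, got {n}")
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    outside = int(np.sum((diffs < lo) | (diffs > hi)))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
        n=n,
        outside_count=outside,
        outside_fraction=outside / n,
    )


def summarize_errors(match: MatchResult) -> pd.DataFrame:
    """Per-label table of n, mean, SD, median and MAE of the time differences
    (seconds).  Labels without pairs are omitted."""
    rows = []
    for lab in EVENT_LABELS:
        pairs = match.pairs.get(lab, [])
        if not pairs:
            continue
        d = np.array([p.time - r.time for p, r in pairs])
        rows.append(
            {
                "label": lab,
                "n": len(d),
                "mean_dt_s": float(np.mean(d)),
                "sd_dt_s": float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
                "median_dt_s": float(np.median(d)),
                "mae_s": float(np.mean(np.abs(d))),
            }
        )
    return pd.DataFrame(rows, columns=["label", "n", "mean_dt_s", "sd_dt_s", "median_dt_s", "mae_s"])


def validation_report(detected, reference, max_gap_ms: float = 100.0) -> pd.DataFrame:
    """Per-label summary plus pooled Bland–Altman fields in one table."""
    match = match_events(detected, reference, max_gap_ms=max_gap_ms)
    table = summarize_errors(match)
    diffs = match.diffs()
    if len(diffs) >= 2:
        ba = bland_altman(diffs)
        table.attrs["bland_altman"] = ba
        pooled = pd.DataFrame(
            [
                {
                    "label": "ALL",
                    "n": ba.n,
                    "mean_dt_s": ba.mean_diff,
                    "sd_dt_s": ba.sd_diff,
                    "median_dt_s": float(np.median(diffs)),
                    "mae_s": float(np.mean(np.abs(diffs))),
                }
            ]
        )
        table = pd.concat([table, pooled], ignore_index=True)
        table.attrs["bland_altman"] = ba
    return table


def plot_histograms(match: MatchResult, path) -> None:
    """Per-label histograms of the time differences (ms)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(8, 6))
    for ax, lab in zip(axes.ravel(), EVENT_LABELS):
        d = 1000.0 * np.array([p.time - r.time for p, r in match.pairs.get(lab, [])])
        if len(d):
            ax.hist(d, bins=15, color="steelblue", edgecolor="black")
        ax.set_title(lab)
        ax.set_xlabel("time difference (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_bland_altman(match: MatchResult, path) -> None:
    """Bland–Altman scatter per label with 95 % limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(8, 6))
    for ax, lab in zip(axes.ravel(), EVENT_LABELS):
        pairs = match.pairs.get(lab, [])
        ax.set_title(lab)
        ax.set_xlabel("mean time (s)")
        ax.set_ylabel("difference (s)")
        if len(pairs) >= 2:
            means = np.array([(p.time + r.time) / 2 for p, r in pairs])
            diffs = np.array([p.time - r.time for p, r in pairs])
            ba = bland_altman(diffs)
            ax.scatter(means, diffs, s=12)
            for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
                ax.axhline(y, linestyle=style, color="gray")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
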