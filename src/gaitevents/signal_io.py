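"""Plain-CSV input/output for accelerometer recordings and gait events.

The interchange dialect is deliberately minimal: comma-separated, one header
line, ``.`` decimal separator.  Recordings carry an optional leading ``time``
column which, when present, is checked for uniform spacing consistent with the
declared sampling frequency.  Times are seconds, sample indices are 0-based,
and intervals throughout the package are half-open ``[start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    ParameterError,
    ParseError,
    SamplingError,
    ShapeError,
)

SITES = ("heel", "toe")
EVENT_LABELS = ("HS", "TS", "HO", "TO")


@dataclass
class AccelerometerRecording:
    """Uniformly sampled tri-axial acceleration for one sensor site.

    The vertical axis is ``az``; sample ``i`` occurs at time ``t0 + i / fs``.
    """

    site: str
    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        if self.site not in SITES:
            raise ParameterError(f"site must be one of {SITES}, got {self.site!r}")
        if not self.fs > 0:
            raise SamplingError(f"sampling frequency must be positive, got {self.fs}")
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.az)
        if not (len(self.ax) == len(self.ay) == n):
            raise ShapeError(
                f"axis length mismatch: ax={len(self.ax)} ay={len(self.ay)} az={n}"
            )
        if n < 2:
            raise ShapeError(f"recording needs at least 2 samples, got {n}")
        for name, arr in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"non-finite value in {name}")

    @property
    def n(self) -> int:
        return len(self.az)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def duration(self) -> float:
        return self.n / self.fs


@dataclass(frozen=True)
class GaitEvent:
    """One labelled gait event: HS, TS, HO or TO at a time in seconds."""

    label: str
    time: float
    sample_index: int

    def __post_init__(self):
        if self.label not in EVENT_LABELS:
            raise FormatError(f"unknown event label {self.label!r}")
        if self.sample_index < 0:
            raise FormatError(f"negative sample index {self.sample_index}")


@dataclass
class GaitEventSequence:
    """Time-ordered gait events; one cycle runs HS ≤ TS ≤ HO ≤ TO."""

    events: list = field(default_factory=list)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e.time, EVENT_LABELS.index(e.label)))

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def with_label(self, label: str) -> list:
        return [e for e in self.events if e.label == label]

    def times(self, label: str | None = None) -> np.ndarray:
        evs = self.events if label is None else self.with_label(label)
        return np.array([e.time for e in evs], dtype=float)

    def cycles(self) -> list:
        """Group events into (HS, TS, HO, TO) quadruples anchored on HS."""
        out = []
        hs = self.with_label("HS")
        for k, h in enumerate(hs):
            upper = hs[k + 1].time if k + 1 < len(hs) else math.inf
            cyc = {"HS": h}
            for lab in ("TS", "HO", "TO"):
                cand = [e for e in self.with_label(lab) if h.time <= e.time < upper]
                if cand:
                    cyc[lab] = cand[0]
            if len(cyc) == 4:
                out.append((cyc["HS"], cyc["TS"], cyc["HO"], cyc["TO"]))
        return out


def _read_numeric_csv(path, expected_cols):
    try:
        df = pd.read_csv(path, header=0, dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas internal failures
        raise ParseError(f"{path}: could not read CSV: {exc}") from exc
    if df.shape[1] not in expected_cols:
        raise FormatError(
            f"{path}: expected {expected_cols} columns, found {df.shape[1]}"
        )
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.where(converted.isna().to_numpy())[0]
        if bad.size:
            # +2: one for the header line, one for 1-based file rows
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at file row {bad[0] + 2}"
            )
        values[:, j] = converted.to_numpy()
    return values


def read_recording(path, site: str, fs: float) -> AccelerometerRecording:
    """Read a tri-axial recording from CSV with 3 or 4 numeric columns.

    A 4-column file has a leading time column; its spacing must agree with
    ``1/fs`` within 1 % relative tolerance.
    """
    values = _read_numeric_csv(path, expected_cols=(3, 4))
    if values.shape[0] < 2:
        raise FormatError(f"{path}: need at least 2 data rows, found {values.shape[0]}")
    t0 = 0.0
    if values.shape[1] == 4:
        t = values[:, 0]
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise SamplingError(f"{path}: time column is not strictly increasing")
        if np.max(np.abs(dt - 1.0 / fs)) > 0.01 / fs:
            raise SamplingError(
                f"{path}: time steps inconsistent with fs={fs} Hz "
                f"(median step {np.median(dt):.6g} s)"
            )
        t0 = float(t[0])
        values = values[:, 1:]
    return AccelerometerRecording(
        site=site, fs=fs, t0=t0, ax=values[:, 0], ay=values[:, 1], az=values[:, 2]
    )


def write_recording(rec: AccelerometerRecording, path) -> None:
    df = pd.DataFrame(
        {"time": rec.times, "ax": rec.ax, "ay": rec.ay, "az": rec.az}
    )
    df.to_csv(path, index=False, float_format="%.9f")


def write_events(seq: GaitEventSequence, path) -> None:
    df = pd.DataFrame(
        {
            "label": [e.label for e in seq],
            "time": [e.time for e in seq],
            "sample_index": [e.sample_index for e in seq],
        }
    )
    df.to_csv(path, index=False, float_format="%.9f")


def read_events(path) -> GaitEventSequence:
    df = pd.read_csv(path, header=0, dtype={"label": str})
    required = {"label", "time", "sample_index"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    events = []
    for i, row in df.iterrows():
        lab = str(row["label"])
        if lab not in EVENT_LABELS:
            raise FormatError(
                f"{path}: unknown event label {lab!r} at file row {i + 2}"
            )
        try:
            events.append(
                GaitEvent(label=lab, time=float(row["time"]), sample_index=int(row["sample_index"]))
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed event at file row {i + 2}") from exc
    return GaitEventSequence(events=events)


def write_displacement(times: np.ndarray, disp: np.ndarray, path) -> None:
    """Write a reference displacement series (time, displacement in m)."""
    if len(times) != len(disp):
        raise ShapeError("times and displacement differ in length")
    pd.DataFrame({"time": times, "disp": disp}).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_displacement(path):
    values = _read_numeric_csv(path, expected_cols=(2,))
    return values[:, 0], values[:, 1]
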