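"""Synthetic treadmill-gait trials with exact ground truth.

The generator emulates the kinematics of heel- and toe-mounted sensors during
steady treadmill walking (about 1.2 m/s, 1 s cycles): each foot point rests
on the ground during its contact phase and travels a smooth arc during swing.
Vertical displacement per cycle is a C² quintic-Hermite curve with

* a swing arc rising to the configured peak (15 cm heel, 5 cm toe),
* a sub-millimetre impact dip whose minimum falls exactly on the strike
  instant (heel pads and shoe soles compress over ~20 ms at impact), and
* a matching dip with its minimum exactly at the lift-off instant, the last
  moment before the displacement rises into swing.

Acceleration is the second difference of that displacement times fs², plus
gravity (9.81 m/s²), white sensor noise on the vertical axis and a slow
sinusoidal drift (0.05 Hz) emulating bias wander.  The horizontal axes carry
small correlated oscillations (about 10 % of the vertical dynamic range) so
that the three-axis jerk magnitude is exercised.

A quarter-cycle lead-in and lead-out pad the record so that every one of the
``n_cycles`` cycles is interior — detectors drop partial boundary cycles, and
a trial whose first heel strike sits on sample 0 would otherwise always lose
its first cycle.  Ground-truth event times are the exact phase instants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BPoly

from .exceptions import ParameterError
from .signal_io import AccelerometerRecording, GaitEvent, GaitEventSequence

__all__ = ["GaitParams", "SyntheticTrial", "heel_toe_trajectories", "make_trial"]

GRAVITY = 9.81

# Impact/lift-off transient shape (fractions of the cycle / metres):
# ~20 ms transients and 0.8 mm dips at a 1 s cycle; see docs/methods.md.
_DIP_M = 0.0008
_TRANSIENT_FRAC = 0.02
_IMPACT_CURVATURE = 20.0  # d2h/dphi2 at the trough bottom (m per cycle^2)
# Lead-in/lead-out padding: the subject stands, lifts into a swing that lands
# on cycle 0's strike, walks n_cycles strides, and returns to standing.  The
# padding keeps every ground-truth cycle clear of the integrator/detrender
# warm-up at the record edges, the way treadmill protocols discard the
# first and last strides.
_LEAD_FRAC = 1.5
# Soft-tissue/limb oscillation during swing: ~2 mm with two incommensurate
# components (8 and 12.5 cycles per gait cycle), windowed to vanish at the
# swing ends — real foot sensors show 5-15 Hz content in swing and
# near-silence in mid-stance.
_RIPPLE_M = 0.002
_RIPPLE_COMPONENTS = ((8.0, 1.0, 0.0), (12.5, 0.6, 1.0))  # (per-cycle f, rel amp, phase)


@dataclass
class GaitParams:
    """Generator parameters; defaults emulate 1.2 m/s treadmill walking
    recorded at 1000 Hz with a 100 Hz reference."""

    cycle_s: float = 1.0
    n_cycles: int = 10
    stance_fraction: float = 0.6
    swing_peak_heel_m: float = 0.15
    swing_peak_toe_m: float = 0.05
    event_phases: tuple = (0.0, 0.12, 0.45, 0.62)  # HS, TS, HO, TO
    noise_sigma: float = 0.2  # m/s^2
    drift_amp: float = 0.1    # m/s^2
    fs_accel: float = 1000.0
    fs_ref: float = 100.0
    seed: int = 0

    def __post_init__(self):
        hs, ts, ho, to = self.event_phases
        if not (0 <= hs < ts < ho < to < 1):
            raise ParameterError(
                f"event phases must satisfy 0 <= HS < TS < HO < TO < 1, got {self.event_phases}"
            )
        if self.cycle_s <= 0 or self.n_cycles < 1:
            raise ParameterError("cycle_s must be > 0 and n_cycles >= 1")
        if not 0 < self.stance_fraction < 1:
            raise ParameterError("stance_fraction must lie in (0, 1)")
        if min(self.swing_peak_heel_m, self.swing_peak_toe_m) < 0:
            raise ParameterError("swing peaks must be >= 0")
        if self.noise_sigma < 0 or self.drift_amp < 0:
            raise ParameterError("noise_sigma and drift_amp must be >= 0")
        if self.fs_accel < 2 * self.fs_ref:
            raise ParameterError("fs_accel must be at least 2 * fs_ref")
        ratio = self.fs_accel / self.fs_ref
        if abs(ratio - round(ratio)) > 1e-9:
            raise ParameterError("fs_accel must be an integer multiple of fs_ref")


@dataclass
class SyntheticTrial:
    heel_rec: AccelerometerRecording
    toe_rec: AccelerometerRecording
    heel_ref: np.ndarray
    toe_ref: np.ndarray
    ref_times: np.ndarray
    truth: GaitEventSequence
    params: GaitParams
    heel_disp: np.ndarray = field(default=None, repr=False)  # clean, at fs_accel
    toe_disp: np.ndarray = field(default=None, repr=False)


def _cycle_poly(contact_start, contact_end, peak):
    """C² displacement over one cycle [contact_start, contact_start + 1).

    Breakpoints carry (value, slope, curvature); BPoly.from_derivatives
    builds quintic pieces that match them, so acceleration is continuous.
    """
    rec = _TRANSIENT_FRAC
    mid_swing = (contact_end + contact_start + 1.0) / 2.0
    swing = contact_start + 1.0 - contact_end
    xk = np.array(
        [
            contact_start,            # strike trough
            contact_start + rec,      # back on the ground
            contact_end - rec,        # pre-lift dip begins
            contact_end,              # lift-off trough
            mid_swing,                # swing apex
            contact_start + 1.0,      # next strike trough
        ]
    )
    dip = [-_DIP_M, 0.0, _IMPACT_CURVATURE]
    flat = [0.0, 0.0, 0.0]
    apex = [peak, 0.0, -8.0 * peak / swing**2]
    yk = [dip, flat, flat, dip, apex, dip]
    return BPoly.from_derivatives(xk, yk)


def heel_toe_trajectories(params: GaitParams):
    """Clean heel and toe vertical displacement (m) at ``fs_accel``.

    The record spans a quarter-cycle lead-in, ``n_cycles`` full cycles and a
    quarter-cycle lead-out.  Returns (heel, toe, times).
    """
    hs, ts, ho, to = params.event_phases
    T = params.cycle_s
    fs = params.fs_accel
    n = int(round((params.n_cycles + 2 * _LEAD_FRAC) * T * fs))
    t = np.arange(n) / fs
    # global phase: cycle k occupies [k, k+1); lead-in sits at negative phase
    g = t / T - _LEAD_FRAC

    out = []
    for contact_start, contact_end, peak in (
        (hs, ho, params.swing_peak_heel_m),
        (ts, to, params.swing_peak_toe_m),
    ):
        poly = _cycle_poly(contact_start, contact_end, peak)
        phase = contact_start + np.mod(g - contact_start, 1.0)
        d = poly(phase)
        # swing-only ripple, C^2 via the sin^2 envelope
        swing_len = contact_start + 1.0 - contact_end
        u = np.mod(g - contact_end, 1.0) / swing_len
        env = np.where(u < 1.0, np.sin(np.pi * np.clip(u, 0.0, 1.0)) ** 2, 0.0)
        ripple = sum(
            a * np.sin(2.0 * np.pi * f * g + p) for f, a, p in _RIPPLE_COMPONENTS
        )
        d = d + _RIPPLE_M * env * ripple
        # outside the walking bout the subject stands: flat before the foot
        # lifts into the swing preceding cycle 0, and flat again after the
        # final landing (cyclic knots are (0,0,0) there, so the junction is
        # C^2); these standing phases touch the record edges and are dropped
        # by detectors as partial boundary intervals.
        walk_start = contact_end - 1.0 - _TRANSIENT_FRAC          # pre-lift knot
        walk_end = contact_start + params.n_cycles + _TRANSIENT_FRAC  # post-landing knot
        d[(g < walk_start) | (g > walk_end)] = 0.0
        out.append(d)
    heel, toe = out
    return heel, toe, t


def _truth_events(params: GaitParams) -> GaitEventSequence:
    T = params.cycle_s
    fs = params.fs_accel
    labels = ("HS", "TS", "HO", "TO")
    events = []
    for k in range(params.n_cycles):
        for lab, ph in zip(labels, params.event_phases):
            time = (_LEAD_FRAC + k + ph) * T
            events.append(
                GaitEvent(label=lab, time=time, sample_index=int(round(time * fs)))
            )
    return GaitEventSequence(events)


def _second_difference(d, fs):
    a = np.empty_like(d)
    a[1:-1] = (d[2:] - 2.0 * d[1:-1] + d[:-2]) * fs * fs
    a[0] = a[1]
    a[-1] = a[-2]
    return a


def make_trial(params: GaitParams | None = None, **overrides) -> SyntheticTrial:
    """Generate a fully reproducible trial (same seed → identical output)."""
    if params is None:
        params = GaitParams()
    if overrides:
        params = replace(params, **overrides)
    rng = np.random.default_rng(params.seed)
    heel, toe, t = heel_toe_trajectories(params)
    fs = params.fs_accel

    drift = params.drift_amp * np.sin(2.0 * np.pi * 0.05 * t)
    recs = {}
    for site, disp in (("heel", heel), ("toe", toe)):
        az_clean = _second_difference(disp, fs) + GRAVITY
        az = az_clean + drift + rng.normal(0.0, params.noise_sigma, len(t))
        kinematic = az_clean - GRAVITY
        # small correlated horizontal components: in-phase plus a smoothed
        # quadrature term, ~10 % of the vertical dynamic range
        quad = np.gradient(kinematic, 1.0 / fs) / (2.0 * np.pi / params.cycle_s)
        ax = 0.10 * kinematic + 0.02 * quad
        ay = 0.06 * kinematic - 0.03 * quad
        recs[site] = AccelerometerRecording(
            site=site, fs=fs, t0=0.0, ax=ax, ay=ay, az=az
        )

    step = int(round(params.fs_accel / params.fs_ref))
    return SyntheticTrial(
        heel_rec=recs["heel"],
        toe_rec=recs["toe"],
        heel_ref=heel[::step].copy(),
        toe_ref=toe[::step].copy(),
        ref_times=t[::step].copy(),
        truth=_truth_events(params),
        params=params,
        heel_disp=heel,
        toe_disp=toe,
    )
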