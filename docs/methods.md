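# Methods

This note documents the models, parameters, numerical choices and known
limitations of `gaitevents`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

During level walking each foot alternates between a stance phase (foot on the
ground, sensor nearly static) and a swing phase (foot airborne). Heel- and
toe-mounted tri-axial accelerometers see this as alternating quiet and active
segments, and the vertical displacement of each sensor — recoverable from the
vertical acceleration by double integration — has a characteristic trough at
ground contact (strike) and a trough immediately before lift-off (off). The
pipeline turns these observations into the four event times HS, TS, HO, TO
per gait cycle.

## Pipeline stages and parameters

### 1. Modulus-maxima denoising (`denoise`)

The stationary (undecimated) wavelet transform is used because maxima
tracking across scales requires translation invariance. Defaults: `db2`
basis, `levels = 4` (dyadic scales 2–16 ms at 1000 Hz — the band where
wideband sensor noise lives; the analysed record must be at least 2^levels
samples).

- Magnitudes are normalised per level by 2^(−j/2) so the continuous-transform
  scaling law applies: white-noise maxima then decay across scale
  (slope ≈ −0.5/level) while smooth oscillatory structure grows. The
  classification slope `beta_hat` is the least-squares slope of
  log2(magnitude) against level; `beta_threshold = 0` splits signal
  (kept, β ≥ 0) from noise (removed, β < 0). Single-scale chains cannot
  demonstrate growth and are conservatively removed.
- Chains link maxima at adjacent levels within a propagation radius taken
  from the **coarser** scale, ceil(2^(j+1)/2) samples. A radius read from
  the finer scale (one sample at level 1) measurably breaks the chains of
  genuine sharp transients — impact transients were misclassified as noise
  and zeroed — because the extrema of a smooth transient shift by several
  samples between scales.
- Removal is done in the coefficient domain: each removed maximum's
  influence hump (the lobe of |W| between the adjacent modulus minima) is
  zeroed, humps of kept chains are protected, and the transform is inverted.
  This makes the no-op case exact (keeping every chain returns the input
  bit-for-bit up to the inverse transform's roundoff) and removes the full
  support of noise maxima. An isolated single-sample impulse has Lipschitz
  exponent ≈ −1 and is therefore treated as noise — that is the correct
  behaviour of the classification, not a defect.

### 2. Gravity removal (`preprocess`)

The whole-record mean of the vertical axis is subtracted. Over whole gait
cycles the kinematic acceleration averages out, so the mean is the gravity
component. No orientation estimation is attempted.

### 3. Jerk segmentation (`segmentation`)

The comprehensive change rate (Euclidean norm of per-axis forward
differences) is smoothed with a **trailing** 30 ms window (`window_ms = 30`;
the leading samples use the truncated available window) and binarized at
`r × max` with `r = 0.05`. Runs shorter than `min_segment_ms = 50` (interior
only) are merged into their neighbours — phases shorter than 50 ms are not
physiological at ~1.2 m/s walking. The threshold is adaptive per record; the
choice of `r` has little effect because segmentation is only a preliminary
step that localises the search regions for the trough rules.

### 4. Double integration and trend removal (`integration`)

Frequency-domain double integration divides each Fourier bin by (jω_k)² with
ω_k = 2πk·f_s/N. The DC bin is always zeroed (the operator is singular
there) and `highpass_hz = 0.1` additionally suppresses near-DC
amplification. Time-domain cumulative integration is not offered — the
quadratic error growth makes it unusable here.

Integration leaves a large slow trend (any residual bias is amplified by
1/ω²). The trend is modelled as the deepest approximation band of an 8-level
wavelet decomposition (`detrend_levels = 8`, `detrend_basis = "sym8"`, with
`db6` selectable). Two implementation decisions matter:

- **The removal band must sit below the locomotor band.** At a native
  1000 Hz an 8-level approximation spans [0, f_s/2⁹ ≈ 1.95 Hz] and would
  swallow the ~1 Hz gait fundamental itself (measured: a 1 Hz sinusoid
  retains 6 % of its energy after native-rate level-8 approximation
  zeroing, and displacement troughs shift by tens of ms). The trend is
  therefore estimated on a copy decimated to `trend_fs = 100 Hz`, where the
  same 8-level construction spans ≈ [0, 0.2 Hz] — low enough to preserve
  gait content, high enough to capture integration drift and slow sensor
  bias wander (including the generator's 0.05 Hz drift, removed to ~2–4 %
  residual). The decimation factor shrinks automatically for short inputs
  so the level-8 precondition (≥ 2^8 samples) is honoured at any length.
- **The estimator is an exact projection.** The decimated signal is
  mirror-extended (even symmetry, circularly smooth), and the trend is the
  rank-truncated least-squares projection onto circular shifts of the
  level-8 scaling function, each shift symmetrized about the fold axis.
  Because every basis vector is even, the projection of an even extension
  is even, and cropping + re-extending reproduces it: applying the detrend
  twice changes the output only at roundoff (measured ~1e-13 relative),
  with no edge-localised basis functions to eat signal near the record
  boundaries. The record mean is handled exactly outside the projection, so
  a constant input maps to exactly zero. Rank truncation (`rcond = 1e-3`)
  is required because overlapping scaling-function shifts form a nearly
  degenerate frame whose min-norm coefficients would amplify the columns'
  tiny out-of-band components. The soft-threshold variant
  (`soft_threshold_mode = "approx_and_details"`) additionally applies the
  universal threshold σ√(2 ln N), σ from the finest band's MAD, to the
  detail bands; the default removes only the trend, which matches the
  observation that the drift lives entirely in the deepest approximation.

### 5. Event rules (`events`)

Strict local minima of the detrended displacement are searched inside each
flat interval extended by `search_margin_ms = 100` on both sides (the
displacement minimum at impact slightly precedes the jerk-quiet region).
"Drops/rises sharply" is quantified as the mean slope over
`slope_window_ms = 50` exceeding `drop_slope_thresh`/`rise_slope_thresh`,
both 0.15 m/s by default: genuine strike/off slopes are 0.3–0.5 m/s while
the residual baseline wobble after trend removal has slopes up to ~0.1 m/s
on records of a few tens of seconds, so the gate sits between the two
populations. (A 0.05 m/s gate admits occasional wobble troughs and produced
30 ms misdetections on clean input.) HO must follow HS within the same flat
interval, TO must follow TS; cycles violating HS ≤ TS ≤ HO ≤ TO and
incomplete boundary cycles are dropped with a warning. Ties break to the
earliest index.

### 6. Validation (`validation`)

Greedy nearest-time matching within label (`max_gap_ms = 100`, each event
used once), per-label summaries (n, mean, SD, median, MAE) and Bland–Altman
statistics with fixed 95 % limits (mean ± 1.96·SD, n−1 denominator).
When only a reference displacement trace is available, reference events can
be extracted with the same trough rules — but synthetic ground truth, which
is exact by construction, is preferred to avoid circularity.

## The synthetic generator (`synthetic`)

The generator emulates steady treadmill walking as acquired in a
motion-capture-synchronized protocol: 1000 Hz accelerometers, a 100 Hz
reference displacement, 1.0 s cycles (≈1.2 m/s), stance fraction 0.6, event
phases HS/TS/HO/TO = 0.0/0.12/0.45/0.62 of the cycle, heel swing peak
0.15 m, toe swing peak 0.05 m, vertical noise σ = 0.2 m/s², drift = a
0.1 m/s² sinusoid at 0.05 Hz (deliberately near the trend band edge so the
wavelet detrend is actually exercised).

Per-cycle vertical displacement is a C² quintic Hermite curve: flat stance,
a raised swing arc, and 0.8 mm dips (within the 1 mm stance-contact
tolerance) whose minima fall exactly on the strike and lift-off instants,
with ~20 ms transients and an impact curvature of 20 m/s² — the timescale of
heel-pad/shoe compression. Mid-swing carries a ~2 mm two-component
oscillation (8 and 12.5 cycles per gait cycle, windowed to vanish at the
swing ends), standing in for the 5–15 Hz soft-tissue and limb-dynamics
content real foot sensors show in swing; without it a smooth synthetic swing
is as jerk-quiet as stance and the threshold segmentation has nothing to
separate. Acceleration is the exact second difference of displacement times
f_s², plus gravity (9.81), noise and drift; the horizontal axes carry
correlated oscillations at ~10 % of the vertical dynamic range so the
three-axis jerk is exercised.

The bout is padded by 1.5 cycles of standing/transition at each end: the
subject stands, lifts into the swing that lands on cycle 0's strike, and
returns to standing after the last cycle. This keeps every ground-truth
cycle clear of the detrender's settling region (measured: max noiseless
event error 11 ms with 1.25-cycle padding, 2 ms with 1.5) and makes the
standing phases partial boundary intervals that detectors correctly drop.
Ground truth contains exactly n_cycles × 4 events at the exact phase times.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: soft-tissue artifact coupled to impact, sensor
axis misalignment and orientation change, treadmill-speed drift, asymmetric
or pathological gait, heel-pad hysteresis, and any motion-capture marker
noise in the reference. Real-data error magnitudes (tens of ms in
comparable published work) should not be expected to match the sub-ms
synthetic recovery reported by the acceptance script, which demonstrates
correctness of the implementation rather than field accuracy.

## Problem sizes and degradation behaviour

Default validation runs use 10-cycle trials (13 s at 1000 Hz; ~0.5 s of
compute per trial), 20 randomized trials for the ordering property, and
100 random inputs for the jerk/smoothing oracle. Detection degrades
gracefully with vertical noise: at σ = 0.2 m/s² all 40 events of the default
trial are recovered (MAE ≈ 0.3 ms); at σ = 0.5 about 70 % of events are
recovered with median shift ≤ 1 ms; by σ ≈ 1.5 the smoothed-jerk noise floor
overwhelms the stance/swing contrast and segmentation — and with it
detection — fails. The timing of whatever is detected remains accurate well
past the point where the detection rate collapses.

## Known limitations

- The modulus-maxima classifier needs several octaves of clean scale
  behaviour; at very high noise some noise chains are kept and the
  segmentation threshold (r × max of smoothed jerk) loses its contrast.
- The trend projection removes everything below ≈ 0.2 Hz, including the
  walking-bout envelope; recovered displacement is therefore only defined
  up to that band (round-trip correlation is ≈ 0.94 against the raw truth
  and 1.000 against the equivalently detrended truth).
- Event rules assume one strike and one off per flat interval; shuffling
  gaits with multiple ground contacts per cycle per sensor are out of scope.
- The 1 % tolerance on time-column spacing in `signal_io` assumes
  crystal-locked uniform sampling; irregularly sampled input must be
  resampled upstream.
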