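"""Acceleration → displacement: frequency-domain double integration and
wavelet trend removal.

Double integration in the frequency domain divides each Fourier component by
``(j omega_k)^2`` with ``omega_k = 2 pi k fs / N``; the DC bin (where the
operator is singular) and all bins below a configurable high-pass corner are
zeroed.  Integrating twice amplifies any low-frequency content by
``1/omega^2``, so the result carries a large slow trend that must be removed
before the displacement troughs are interpretable.

The trend is modelled as the deepest-level approximation of an 8-level
discrete wavelet decomposition (sym8 by default, db6 selectable).  Because an
8-level approximation is only a *slow drift* when the decomposition operates
well below the locomotor band, the trend is estimated on a copy of the signal
decimated to ``trend_fs`` (default 100 Hz, giving an approximation band of
roughly [0, 0.2] Hz), as an exact least-squares projection onto the span of
the level-8 scaling functions, then interpolated back to the full rate and
subtracted.  Zeroing the deepest approximation of the decomposition and the
projection implemented here remove the same subspace; the projection form is
exactly idempotent and makes the removal band independent of the native
sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.interpolate import CubicSpline

from .exceptions import LengthError, ParameterError

__all__ = [
    "DisplacementTrace",
    "double_integrate_fft",
    "detrend_wavelet",
    "acceleration_to_displacement",
]


@dataclass
class DisplacementTrace:
    """Vertical displacement from double integration, raw and detrended."""

    site: str
    fs: float
    raw: np.ndarray
    detrended: np.ndarray

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        self.detrended = np.asarray(self.detrended, dtype=float)
        if len(self.raw) != len(self.detrended):
            raise LengthError("raw and detrended traces differ in length")

    @property
    def n(self) -> int:
        return len(self.raw)


def double_integrate_fft(az, fs: float, highpass_hz: float = 0.1) -> np.ndarray:
    """Twice-integrate acceleration in the frequency domain.

    Each retained bin k is divided by ``(j omega_k)^2``; the DC bin and all
    bins with ``|f| < highpass_hz`` are zeroed.  The output is real-valued
    with the same length as the input.
    """
    az = np.asarray(az, dtype=float)
    n = len(az)
    if n < 8:
        raise LengthError(f"need at least 8 samples, got {n}")
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if highpass_hz < 0 or highpass_hz >= fs / 2:
        raise ParameterError(
            f"highpass_hz must lie in [0, fs/2) = [0, {fs / 2}), got {highpass_hz}"
        )
    spectrum = np.fft.fft(az)
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    omega = 2.0 * np.pi * freqs
    keep = np.abs(freqs) >= max(highpass_hz, 0.5 * fs / n)  # always drop DC
    out = np.zeros(n, dtype=complex)
    out[keep] = spectrum[keep] / (1j * omega[keep]) ** 2
    return np.fft.ifft(out).real


def _scaling_shape(levels: int, basis: str) -> np.ndarray:
    """Impulse response of the level-`levels` approximation synthesis: one
    deepest-level scaling function, on a domain longer than its support."""
    stride = 2**levels
    support = (pywt.Wavelet(basis).rec_len - 1) * (stride - 1) + stride
    m = stride * (2 ** int(np.ceil(np.log2(max(2, support / stride + 1)))))
    template = pywt.wavedec(np.zeros(m), basis, level=levels, mode="periodization")
    template[0] = np.zeros(len(template[0]))
    template[0][len(template[0]) // 2] = 1.0
    shape = pywt.waverec(template, basis, mode="periodization")[:m]
    return shape, int(np.argmax(np.abs(shape)))


def _symmetric_circular_basis(m: int, levels: int, basis: str) -> np.ndarray:
    """Even-symmetric circular shifts of the deepest scaling function on Z_m.

    Columns are placed at stride 2**levels and symmetrized about the
    half-sample axis (i -> m-1-i), so that every column — and hence any
    fitted trend — is even on the doubled circle.
    """
    stride = 2**levels
    shape, peak = _scaling_shape(levels, basis)
    rel = np.arange(len(shape)) - peak  # offsets about the peak
    k = max(1, int(round(m / stride)))
    cols = np.empty((m, k + 1))
    for i in range(k):
        pos = int(round(i * m / k))  # uniform spacing, no seam clustering
        col = np.zeros(m)
        np.add.at(col, (rel + pos) % m, shape)  # smooth periodization
        cols[:, i] = 0.5 * (col + col[::-1])
    cols[:, k] = 1.0  # constants are trend by definition
    return cols


def estimate_trend(
    d,
    fs: float,
    levels: int = 8,
    basis: str = "sym8",
    trend_fs: float = 100.0,
) -> np.ndarray:
    """Trend of ``d``: least-squares projection onto the deepest-level
    scaling subspace, computed on the even (mirror) extension of a copy
    decimated to ``trend_fs``.

    The mirror extension plus the even-symmetrized circular basis make the
    estimator an exact linear projection (idempotent to roundoff) with no
    edge-localized degrees of freedom: the projection of an even signal is
    even, so re-extending the cropped trend reproduces it exactly.
    """
    d = np.asarray(d, dtype=float)
    n = len(d)
    if n < 2**levels:
        raise LengthError(
            f"signal of length {n} is too short for a {levels}-level "
            f"decomposition (needs >= {2**levels}; reduce levels)"
        )
    q = int(round(fs / trend_fs)) if trend_fs > 0 else 1
    q = max(1, min(q, n // 2**levels))
    idx = np.arange(0, n, q)
    xs = d[idx]
    mean = xs.mean()  # handled exactly, outside the projection
    ext = np.concatenate([xs, xs[::-1]]) - mean  # even extension, smooth on the circle
    cols = _symmetric_circular_basis(len(ext), levels, basis)
    # rank truncation: overlapping shifts make the frame nearly degenerate,
    # and min-norm coefficients would amplify the columns' out-of-band dregs
    coef, *_ = np.linalg.lstsq(cols, ext, rcond=1e-3)
    trend_grid = mean + (cols @ coef)[: len(xs)]
    if q == 1:
        return trend_grid[:n]
    return CubicSpline(idx, trend_grid)(np.arange(n))


def detrend_wavelet(
    d,
    fs: float,
    levels: int = 8,
    basis: str = "sym8",
    mode: str = "approx_only",
    trend_fs: float = 100.0,
) -> np.ndarray:
    """Remove the deepest-approximation trend; optionally soft-threshold the
    detail bands as well (``mode='approx_and_details'``).

    The universal threshold ``sigma * sqrt(2 ln N)`` with sigma estimated from
    the finest band's median absolute deviation is used for the soft variant.
    The output is mean-free.
    """
    d = np.asarray(d, dtype=float)
    out = d - estimate_trend(d, fs, levels=levels, basis=basis, trend_fs=trend_fs)
    if mode == "approx_and_details":
        max_lvl = pywt.dwt_max_level(len(out), pywt.Wavelet(basis).dec_len)
        lvl = min(levels, max_lvl)
        coeffs = pywt.wavedec(out, basis, level=lvl, mode="symmetric")
        sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if len(coeffs[-1]) else 0.0
        thresh = sigma * np.sqrt(2.0 * np.log(max(len(out), 2)))
        coeffs[1:] = [pywt.threshold(c, thresh, mode="soft") for c in coeffs[1:]]
        out = pywt.waverec(coeffs, basis, mode="symmetric")[: len(out)]
    elif mode != "approx_only":
        raise ParameterError(f"unknown detrend mode {mode!r}")
    return out - out.mean()


def acceleration_to_displacement(rec, cfg, denoise_cfg=None) -> DisplacementTrace:
    """Full vertical-displacement pipeline for one recording:
    (optional) denoise → gravity removal → FFT double integration → detrend."""
    from .denoise import denoise as mm_denoise
    from .preprocess import remove_gravity

    az = np.asarray(rec.az, dtype=float)
    if denoise_cfg is not None:
        az = mm_denoise(
            az,
            levels=denoise_cfg.levels,
            wavelet=denoise_cfg.wavelet,
            beta_threshold=denoise_cfg.beta_threshold,
        )
    az = remove_gravity(az)
    raw = double_integrate_fft(az, rec.fs, highpass_hz=cfg.highpass_hz)
    detrended = detrend_wavelet(
        raw,
        rec.fs,
        levels=cfg.detrend_levels,
        basis=cfg.detrend_basis,
        mode=cfg.soft_threshold_mode,
        trend_fs=cfg.trend_fs,
    )
    return DisplacementTrace(site=rec.site, fs=rec.fs, raw=raw, detrended=detrended)
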