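"""Jerk magnitude, trailing smoothing, threshold binarization, run filtering."""

import numpy as np
import pytest

from gaitevents.exceptions import (
    DegenerateSignalError,
    ParameterError,
    ShapeError,
)
from gaitevents.segmentation import (
    PhaseSegmentation,
    binarize,
    filter_short_segments,
    jerk_magnitude,
    smooth,
)


def brute_jerk(ax, ay, az):
    return np.array(
        [
            np.sqrt(
                (ax[i + 1] - ax[i]) ** 2
                + (ay[i + 1] - ay[i]) ** 2
                + (az[i + 1] - az[i]) ** 2
            )
            for i in range(len(ax) - 1)
        ]
    )


def brute_smooth(ja, w):
    return np.array(
        [np.mean(ja[max(0, j - w + 1) : j + 1]) for j in range(len(ja))]
    )


class TestJerk:
    def test_constant_signal_zero_rate(self):
        np.testing.assert_array_equal(
            jerk_magnitude([1.0] * 5, [2.0] * 5, [3.0] * 5), np.zeros(4)
        )

    def test_unit_step(self):
        np.testing.assert_allclose(
            jerk_magnitude([0, 1, 1], [0, 0, 0], [0, 0, 0]), [1.0, 0.0]
        )

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 200))
            ax, ay, az = rng.normal(size=(3, n))
            got = jerk_magnitude(ax, ay, az)
            ref = brute_jerk(ax, ay, az)
            np.testing.assert_allclose(got, ref, rtol=1e-12, atol=1e-14)

    def test_shape_error(self):
        with pytest.raises(ShapeError):
            jerk_magnitude([1, 2, 3], [1, 2], [1, 2, 3])


class TestSmooth:
    def test_constant_preserved(self):
        np.testing.assert_allclose(smooth(np.full(50, 3.3), fs=1000.0), 3.3)

    def test_impulse_closed_form(self):
        # impulse of height W at k >= W-1 -> value 1 over [k, k+W-1]
        w, k = 30, 40
        ja = np.zeros(200)
        ja[k] = w
        out = smooth(ja, fs=1000.0, window_ms=30.0)
        expected = np.zeros(200)
        expected[k : k + w] = 1.0
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_window_is_30_samples_at_1khz(self):
        # 30 ms at 1000 Hz is a 30-sample trailing window
        ja = np.zeros(100)
        ja[50] = 1.0
        out = smooth(ja, fs=1000.0, window_ms=30.0)
        assert np.count_nonzero(out) == 30

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 300))
            ja = np.abs(rng.normal(size=n))
            got = smooth(ja, fs=1000.0, window_ms=30.0)
            np.testing.assert_allclose(got, brute_smooth(ja, 30), rtol=1e-12)

    def test_nonpositive_window(self):
        with pytest.raises(ParameterError):
            smooth(np.ones(10), fs=1000.0, window_ms=0.0)


class TestBinarize:
    def test_hand_computable_example(self):
        seg = binarize(np.array([0.0, 0, 5, 5, 0]), r=0.5)
        np.testing.assert_array_equal(seg.binary, [0, 0, 1, 1, 0])
        assert seg.flat_intervals == [(0, 2), (4, 5)]
        assert seg.nonflat_intervals == [(2, 4)]
        assert seg.threshold_used == pytest.approx(2.5)

    def test_near_one_r_marks_only_argmax(self):
        seg = binarize(np.array([1.0, 2.0, 3.0]), r=0.99)
        np.testing.assert_array_equal(seg.binary, [0, 0, 1])

    def test_monotone_in_r(self, rng):
        ja = np.abs(rng.normal(size=500))
        counts = [binarize(ja, r).binary.sum() for r in (0.05, 0.2, 0.5, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            binarize(np.zeros(10), r=0.1)

    def test_r_out_of_range(self):
        with pytest.raises(ParameterError):
            binarize(np.ones(10), r=1.5)

    def test_tiling_invariant(self, rng):
        ja = np.abs(rng.normal(size=333))
        seg = binarize(ja, r=0.3)
        covered = sorted(seg.flat_intervals + seg.nonflat_intervals)
        assert covered[0][0] == 0 and covered[-1][1] == len(ja)
        for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
            assert e1 == s2


class TestFilterShort:
    def test_identity_when_no_short_runs(self):
        seg = binarize(np.array([0.0, 0, 0, 9, 9, 9, 0, 0, 0]), r=0.5)
        out = filter_short_segments(seg, min_ms=2.0, fs=1000.0)
        np.testing.assert_array_equal(out.binary, seg.binary)

    def test_single_blip_absorbed(self):
        binary = np.zeros(200, dtype=np.int8)
        binary[100] = 1  # 1-sample non-flat blip in a flat run
        seg = PhaseSegmentation(binary=binary, threshold_used=1.0, r=0.1)
        out = filter_short_segments(seg, min_ms=50.0, fs=1000.0)
        assert out.flat_intervals == [(0, 200)]

    def test_interior_runs_meet_minimum(self, rng):
        binary = (rng.random(400) < 0.4).astype(np.int8)
        seg = PhaseSegmentation(binary=binary, threshold_used=1.0, r=0.1)
        out = filter_short_segments(seg, min_ms=20.0, fs=1000.0)
        runs = sorted(out.flat_intervals + out.nonflat_intervals)
        for s, e in runs[1:-1]:
            assert e - s >= 20
        # tiling preserved
        assert runs[0][0] == 0 and runs[-1][1] == 400
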