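"""Event matching, error summaries and Bland–Altman agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitevents.exceptions import SampleSizeError
from gaitevents.signal_io import GaitEvent, GaitEventSequence
from gaitevents.validation import (
    bland_altman,
    match_events,
    summarize_errors,
    validation_report,
)


def seq(times_by_label):
    evs = [
        GaitEvent(lab, float(t), int(round(t * 1000)))
        for lab, times in times_by_label.items()
        for t in times
    ]
    return GaitEventSequence(evs)


def brute_bland_altman(diffs):
    d = np.asarray(diffs, float)
    mean = d.mean()
    sd = np.sqrt(((d - mean) ** 2).sum() / (len(d) - 1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    outside = int(((d < lo) | (d > hi)).sum())
    return mean, sd, lo, hi, outside


class TestMatching:
    def test_identical_sequences_match_perfectly(self):
        a = seq({"HS": [1.0, 2.0], "TO": [1.6, 2.6]})
        m = match_events(a, a, max_gap_ms=100)
        assert m.n_matched == 4
        assert np.allclose(m.diffs(), 0.0)
        assert not m.unmatched_detected and not m.unmatched_reference

    def test_uniform_shift_matches_with_constant_diff(self):
        ref = seq({"HS": [1.0, 2.0, 3.0]})
        det = seq({"HS": [1.015, 2.015, 3.015]})
        m = match_events(det, ref, max_gap_ms=100)
        assert m.n_matched == 3
        np.testing.assert_allclose(m.diffs("HS"), 0.015, atol=1e-12)

    def test_missing_detection_reported_unmatched(self):
        ref = seq({"HS": [1.0, 2.0]})
        det = seq({"HS": [1.0]})
        m = match_events(det, ref, max_gap_ms=100)
        assert m.n_matched == 1
        assert [e.time for e in m.unmatched_reference["HS"]] == [2.0]

    def test_gap_limit_respected(self):
        ref = seq({"TO": [1.0]})
        det = seq({"TO": [1.3]})
        m = match_events(det, ref, max_gap_ms=100)
        assert m.n_matched == 0


class TestBlandAltman:
    def test_degenerate_equal_diffs(self):
        ba = bland_altman([0.02] * 5)
        assert ba.mean_diff == pytest.approx(0.02)
        assert ba.sd_diff == 0.0
        assert (ba.loa_low, ba.loa_high) == (pytest.approx(0.02), pytest.approx(0.02))
        assert ba.outside_count == 0

    def test_two_point_hand_computation(self):
        ba = bland_altman([-1.0, 1.0])
        assert ba.mean_diff == pytest.approx(0.0)
        assert ba.sd_diff == pytest.approx(np.sqrt(2))
        assert ba.loa_high == pytest.approx(1.96 * np.sqrt(2))
        assert ba.outside_count == 0

    def test_against_bruteforce(self, rng):
        diffs = rng.normal(0.02, 0.01, 30)
        ba = bland_altman(diffs)
        mean, sd, lo, hi, outside = brute_bland_altman(diffs)
        assert ba.mean_diff == pytest.approx(mean, abs=1e-12)
        assert ba.sd_diff == pytest.approx(sd, abs=1e-12)
        assert ba.loa_low == pytest.approx(lo, abs=1e-12)
        assert ba.loa_high == pytest.approx(hi, abs=1e-12)
        assert ba.outside_count == outside
        assert ba.outside_fraction == pytest.approx(outside / 30)
        assert ba.outside_fraction <= 2 / 30

    def test_sample_size_error(self):
        with pytest.raises(SampleSizeError):
            bland_altman([0.1])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-0.1, 0.1), min_size=3, max_size=40),
        st.floats(-0.5, 0.5),
    )
    def test_shift_invariance(self, diffs, c):
        base = bland_altman(diffs)
        shifted = bland_altman(np.asarray(diffs) + c)
        assert shifted.mean_diff == pytest.approx(base.mean_diff + c, abs=1e-9)
        assert shifted.loa_low == pytest.approx(base.loa_low + c, abs=1e-9)
        assert shifted.loa_high == pytest.approx(base.loa_high + c, abs=1e-9)
        assert shifted.sd_diff == pytest.approx(base.sd_diff, abs=1e-9)
        assert shifted.outside_count == base.outside_count


class TestSummaries:
    def test_constant_plus_20ms_bias(self):
        ref = seq({lab: [1.0 + i for i in range(3)] for lab in ("HS", "TS", "HO", "TO")})
        det = seq(
            {lab: [1.02 + i for i in range(3)] for lab in ("HS", "TS", "HO", "TO")}
        )
        table = summarize_errors(match_events(det, ref, 100))
        assert set(table["label"]) == {"HS", "TS", "HO", "TO"}
        np.testing.assert_allclose(table["mean_dt_s"], 0.02, atol=1e-12)

    def test_symmetric_diffs_zero_mean_mae_x(self):
        ref = seq({"HS": [1.0, 2.0]})
        det = seq({"HS": [1.01, 1.99]})
        table = summarize_errors(match_events(det, ref, 100))
        row = table[table["label"] == "HS"].iloc[0]
        assert row["mean_dt_s"] == pytest.approx(0.0, abs=1e-12)
        assert row["mae_s"] == pytest.approx(0.01, abs=1e-12)

    def test_report_includes_pooled_bland_altman(self):
        ref = seq({"HS": [1.0, 2.0], "TO": [1.6, 2.6]})
        det = seq({"HS": [1.01, 2.02], "TO": [1.61, 2.59]})
        table = validation_report(det, ref)
        assert "ALL" in set(table["label"])
        ba = table.attrs["bland_altman"]
        assert ba.n == 4
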