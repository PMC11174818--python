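"""Range summaries, disjointness, and the FP/FN subject-status rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegstates.classify import (
    AlignmentError,
    ClassificationOutcome,
    RangeSummary,
    SelectionError,
    discriminating_signals,
    is_disjoint,
    range_summary,
    subject_status,
)
from eegstates.filtering import CANONICAL_BANDS


def make_peaks(values: dict) -> pd.DataFrame:
    """Peak table from {(subject, channel, band, state): magnitude}."""
    rows = [
        {"subject_id": sid, "channel": ch, "band": band, "state": state,
         "peak_magnitude": mag, "peak_freq": 5.0}
        for (sid, ch, band, state), mag in values.items()
    ]
    return pd.DataFrame(rows)


def series(values: dict) -> pd.Series:
    return pd.Series(values, dtype=float)


def enumeration_oracle(vals_r: dict, vals_t: dict):
    """O(n^2) pairwise re-derivation of the group-referenced rules."""
    subjects = sorted(vals_r)
    fp = sum(
        any(vals_t[s] <= vals_r[o] for o in subjects) for s in subjects)
    fn = sum(
        any(vals_r[s] >= vals_t[o] for o in subjects) for s in subjects)
    return fp, fn


class TestRangeSummary:
    def test_single_subject(self):
        peaks = make_peaks({("S1", "F7", "theta", "R"): 5.0})
        rs = range_summary(peaks, "F7", "theta", "R", "G", ["S1"])
        assert (rs.min, rs.max, rs.median, rs.n) == (5.0, 5.0, 5.0, 1)

    def test_order_statistics(self):
        peaks = make_peaks({
            ("S1", "F7", "theta", "R"): 1.0,
            ("S2", "F7", "theta", "R"): 2.0,
            ("S3", "F7", "theta", "R"): 9.0,
        })
        rs = range_summary(peaks, "F7", "theta", "R", "G", ["S1", "S2", "S3"])
        assert (rs.min, rs.max, rs.median) == (1.0, 9.0, 2.0)

    def test_empty_selection_rejected(self):
        peaks = make_peaks({("S1", "F7", "theta", "R"): 5.0})
        with pytest.raises(SelectionError):
            range_summary(peaks, "Fz", "theta", "R", "G", ["S1"])

    def test_invalid_summary_rejected(self):
        with pytest.raises(ValueError):
            RangeSummary("F7", "theta", "R", "G",
                         min=2.0, max=1.0, median=1.5, n=3)


class TestDisjointness:
    def _rs(self, lo, hi, state):
        return RangeSummary("F7", "theta", state, "G",
                            min=lo, max=hi, median=(lo + hi) / 2, n=3)

    @pytest.mark.parametrize("r,t,expected", [
        ((1, 3), (5, 9), True),
        ((1, 5), (5, 9), False),  # shared endpoint counts as overlap
        ((1, 6), (5, 9), False),
        ((5, 9), (1, 3), True),   # order-free
    ])
    def test_interval_cases(self, r, t, expected):
        assert is_disjoint(self._rs(*r, "R"), self._rs(*t, "T")) is expected

    def test_mismatched_selection_rejected(self):
        other = RangeSummary("Fz", "theta", "T", "G", 1, 2, 1.5, 3)
        with pytest.raises(ValueError):
            is_disjoint(self._rs(1, 2, "R"), other)


class TestSubjectStatus:
    def test_perfect_separation(self):
        r = series({f"S{i}": float(i) for i in range(1, 6)})
        t = r + 10.0
        out = subject_status(r, t)
        assert (out.fp, out.fn, out.tp, out.tn) == (0, 0, 5, 5)

    def test_constructed_fp6_fn2_table(self):
        """25 subjects, 6 task values at/below max(R), 2 rest values at/above
        min(T): the counts that give the 84/79/0.69/85/92/76 metric row."""
        n = 25
        vals_r = {f"S{i}": 1.0 + 0.02 * i for i in range(n)}     # max 1.48
        vals_t = {f"S{i}": 8.0 + 0.1 * i for i in range(n)}
        for i in range(6):          # task values at/below the resting max
            vals_t[f"S{i}"] = 2.0 + 0.05 * i
        for i in (10, 11):          # resting values at/above the task min
            vals_r[f"S{i}"] = 5.0
        out = subject_status(series(vals_r), series(vals_t))
        assert (out.fp, out.fn) == (6, 2)
        assert (out.tp, out.tn) == (23, 19)
        assert set(out.flagged_fp) == {f"S{i}" for i in range(6)}
        assert set(out.flagged_fn) == {"S10", "S11"}

    def test_inclusive_boundary(self):
        """Task values exactly at max(R) are all false positives."""
        r = series({"S1": 1.0, "S2": 4.0})
        t = series({"S1": 4.0, "S2": 4.0})
        out = subject_status(r, t)
        assert out.fp == 2

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(AlignmentError, match="S3"):
            subject_status(series({"S1": 1, "S2": 2}),
                           series({"S1": 1, "S3": 2}))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=1, max_size=50))
    def test_matches_enumeration_oracle(self, pairs):
        vals_r = {f"S{i}": r for i, (r, _) in enumerate(pairs)}
        vals_t = {f"S{i}": t for i, (_, t) in enumerate(pairs)}
        out = subject_status(series(vals_r), series(vals_t))
        fp, fn = enumeration_oracle(vals_r, vals_t)
        assert (out.fp, out.fn) == (fp, fn)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 10), st.floats(0, 10)),
                    min_size=2, max_size=12), st.randoms())
    def test_permutation_invariance(self, pairs, rnd):
        vals_r = {f"S{i}": r for i, (r, _) in enumerate(pairs)}
        vals_t = {f"S{i}": t for i, (_, t) in enumerate(pairs)}
        out = subject_status(series(vals_r), series(vals_t))
        order = list(vals_r)
        rnd.shuffle(order)
        out2 = subject_status(series(vals_r).loc[order],
                              series(vals_t).loc[order])
        assert (out.fp, out.fn) == (out2.fp, out2.fn)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=1, max_size=20))
    def test_zero_errors_iff_task_range_above_resting_range(self, pairs):
        """FP = FN = 0 exactly when the T interval lies strictly above R."""
        vals_r = {f"S{i}": r for i, (r, _) in enumerate(pairs)}
        vals_t = {f"S{i}": t for i, (_, t) in enumerate(pairs)}
        out = subject_status(series(vals_r), series(vals_t))
        above = min(vals_t.values()) > max(vals_r.values())
        assert (out.fp == 0 and out.fn == 0) == above

    def test_outcome_identities(self):
        out = ClassificationOutcome("F7", "theta", "G", n=25, fp=6, fn=2)
        assert out.tp == 25 - 2 and out.tn == 25 - 6
        with pytest.raises(ValueError):
            ClassificationOutcome("F7", "theta", "G", n=5, fp=6, fn=0)


class TestDiscriminatingSignals:
    def test_constructed_single_discriminator(self):
        """Only F7-theta is disjoint; everything else overlaps."""
        subjects = ["S1", "S2", "S3"]
        values = {}
        for band in ("theta", "alpha", "beta"):
            for ch in ("F7", "Fz"):
                for i, sid in enumerate(subjects):
                    if (ch, band) == ("F7", "theta"):
                        r, t = 1.0 + i * 0.1, 8.0 + i * 0.1
                    else:
                        r, t = 1.0 + i, 1.5 + i  # interleaved: overlap
                    values[(sid, ch, band, "R")] = r
                    values[(sid, ch, band, "T")] = t
        peaks = make_peaks(values)
        assert discriminating_signals(peaks, "G", subjects,
                                      bands=CANONICAL_BANDS) == [("F7", "theta")]

    def test_no_disjoint_ranges_gives_empty_list(self):
        subjects = ["S1", "S2"]
        values = {}
        for band in ("theta", "alpha", "beta"):
            for i, sid in enumerate(subjects):
                values[(sid, "F7", band, "R")] = 1.0 + i
                values[(sid, "F7", band, "T")] = 1.5 + i
        assert discriminating_signals(make_peaks(values), "G", subjects) == []

    def test_band_overlapping_everywhere_absent(self, small_cohort,
                                                small_peaks):
        """On the generated cohort the designated channels discriminate in
        theta/beta while alpha (no designations) never does."""
        _, dataset, truth = small_cohort
        out = discriminating_signals(small_peaks, "G",
                                     dataset.subjects("G"))
        designated = set(truth.designated_channels)
        assert designated <= set(out)
        assert all(band != "alpha" for _, band in out)
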