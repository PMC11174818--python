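"""Range-limit classification of spectral peaks.

For each (channel, band) and subject group, the set of per-subject peak
magnitudes in the resting state and the set in the task state define
two closed intervals [min, max]. A (channel, band) discriminates the
two mental states when the intervals are disjoint; any shared point
(including a touching endpoint) counts as overlap.

Subject-level error statuses are group-referenced:

    FP: subject's task value  <= MAX over all resting values
    FN: subject's rest value  >= MIN over all task values
    TP = n - FN,  TN = n - FP

so FP = FN = 0 exactly when the two intervals are disjoint with every
task value above every resting value (task spectral peaks are expected
to exceed resting ones in the discriminating bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import CANONICAL_BANDS, BandDefinition

__all__ = [
    "RangeSummary",
    "ClassificationOutcome",
    "SelectionError",
    "AlignmentError",
    "range_summary",
    "is_disjoint",
    "subject_status",
    "discriminating_signals",
    "subject_peak_values",
]


class SelectionError(ValueError):
    """No peak rows match the requested selection."""


class AlignmentError(ValueError):
    """R and T inputs do not cover the same subject set."""


@dataclass(frozen=True)
class RangeSummary:
    """Min/max/median of peak magnitudes over a group in one state."""

    channel: str
    band: str
    state: str
    group: str
    min: float
    max: float
    median: float
    n: int

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ValueError("requires min <= median <= max")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class ClassificationOutcome:
    """FP/FN/TP/TN counts for one (channel, band, group)."""

    channel: str
    band: str
    group: str
    n: int
    fp: int
    fn: int
    flagged_fp: tuple[str, ...] = ()
    flagged_fn: tuple[str, ...] = ()
    tp: int = field(init=False)
    tn: int = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.fp <= self.n and 0 <= self.fn <= self.n):
            raise ValueError("FP/FN must lie in [0, n]")
        self.tp = self.n - self.fn
        self.tn = self.n - self.fp


def subject_peak_values(
    peaks: pd.DataFrame,
    channel: str,
    band: str,
    state: str,
    subjects: list[str],
) -> pd.Series:
    """Per-subject peak magnitudes for one selection, indexed by subject."""
    sel = peaks[
        (peaks["channel"] == channel)
        & (peaks["band"] == band)
        & (peaks["state"] == state)
        & (peaks["subject_id"].isin(subjects))
    ]
    if sel.empty:
        raise SelectionError(
            f"no peaks for channel={channel} band={band} state={state}"
        )
    return sel.set_index("subject_id")["peak_magnitude"]


def range_summary(
    peaks: pd.DataFrame,
    channel: str,
    band: str,
    state: str,
    group: str,
    subjects: list[str],
) -> RangeSummary:
    """Summarize a group's peak-magnitude range in one state."""
    vals = subject_peak_values(peaks, channel, band, state, subjects)
    return RangeSummary(
        channel=channel, band=band, state=state, group=group,
        min=float(vals.min()), max=float(vals.max()),
        median=float(vals.median()), n=len(vals),
    )


def is_disjoint(range_r: RangeSummary, range_t: RangeSummary) -> bool:
    """True iff [min_R, max_R] and [min_T, max_T] share no point.

    A shared endpoint counts as overlap (closed intervals).
    """
    if (range_r.channel, range_r.band) != (range_t.channel, range_t.band):
        raise ValueError("ranges must refer to the same channel and band")
    return range_r.max < range_t.min or range_t.max < range_r.min


def subject_status(
    peaks_r: pd.Series,
    peaks_t: pd.Series,
    channel: str = "",
    band: str = "",
    group: str = "",
) -> ClassificationOutcome:
    """Apply the group-referenced FP/FN rules to aligned per-subject values.

    Both inputs are indexed by subject id and must cover the same
    subjects. The comparisons are inclusive (<=, >=), so a task value
    exactly at the resting maximum is a false positive and a resting
    value exactly at the task minimum is a false negative.
    """
    set_r, set_t = set(peaks_r.index), set(peaks_t.index)
    if set_r != set_t:
        raise AlignmentError(
            f"subject sets differ: only-R={sorted(set_r - set_t)}, "
            f"only-T={sorted(set_t - set_r)}"
        )
    if len(peaks_r) < 1:
        raise AlignmentError("need at least one subject")
    max_r = float(peaks_r.max())
    min_t = float(peaks_t.min())
    fp_subjects = tuple(sorted(peaks_t.index[peaks_t <= max_r]))
    fn_subjects = tuple(sorted(peaks_r.index[peaks_r >= min_t]))
    return ClassificationOutcome(
        channel=channel, band=band, group=group, n=len(peaks_r),
        fp=len(fp_subjects), fn=len(fn_subjects),
        flagged_fp=fp_subjects, flagged_fn=fn_subjects,
    )


def discriminating_signals(
    peaks: pd.DataFrame,
    group: str,
    subjects: list[str],
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
) -> list[tuple[str, str]]:
    """All (channel, band) whose R/T ranges are disjoint for the group.

    Output in canonical order: channels in montage order within each
    band, bands in theta/alpha/beta order.
    """
    channels = [c for c in peaks["channel"].unique()]
    # preserve montage order as it appears in the peak table
    seen = dict.fromkeys(peaks["channel"])
    channels = list(seen)
    out: list[tuple[str, str]] = []
    for band in bands:
        for channel in channels:
            r = range_summary(peaks, channel, band.name, "R", group, subjects)
            t = range_summary(peaks, channel, band.name, "T", group, subjects)
            if is_disjoint(r, t):
                out.append((channel, band.name))
    return out
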