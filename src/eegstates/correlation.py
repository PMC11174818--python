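"""Pairwise Pearson correlation and the conjugate threshold discriminator.

For every unordered pair of the 19 channels (171 pairs) the Pearson
coefficient is computed per subject, state and signal type (raw or one
of the three bands). The discriminator applies the conjugate conditions

    c_corr R > threshold    and    c_corr T < threshold

over a subject group: N is the set of subjects meeting the resting
condition, M the set meeting the task condition, and CS = N & M the
common subjects whose states the pair classifies correctly; the pair's
confidence is 100 * |CS| / group size. Pairs are ranked by |CS|.

The Pearson coefficient follows the population definition (divisor n in
the standard deviations); the n's cancel, so it coincides with the
sample coefficient wherever both are defined.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CANONICAL_CHANNELS, Recording, StudyDataset
from .filtering import (
    CANONICAL_BANDS,
    DEFAULT_SETTLE_S,
    BandDefinition,
    apply_bandpass,
    design_bandpass,
)

__all__ = [
    "UndefinedCorrelationError",
    "pearson",
    "pairwise_correlations",
    "compute_correlation_table",
    "SubjectCountMatrix",
    "count_matrix",
    "PairDiscriminationResult",
    "discriminating_pairs",
    "threshold_sweep",
    "CHANNEL_PAIRS",
]

logger = logging.getLogger(__name__)

#: All 171 unordered channel pairs in canonical order (a before b).
CHANNEL_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(CANONICAL_CHANNELS, 2)
)


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined for a constant series."""


def pearson(s1: np.ndarray, s2: np.ndarray) -> float:
    """Pearson correlation of two equal-length series.

    Computed directly from the defining sum with population standard
    deviations: R = sum((s1-m1)(s2-m2)) / (n * sigma1 * sigma2).

    Raises
    ------
    UndefinedCorrelationError
        If either series is constant (zero standard deviation).
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1 or s1.size < 2:
        raise ValueError("series must be equal-length 1-D with n >= 2")
    d1 = s1 - s1.mean()
    d2 = s2 - s2.mean()
    n = s1.size
    sd1 = np.sqrt((d1 @ d1) / n)
    sd2 = np.sqrt((d2 @ d2) / n)
    if sd1 == 0.0 or sd2 == 0.0:
        raise UndefinedCorrelationError("constant series has no defined correlation")
    r = float((d1 @ d2) / (n * sd1 * sd2))
    return max(-1.0, min(1.0, r))  # clip round-off just past +/-1


def pairwise_correlations(recording: Recording) -> pd.DataFrame:
    """Pearson coefficients for all 171 channel pairs of one recording.

    Trivial self-pairs are excluded. Transient-flagged samples are
    dropped before computation. Undefined pairs (a constant channel)
    are recorded with r = NaN and a logged warning; downstream counting
    excludes them.

    Returns a DataFrame with columns
    subject_id, state, band, channel_a, channel_b, r.
    """
    data = recording.settled()
    n_ch = data.shape[0]
    means = data.mean(axis=1, keepdims=True)
    dev = data - means
    sd = dev.std(axis=1)  # population (divisor n)
    constant = sd == 0.0
    if np.any(constant):
        bad = [recording.channels.names[i] for i in np.flatnonzero(constant)]
        logger.warning(
            "subject %s state %s band %s: constant channel(s) %s; "
            "correlations undefined and excluded from counts",
            recording.subject_id, recording.state, recording.band, bad,
        )
    cov = (dev @ dev.T) / data.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr = np.clip(corr, -1.0, 1.0)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    rows = []
    names = recording.channels.names
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            rows.append({
                "subject_id": recording.subject_id,
                "state": recording.state,
                "band": recording.band if recording.band is not None else "raw",
                "channel_a": names[i],
                "channel_b": names[j],
                "r": corr[i, j],
            })
    return pd.DataFrame(rows)


def compute_correlation_table(
    dataset: StudyDataset,
    group: str | None = None,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
    include_raw: bool = True,
    settle_s: float = DEFAULT_SETTLE_S,
) -> pd.DataFrame:
    """All pair correlations for a group: per subject, state and signal type.

    ``band`` is "raw" for the unfiltered acquisition-band signal, else
    the band name.
    """
    subjects = dataset.subjects(group)
    if not subjects:
        raise ValueError(f"empty group {group!r}")
    frames = []
    specs = [design_bandpass(b, next(iter(dataset.recordings.values())).rate)
             for b in bands]
    for sid in subjects:
        for state in ("R", "T"):
            rec = dataset.get(sid, state)
            if include_raw:
                frames.append(pairwise_correlations(rec))
            for b, spec in zip(bands, specs):
                frames.append(
                    pairwise_correlations(apply_bandpass(rec, spec, settle_s))
                )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SubjectCountMatrix:
    """19x19 symmetric matrix of subjects meeting a threshold condition.

    ``condition`` is "R_above" (c_corr R > threshold) or "T_below"
    (c_corr T < threshold); the diagonal is empty (self-pairs are
    trivial and excluded).
    """

    band: str
    condition: str
    threshold: float
    n_group: int
    counts: pd.DataFrame  # channel-labelled 19x19 integer frame

    def pair_count(self, a: str, b: str) -> int:
        return int(self.counts.loc[a, b])


def _condition_mask(r: pd.Series, condition: str, threshold: float) -> pd.Series:
    # Strict inequalities: a value equal to the threshold satisfies neither.
    if condition == "R_above":
        return r > threshold
    if condition == "T_below":
        return r < threshold
    raise ValueError(f"condition must be 'R_above' or 'T_below', got {condition!r}")


def count_matrix(
    corr_table: pd.DataFrame,
    band: str,
    condition: str,
    threshold: float,
) -> SubjectCountMatrix:
    """Count, per pair, the subjects satisfying the strict condition.

    ``corr_table`` is the output of :func:`compute_correlation_table`
    restricted to one group. NaN correlations (undefined pairs) never
    satisfy a condition.
    """
    state = "R" if condition == "R_above" else "T"
    sub = corr_table[(corr_table["band"] == band) & (corr_table["state"] == state)]
    if sub.empty:
        raise ValueError(f"no correlations for band {band!r}, state {state!r}")
    n_group = sub["subject_id"].nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        hits = sub.assign(hit=_condition_mask(sub["r"], condition, threshold))
    tallies = hits.groupby(["channel_a", "channel_b"])["hit"].sum()
    mat = pd.DataFrame(0, index=list(CANONICAL_CHANNELS),
                       columns=list(CANONICAL_CHANNELS), dtype=int)
    for (a, b), v in tallies.items():
        mat.loc[a, b] = int(v)
        mat.loc[b, a] = int(v)
    return SubjectCountMatrix(band=band, condition=condition,
                              threshold=threshold, n_group=n_group, counts=mat)


@dataclass
class PairDiscriminationResult:
    """Discriminator outcome for one channel pair.

    N: subjects with c_corr R > threshold; M: subjects with
    c_corr T < threshold; CS = N & M; confidence = 100 |CS| / n_group.
    """

    channel_a: str
    channel_b: str
    band: str
    threshold: float
    n_group: int
    n_set: frozenset[str]
    m_set: frozenset[str]
    cs: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.cs = frozenset(self.n_set & self.m_set)

    @property
    def confidence_pct(self) -> float:
        return 100.0 * len(self.cs) / self.n_group


def discriminating_pairs(
    corr_table: pd.DataFrame,
    band: str,
    threshold: float = 0.5,
) -> list[PairDiscriminationResult]:
    """Rank all pairs by |CS| = |N & M| descending.

    Ties are broken by canonical pair order. The top-ranked pairs
    maximize the number of subjects whose two states are both correctly
    classified by the conjugate conditions.
    """
    sub = corr_table[corr_table["band"] == band]
    if sub.empty:
        raise ValueError(f"no correlations for band {band!r}")
    n_group = sub["subject_id"].nunique()
    results = []
    grouped = sub.groupby(["channel_a", "channel_b", "state"])
    sets: dict[tuple[str, str, str], frozenset[str]] = {}
    for (a, b, state), g in grouped:
        cond = "R_above" if state == "R" else "T_below"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ok = _condition_mask(g["r"], cond, threshold)
        sets[(a, b, state)] = frozenset(g.loc[ok.fillna(False), "subject_id"])
    pair_rank = {p: i for i, p in enumerate(CHANNEL_PAIRS)}
    for a, b in CHANNEL_PAIRS:
        results.append(PairDiscriminationResult(
            channel_a=a, channel_b=b, band=band, threshold=threshold,
            n_group=n_group,
            n_set=sets.get((a, b, "R"), frozenset()),
            m_set=sets.get((a, b, "T"), frozenset()),
        ))
    results.sort(key=lambda r: (-len(r.cs), pair_rank[(r.channel_a, r.channel_b)]))
    return results


def threshold_sweep(
    corr_table: pd.DataFrame,
    r_thresholds: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8),
    t_threshold: float = 0.5,
    min_subjects: int = 1,
    bands: tuple[str, ...] = ("raw", "theta", "alpha", "beta"),
) -> pd.DataFrame:
    """Count pairs fulfilling each condition per signal type and threshold.

    For each (signal type, threshold) cell the reported number is the
    count of channel pairs whose subject count for the condition reaches
    ``min_subjects`` (default 1; the criterion is configurable because
    the per-pair reporting rule is a study choice, and it is recorded in
    pipeline provenance). Counts are monotone non-increasing along
    increasing thresholds since the strict conditions are nested.
    """
    rows = []
    for band in bands:
        row: dict[str, object] = {"signal_type": band}
        for thr in r_thresholds:
            cm = count_matrix(corr_table, band, "R_above", thr)
            tri = cm.counts.values[np.triu_indices(len(CANONICAL_CHANNELS), k=1)]
            row[f"R>{thr:g}"] = int((tri >= min_subjects).sum())
        cm = count_matrix(corr_table, band, "T_below", t_threshold)
        tri = cm.counts.values[np.triu_indices(len(CANONICAL_CHANNELS), k=1)]
        row[f"T<{t_threshold:g}"] = int((tri >= min_subjects).sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("signal_type")
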