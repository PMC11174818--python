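"""Model-style front ends for the two state-discrimination criteria.

Two model classes are fitted to a :class:`~eegstates.data.StudyDataset`
and return results objects carrying the estimates, diagnostics and a
``summary()`` table:

* :class:`SpectralRangeClassification` — the spectral-peak range-limit
  criterion: band-filter every recording, extract per-band spectral
  peaks, compare group-level [min, max] ranges between states, classify
  subjects (FP/FN/TP/TN) and compute the six performance measures.
* :class:`CorrelationDiscrimination` — the conjugate Pearson-threshold
  criterion: correlate all 171 channel pairs per band and state, count
  subjects meeting c_corr R > thr and c_corr T < thr, rank pairs by the
  number of common subjects, and sweep thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as _classify
from . import correlation as _correlation
from . import metrics as _metrics
from . import spectral as _spectral
from .data import StudyDataset
from .filtering import CANONICAL_BANDS, DEFAULT_SETTLE_S, BandDefinition

__all__ = [
    "SpectralRangeClassification",
    "SpectralRangeResults",
    "CorrelationDiscrimination",
    "CorrelationResults",
]


class SpectralRangeClassification:
    """Range-limit mental-state classifier over spectral peaks.

    Parameters
    ----------
    dataset : StudyDataset
    groups : tuple of str
        Subject groups analyzed ("G", "B", "G*").
    bands : tuple of BandDefinition
    settle_s : float
        Leading seconds of filter output excluded as transient.
    specificity_mode : str
        "table_consistent" (TN/(TN+FP), default) or "paper_literal"
        (TN/(TN+FN)).
    """

    def __init__(
        self,
        dataset: StudyDataset,
        groups: tuple[str, ...] = ("G", "B", "G*"),
        bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
        settle_s: float = DEFAULT_SETTLE_S,
        specificity_mode: str = "table_consistent",
    ) -> None:
        dataset.validate_complete()
        self.dataset = dataset
        self.groups = groups
        self.bands = bands
        self.settle_s = settle_s
        self.specificity_mode = specificity_mode

    def fit(self, peaks: pd.DataFrame | None = None) -> "SpectralRangeResults":
        """Run the full criterion; optionally reuse a precomputed peak table."""
        if peaks is None:
            peaks = _spectral.collect_peaks(self.dataset, bands=self.bands,
                                            settle_s=self.settle_s)
        outcomes = []
        summaries = []
        discriminators: dict[str, list[tuple[str, str]]] = {}
        for group in self.groups:
            subjects = self.dataset.subjects(group)
            if not subjects:
                raise ValueError(f"group {group!r} has no subjects")
            discriminators[group] = _classify.discriminating_signals(
                peaks, group, subjects, bands=self.bands)
            for band in self.bands:
                for channel in self.dataset.recordings[
                        next(iter(self.dataset.recordings))].channels:
                    vals_r = _classify.subject_peak_values(
                        peaks, channel, band.name, "R", subjects)
                    vals_t = _classify.subject_peak_values(
                        peaks, channel, band.name, "T", subjects)
                    outcomes.append(_classify.subject_status(
                        vals_r, vals_t, channel=channel, band=band.name,
                        group=group))
                    for state in ("R", "T"):
                        summaries.append(_classify.range_summary(
                            peaks, channel, band.name, state, group, subjects))
        return SpectralRangeResults(
            model=self,
            peaks=peaks,
            outcomes=outcomes,
            range_summaries=pd.DataFrame([s.__dict__ for s in summaries]),
            discriminators=discriminators,
            metrics=_metrics.metrics_table(outcomes, self.specificity_mode),
        )


@dataclass
class SpectralRangeResults:
    """Fitted range-limit classification results."""

    model: SpectralRangeClassification
    peaks: pd.DataFrame
    outcomes: list
    range_summaries: pd.DataFrame
    discriminators: dict[str, list[tuple[str, str]]]
    metrics: pd.DataFrame

    def metrics_for(self, channel: str, band: str, group: str) -> pd.Series:
        m = self.metrics
        row = m[(m["channel"] == channel) & (m["band"] == band)
                & (m["group"] == group)]
        if row.empty:
            raise KeyError((channel, band, group))
        return row.iloc[0]

    def summary(self, only_discriminators: bool = True) -> str:
        """Human-readable report: discriminators and their measures."""
        lines = ["Spectral-peak range-limit classification", "=" * 44]
        for group, sigs in self.discriminators.items():
            pretty = ", ".join(f"{c} ({b})" for c, b in sigs) or "none"
            lines.append(f"group {group}: disjoint R/T ranges at: {pretty}")
        lines.append("")
        table = self.metrics
        if only_discriminators:
            keep = [
                (r["channel"], r["band"], r["group"]) in {
                    (c, b, g) for g, sigs in self.discriminators.items()
                    for c, b in sigs}
                or r["fp"] + r["fn"] < r["n"] // 2
                for _, r in table.iterrows()
            ]
            table = table[pd.Series(keep, index=table.index)]
        shown = _metrics.format_metrics_table(table)
        lines.append(shown.to_string(index=False))
        return "\n".join(lines)

    def plot_ranges(self, band: str, group: str, ax=None):
        """Min-max range bars per channel for both states, with medians."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        rs = self.range_summaries
        sel = rs[(rs["band"] == band) & (rs["group"] == group)]
        channels = list(dict.fromkeys(sel["channel"]))
        for i, ch in enumerate(channels):
            for state, color, dx in (("R", "tab:blue", -0.15),
                                     ("T", "tab:red", 0.15)):
                row = sel[(sel["channel"] == ch) & (sel["state"] == state)].iloc[0]
                ax.plot([i + dx, i + dx], [row["min"], row["max"]],
                        color=color, lw=3)
                ax.plot(i + dx, row["median"], "o", color=color, ms=4)
        ax.set_xticks(range(len(channels)), channels, rotation=45)
        ax.set_ylabel("spectral peak (uV)")
        ax.set_title(f"{band} band, group {group} (blue R, red T)")
        return ax


class CorrelationDiscrimination:
    """Conjugate Pearson-threshold discriminator over channel pairs."""

    def __init__(
        self,
        dataset: StudyDataset,
        group: str = "G",
        bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
        include_raw: bool = True,
        threshold: float = 0.5,
        sweep_thresholds: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8),
        settle_s: float = DEFAULT_SETTLE_S,
    ) -> None:
        if not 0 < threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        dataset.validate_complete()
        self.dataset = dataset
        self.group = group
        self.bands = bands
        self.include_raw = include_raw
        self.threshold = threshold
        self.sweep_thresholds = sweep_thresholds
        self.settle_s = settle_s

    def fit(self, corr_table: pd.DataFrame | None = None) -> "CorrelationResults":
        if corr_table is None:
            corr_table = _correlation.compute_correlation_table(
                self.dataset, self.group, bands=self.bands,
                include_raw=self.include_raw, settle_s=self.settle_s)
        band_names = [b.name for b in self.bands]
        count_matrices = {}
        signal_types = (["raw"] if self.include_raw else []) + band_names
        for band in signal_types:
            for condition in ("R_above", "T_below"):
                count_matrices[(band, condition)] = _correlation.count_matrix(
                    corr_table, band, condition, self.threshold)
        pair_results = {
            band: _correlation.discriminating_pairs(corr_table, band,
                                                    self.threshold)
            for band in band_names
        }
        sweep = _correlation.threshold_sweep(
            corr_table, r_thresholds=self.sweep_thresholds,
            t_threshold=self.threshold, bands=tuple(signal_types))
        return CorrelationResults(
            model=self, corr_table=corr_table,
            count_matrices=count_matrices, pair_results=pair_results,
            sweep=sweep,
        )


@dataclass
class CorrelationResults:
    """Fitted conjugate-threshold discrimination results."""

    model: CorrelationDiscrimination
    corr_table: pd.DataFrame
    count_matrices: dict[tuple[str, str], "_correlation.SubjectCountMatrix"]
    pair_results: dict[str, list["_correlation.PairDiscriminationResult"]]
    sweep: pd.DataFrame

    def top_pairs(self, band: str, k: int = 4) -> pd.DataFrame:
        """The k pairs with the largest common-subject sets."""
        rows = []
        for res in self.pair_results[band][:k]:
            rows.append({
                "pair": f"{res.channel_a}-{res.channel_b}", "band": band,
                "n_N": len(res.n_set), "n_M": len(res.m_set),
                "n_CS": len(res.cs),
                "confidence_pct": res.confidence_pct,
                "members_CS": " ".join(sorted(res.cs)),
            })
        return pd.DataFrame(rows)

    def summary(self, k: int = 4) -> str:
        lines = [
            "Conjugate correlation-threshold discrimination",
            "=" * 46,
            f"group {self.model.group}, threshold {self.model.threshold}",
            "",
            "Pairs fulfilling the conditions per signal type and threshold:",
            self.sweep.to_string(),
            "",
        ]
        for band in self.pair_results:
            lines.append(f"top pairs by |N & M| in {band}:")
            lines.append(self.top_pairs(band, k).to_string(index=False))
            lines.append("")
        return "\n".join(lines)

    def plot_count_matrix(self, band: str, condition: str, ax=None):
        """Heatmap of the 19x19 subject-count matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 6))
        cm = self.count_matrices[(band, condition)]
        im = ax.imshow(cm.counts.values, cmap="viridis",
                       vmin=0, vmax=cm.n_group)
        ax.set_xticks(range(19), cm.counts.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(19), cm.counts.index, fontsize=7)
        ax.set_title(f"{band}, {condition} @ {cm.threshold:g} "
                     f"(n={cm.n_group})")
        ax.figure.colorbar(im, ax=ax, shrink=0.8)
        return ax
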