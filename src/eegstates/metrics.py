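"""Confusion-matrix performance measures for range-limit classification.

Six measures are derived from the subject-level TP/TN/FP/FN counts:
accuracy, precision, F1, sensitivity, specificity (as percentages) and
Matthews correlation coefficient (MCC, in [-1, 1]).

Two specificity conventions are provided. The reference analysis prints
the formula TN/(TN+FN) but its reported values are consistent only with
the standard TN/(TN+FP); the default mode ``table_consistent`` uses
TN/(TN+FP), while ``paper_literal`` applies TN/(TN+FN) as printed.
Any ratio with a zero denominator is reported as NaN with a logged
reason, never silently as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .classify import ClassificationOutcome

__all__ = ["MetricSet", "compute_metrics", "metrics_table"]

logger = logging.getLogger(__name__)

SPECIFICITY_MODES = ("table_consistent", "paper_literal")


@dataclass(frozen=True)
class MetricSet:
    """The six performance measures; percentages in [0, 100], MCC in [-1, 1]."""

    accuracy: float
    precision: float
    f1: float
    sensitivity: float
    specificity: float
    mcc: float
    specificity_mode: str = "table_consistent"


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reported as NaN", name)
        return math.nan
    return num / den


def compute_metrics(
    outcome: ClassificationOutcome,
    specificity_mode: str = "table_consistent",
) -> MetricSet:
    """Six performance measures from a classification outcome."""
    if specificity_mode not in SPECIFICITY_MODES:
        raise ValueError(f"unknown specificity_mode {specificity_mode!r}")
    tp, tn, fp, fn = outcome.tp, outcome.tn, outcome.fp, outcome.fn
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = 100.0 * _ratio(tp + tn, total, "accuracy")
    precision = 100.0 * _ratio(tp, tp + fp, "precision")
    f1 = 100.0 * _ratio(2 * tp, 2 * tp + fp + fn, "F1")
    sensitivity = 100.0 * _ratio(tp, tp + fn, "sensitivity")
    spec_den = (tn + fp) if specificity_mode == "table_consistent" else (tn + fn)
    specificity = 100.0 * _ratio(tn, spec_den, "specificity")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        logger.warning("MCC undefined (zero denominator); reported as NaN")
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricSet(
        accuracy=accuracy, precision=precision, f1=f1,
        sensitivity=sensitivity, specificity=specificity, mcc=mcc,
        specificity_mode=specificity_mode,
    )


def metrics_table(
    outcomes: list[ClassificationOutcome],
    specificity_mode: str = "table_consistent",
) -> pd.DataFrame:
    """Report table: one row per (channel, band, group).

    Full-precision values are stored; use :func:`format_metrics_table`
    for the display convention (integer percentages, two-decimal MCC).
    """
    rows = []
    for o in outcomes:
        m = compute_metrics(o, specificity_mode)
        rows.append({
            "channel": o.channel, "band": o.band, "group": o.group,
            "n": o.n, "tp": o.tp, "tn": o.tn, "fp": o.fp, "fn": o.fn,
            "accuracy_pct": m.accuracy, "precision_pct": m.precision,
            "mcc": m.mcc, "f1_pct": m.f1,
            "sensitivity_pct": m.sensitivity, "specificity_pct": m.specificity,
        })
    cols = ["channel", "band", "group", "n", "tp", "tn", "fp", "fn",
            "accuracy_pct", "precision_pct", "mcc", "f1_pct",
            "sensitivity_pct", "specificity_pct"]
    return pd.DataFrame(rows, columns=cols)


def format_metrics_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display rounding: percentages to the nearest integer, MCC to 2 dp."""
    out = table.copy()
    for col in ("accuracy_pct", "precision_pct", "f1_pct",
                "sensitivity_pct", "specificity_pct"):
        out[col] = out[col].round(0).astype("Int64")
    out["mcc"] = out["mcc"].round(2)
    return out
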