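"""Evaluation metrics for imbalanced responder classification.

Implements the metric suite used to judge responder prediction — MCC,
macro F1, accuracy, precision, recall (TPR) and specificity (TNR) — at
overall, per-participant and per-AIS-grade granularity, together with the
closed-form chance baseline of a prevalence-matched random predictor and a
utility that reconstructs integer confusion counts from printed
two-decimal metrics.

Zero-denominator convention: any ratio with an empty denominator is 0
(e.g. recall for a participant with no responder muscles), and MCC with a
zero factor under the square root is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Sequence

import numpy as np

from .simulate import RESPONDER

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ReconstructionError",
    "confusion",
    "mcc",
    "metric_suite",
    "participant_metrics",
    "ais_breakdown",
    "chance_baseline",
    "reconstruct_confusion",
    "round_half_up",
]


class ReconstructionError(ValueError):
    """No or multiple integer confusion matrices match the printed metrics."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass
class MetricsReport:
    mcc: float
    macro_f1: float
    accuracy: float
    precision: float
    recall_tpr: float
    tnr: float
    granularity: str = "overall"
    n: int = 0


def confusion(records: Sequence) -> ConfusionCounts:
    """Tally muscle-level predictions (one record per muscle, not per trial)."""
    records = list(records)
    if not records:
        raise ValueError("no prediction records")
    tp = fp = fn = tn = 0
    for r in records:
        truth = r.true_label == RESPONDER
        pred = r.final_label == RESPONDER
        if truth and pred:
            tp += 1
        elif truth:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; zero-denominator convention -> 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metric_suite(c: ConfusionCounts, granularity: str = "overall") -> MetricsReport:
    """Full metric suite from confusion counts.

    Macro F1 averages the per-class F1 of the responder and non-responder
    classes; undefined ratios follow the zero-denominator convention.
    """
    if c.n == 0:
        raise ValueError("empty confusion matrix")
    precision = _safe_div(c.tp, c.tp + c.fp)
    recall = _safe_div(c.tp, c.tp + c.fn)
    tnr = _safe_div(c.tn, c.tn + c.fp)
    f1_pos = _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    f1_neg = _safe_div(2 * c.tn, 2 * c.tn + c.fn + c.fp)
    return MetricsReport(
        mcc=mcc(c),
        macro_f1=(f1_pos + f1_neg) / 2.0,
        accuracy=(c.tp + c.tn) / c.n,
        precision=precision,
        recall_tpr=recall,
        tnr=tnr,
        granularity=granularity,
        n=c.n,
    )


def participant_metrics(records: Sequence) -> Dict[str, MetricsReport]:
    """Per-participant metric reports (LOPO participant-specific evaluation)."""
    by_p: Dict[str, List] = {}
    for r in records:
        by_p.setdefault(r.participant_id, []).append(r)
    return {
        pid: metric_suite(confusion(rs), granularity="participant")
        for pid, rs in sorted(by_p.items())
    }


def ais_breakdown(
    records: Sequence, participant_ais: Dict[str, str]
) -> Dict[str, MetricsReport]:
    """Metric reports per AIS grade, partitioning all records by grade."""
    by_g: Dict[str, List] = {}
    for r in records:
        by_g.setdefault(participant_ais[r.participant_id], []).append(r)
    return {
        g: metric_suite(confusion(rs), granularity="ais_grade")
        for g, rs in sorted(by_g.items())
    }


def chance_baseline(n: int, n_pos: int) -> MetricsReport:
    """Expected metrics of a prevalence-matched independent random predictor.

    With prevalence pi = n_pos / n: accuracy = pi^2 + (1-pi)^2,
    precision = recall = pi, TNR = 1 - pi, macro F1 = 1/2, MCC = 0.
    """
    if not 0 < n_pos < n:
        raise ValueError("chance baseline needs 0 < n_pos < n")
    pi = n_pos / n
    return MetricsReport(
        mcc=0.0,
        macro_f1=0.5,
        accuracy=pi**2 + (1 - pi) ** 2,
        precision=pi,
        recall_tpr=pi,
        tnr=1 - pi,
        granularity="chance",
        n=n,
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round-half-up to the printed precision (0.425 -> 0.43)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def reconstruct_confusion(
    n: int,
    n_pos: int,
    precision_2dp: float,
    recall_2dp: float,
    tnr_2dp: float,
) -> ConfusionCounts:
    """Recover integer confusion counts from metrics printed to 2 decimals.

    Exhaustive search over TP in 0..n_pos and FP in 0..(n - n_pos) for
    counts whose half-up-rounded precision/recall/TNR reproduce the printed
    values; errors if no or several matrices match.
    """
    n_neg = n - n_pos
    matches = []
    for tp in range(n_pos + 1):
        fn = n_pos - tp
        if round_half_up(_safe_div(tp, n_pos)) != round_half_up(recall_2dp):
            continue
        for fp in range(n_neg + 1):
            tn = n_neg - fp
            if round_half_up(_safe_div(tn, n_neg)) != round_half_up(tnr_2dp):
                continue
            if round_half_up(_safe_div(tp, tp + fp)) != round_half_up(precision_2dp):
                continue
            matches.append(ConfusionCounts(tp, fp, fn, tn))
    if not matches:
        raise ReconstructionError("no confusion matrix matches the printed metrics")
    if len(matches) > 1:
        raise ReconstructionError(
            f"{len(matches)} confusion matrices match the printed metrics: {matches}"
        )
    return matches[0]
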