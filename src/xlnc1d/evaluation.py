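"""Classifier evaluation: confusion counts, derived metrics, ROC/AUC,
accuracy by sequence-length bin, and annotation-summary percentages.

lncRNA is the positive class: TP = lncRNA called lncRNA, TN = mRNA called
mRNA, FP = mRNA called lncRNA, FN = lncRNA called mRNA. Metrics are
reported on the 0-100 scale; display rounding is half-up at two decimals
and exact (integer counts are carried through rational arithmetic), while
full-precision values remain available. Metrics with a zero denominator
are reported as None, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve, roc_auc_score as _sk_roc_auc

from .cnn_model import PredictionRecord
from .sequence_io import LNCRNA, MRNA


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _pct(num: Fraction | int, den: Fraction | int) -> Fraction | None:
    if den == 0:
        return None
    return Fraction(100) * Fraction(num) / Fraction(den)


def round_half_up(value: Fraction | float, digits: int = 2) -> float:
    """Half-up rounding (the convention of printed tables), exact for rationals."""
    if isinstance(value, Fraction):
        d = Decimal(int(value.numerator)) / Decimal(int(value.denominator))
    else:
        d = Decimal(repr(float(value)))
    return float(d.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """Percent-scale metrics (full precision); ``rounded()`` gives 2-dp display."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    auc: float | None = None

    _FIELDS = ("accuracy", "sensitivity", "specificity", "precision", "f1")

    def rounded(self) -> dict[str, float | None]:
        out = {
            name: (None if v is None else round_half_up(v, 2))
            for name in self._FIELDS
            for v in [getattr(self, name)]
        }
        out["auc"] = None if self.auc is None else round(self.auc, 4)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.rounded()])


def confusion(
    labels: Mapping[str, str], predictions: Sequence[PredictionRecord]
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN; ids must match one-to-one with the label map."""
    pred_ids = [p.id for p in predictions]
    if len(set(pred_ids)) != len(pred_ids):
        dupes = sorted({i for i in pred_ids if pred_ids.count(i) > 1})
        raise ValueError(f"duplicate prediction ids: {dupes[:10]}")
    missing = [i for i in pred_ids if i not in labels]
    if missing:
        raise ValueError(f"predictions without labels: {missing[:10]}")
    extra = set(labels) - set(pred_ids)
    if extra:
        raise ValueError(f"labels without predictions: {sorted(extra)[:10]}")
    tp = fp = tn = fn = 0
    for p in predictions:
        truth = labels[p.id]
        if truth == LNCRNA:
            if p.predicted_label == LNCRNA:
                tp += 1
            else:
                fn += 1
        elif truth == MRNA:
            if p.predicted_label == MRNA:
                tn += 1
            else:
                fp += 1
        else:
            raise ValueError(f"unknown label {truth!r} for id {p.id!r}")
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def metrics(c: ConfusionCounts, auc: float | None = None) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), precision = TP/(TP+FP),
    F1 = 2*precision*sensitivity/(precision+sensitivity); all x100.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    acc = _pct(c.TP + c.TN, c.total)
    sens = _pct(c.TP, c.TP + c.FN)
    spec = _pct(c.TN, c.TN + c.FP)
    prec = _pct(c.TP, c.TP + c.FP)
    if prec is None or sens is None or prec + sens == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    as_float = lambda v: None if v is None else float(v)
    report = MetricsReport(
        accuracy=as_float(acc),
        sensitivity=as_float(sens),
        specificity=as_float(spec),
        precision=as_float(prec),
        f1=as_float(f1),
        auc=auc,
    )
    # keep the exact rationals for display rounding
    report._exact = {"accuracy": acc, "sensitivity": sens, "specificity": spec,
                     "precision": prec, "f1": f1}
    return report


def metrics_rounded(c: ConfusionCounts) -> dict[str, float | None]:
    """2-decimal half-up display values computed in exact rational arithmetic."""
    rep = metrics(c)
    return {
        name: (None if v is None else round_half_up(v, 2))
        for name, v in rep._exact.items()
    }


def roc_auc(
    scores: Sequence[float], labels: Sequence[int] | Sequence[str]
) -> tuple[pd.DataFrame, float]:
    """ROC curve points and AUC (score = p_lncRNA, positive = lncRNA).

    AUC equals the Mann-Whitney probability that a random positive outscores
    a random negative, with ties counted half.
    """
    y = np.asarray(
        [1 if l == LNCRNA else 0 if l == MRNA else l for l in labels], dtype=float
    )
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(y, s)
    auc = float(_sk_roc_auc(y, s))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return curve, auc


@dataclass
class LengthBinTable:
    """Per-length-bin accuracy; empty bins carry accuracy None."""

    table: pd.DataFrame  # columns: bin_lo, bin_hi, count, correct, accuracy_pct

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def default_length_bins(
    lo: int = 200, hi: int = 3000, width: int = 280
) -> list[int]:
    return list(range(lo, hi + 1, width))


def accuracy_by_length(
    predictions: Sequence[PredictionRecord],
    labels: Mapping[str, str],
    lengths: Mapping[str, int],
    bin_edges: Sequence[int] | None = None,
) -> LengthBinTable:
    """Accuracy per length bin; bins are [e_i, e_{i+1}) with the last edge
    inclusive. A length outside every bin is an error, not a silent drop."""
    edges = list(bin_edges) if bin_edges is not None else default_length_bins()
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    n_bins = len(edges) - 1
    count = np.zeros(n_bins, dtype=int)
    correct = np.zeros(n_bins, dtype=int)
    for p in predictions:
        L = lengths[p.id]
        if L == edges[-1]:
            b = n_bins - 1
        else:
            b = int(np.searchsorted(edges, L, side="right")) - 1
            if b < 0 or b >= n_bins:
                raise ValueError(
                    f"length {L} of {p.id!r} outside bins [{edges[0]}, {edges[-1]}]"
                )
        count[b] += 1
        correct[b] += int(p.predicted_label == labels[p.id])
    rows = []
    for b in range(n_bins):
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "count": int(count[b]),
                "correct": int(correct[b]),
                "accuracy_pct": (
                    round_half_up(Fraction(100 * correct[b], count[b]), 2)
                    if count[b]
                    else None
                ),
            }
        )
    return LengthBinTable(table=pd.DataFrame(rows))


def annotation_summary_pct(numerator: int, denominator: int) -> float:
    """100*numerator/denominator, half-up at 2 decimals (annotation tables)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    return round_half_up(Fraction(100 * numerator, denominator), 2)
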