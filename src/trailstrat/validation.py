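"""Leave-one-out cross-validation of the predictor and confusion metrics.

Each LOOCV fold refits the *entire* predictor — standardization, PCA and LDA
— on the remaining n-1 samples before projecting the held-out sample, so no
information from the held-out profile leaks into the fold's model.  The
synergistic class is the positive class throughout: sensitivity is the
fraction of synergistic responders correctly called, specificity the
fraction of low responders correctly called.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import ExpressionPanel, ResponseTable
from .errors import DegenerateError, DimensionError
from .predictor import ResponsePredictor
from .vocabulary import LOW, SYNERGISTIC

logger = logging.getLogger("trailstrat")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Two-class confusion counts with synergistic as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")


def confusion_metrics(truth, predicted) -> ConfusionMetrics:
    """Confusion counts/rates from paired label vectors."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise DimensionError("truth and predicted label vectors differ in length")
    tp = sum(t == SYNERGISTIC and p == SYNERGISTIC for t, p in zip(truth, predicted))
    fn = sum(t == SYNERGISTIC and p == LOW for t, p in zip(truth, predicted))
    tn = sum(t == LOW and p == LOW for t, p in zip(truth, predicted))
    fp = sum(t == LOW and p == SYNERGISTIC for t, p in zip(truth, predicted))
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class CVReport:
    """Per-sample LOOCV outcomes plus aggregate metrics.

    ``table`` has one row per sample: sample, truth, predicted, posterior,
    evaluable.  Samples whose training fold lost a class entirely are marked
    unevaluable and excluded from every denominator.
    """

    table: pd.DataFrame

    @property
    def evaluable(self) -> pd.DataFrame:
        return self.table[self.table["evaluable"]]

    @property
    def metrics(self) -> ConfusionMetrics:
        ev = self.evaluable
        return confusion_metrics(ev["truth"], ev["predicted"])

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy

    @property
    def sensitivity(self) -> float:
        return self.metrics.sensitivity

    @property
    def specificity(self) -> float:
        return self.metrics.specificity

    @property
    def n_correct(self) -> int:
        m = self.metrics
        return m.tp + m.tn

    def summary(self) -> str:
        m = self.metrics
        lines = ["Leave-one-out cross-validation", "=" * 40]
        lines.append(f"evaluable samples: {m.n}/{len(self.table)}")
        lines.append(f"correct predictions: {self.n_correct}/{m.n}"
                     f" ({100 * m.accuracy:.0f}%)")
        lines.append(f"sensitivity (synergistic recalled): {100 * m.sensitivity:.0f}%")
        lines.append(f"specificity (low recalled): {100 * m.specificity:.0f}%")
        lines.append(f"counts: TP={m.tp} FN={m.fn} TN={m.tn} FP={m.fp}")
        return "\n".join(lines)


def loocv(panel: ExpressionPanel, labels: ResponseTable,
          config: RunConfig | None = None) -> CVReport:
    """Leave-one-out cross-validation with per-fold refitting.

    For every sample, a fresh predictor (standardization + PCA + LDA) is
    trained on the other n-1 samples and used to classify the held-out
    profile.  Folds whose training labels collapse to a single class are
    skipped with a warning and reported as unevaluable.
    """
    config = config or RunConfig()
    if panel.n_samples < 3:
        raise DegenerateError("LOOCV needs at least 3 samples")
    labels = labels.aligned_to(panel)
    rows = []
    for sid in panel.sample_ids:
        sub_panel = panel.drop_sample(sid)
        sub_labels = labels.drop_sample(sid)
        counts = sub_labels.class_counts()
        if counts[SYNERGISTIC] == 0 or counts[LOW] == 0:
            warnings.warn(
                f"LOOCV fold for {sid!r}: training labels collapse to one class; "
                "sample unevaluable"
            )
            rows.append(dict(sample=sid, truth=labels.label_of(sid), predicted=None,
                             posterior=np.nan, evaluable=False))
            continue
        fold = ResponsePredictor(sub_panel, sub_labels, config).fit()
        pred = fold.predict(panel.sample_vector(sid), sample_id=sid)
        rows.append(dict(sample=sid, truth=labels.label_of(sid), predicted=pred.label,
                         posterior=pred.posterior, evaluable=True))
    report = CVReport(pd.DataFrame(rows))
    logger.info("LOOCV on %d samples: accuracy %.3f", panel.n_samples, report.accuracy)
    return report
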