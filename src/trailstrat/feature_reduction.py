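"""Correlation-merit feature ranking and iterative predictor reduction.

Each protein's *merit* is the absolute Pearson correlation between its
expression values and the binary response class (synergistic = 1, low = 0),
averaged over the training portions of seeded stratified cross-validation
folds.  Absolute correlation is used because anti-apoptotic and pro-apoptotic
proteins associate with responsiveness in opposite directions and both are
informative.  The predictor is then shrunk by repeatedly removing the
lowest-merit protein and re-running LOOCV on the sub-panel, producing an
accuracy-versus-panel-size curve from which the smallest subset that holds
the full-panel accuracy is selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import ExpressionPanel, ResponseTable
from .errors import DegenerateError, DomainError
from .predictor import train_predictor
from .validation import CVReport, loocv
from .vocabulary import canonical_sort_key

logger = logging.getLogger("trailstrat")


@dataclass(frozen=True)
class MeritRanking:
    """Per-protein merit scores and their rank order (1 = highest merit)."""

    protein_ids: tuple[str, ...]
    merits: np.ndarray
    seed: int
    n_folds: int

    def __post_init__(self) -> None:
        merits = np.asarray(self.merits, dtype=float)
        if merits.size != len(self.protein_ids):
            raise DomainError("merits and protein ids differ in length")
        object.__setattr__(self, "merits", merits)

    @property
    def order(self) -> tuple[str, ...]:
        """Proteins from highest to lowest merit, ties broken canonically."""
        idx = sorted(
            range(len(self.protein_ids)),
            key=lambda j: (-self.merits[j], canonical_sort_key(self.protein_ids[j])),
        )
        return tuple(self.protein_ids[j] for j in idx)

    @property
    def ranks(self) -> dict[str, int]:
        return {p: i + 1 for i, p in enumerate(self.order)}

    def to_dataframe(self) -> pd.DataFrame:
        ranks = self.ranks
        return pd.DataFrame(
            {
                "protein": self.order,
                "merit": [self.merits[self.protein_ids.index(p)] for p in self.order],
                "rank": [ranks[p] for p in self.order],
            }
        )


def _stratified_folds(indicator: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Assign samples to k folds, distributing each class round-robin after a
    seeded within-class shuffle.  Works for classes smaller than k (those
    folds simply lack that class; the training portions retain it)."""
    fold = np.empty(indicator.size, dtype=int)
    for cls in np.unique(indicator):
        members = np.flatnonzero(indicator == cls)
        members = rng.permutation(members)
        fold[members] = np.arange(members.size) % k
    return fold


def _abs_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson r| of each column of x with y; 0 for constant columns."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r[~np.isfinite(r)] = 0.0
    return np.abs(r)


def merit_rank(panel: ExpressionPanel, labels: ResponseTable,
               config: RunConfig | None = None, cross_validate: bool = True) -> MeritRanking:
    """Rank proteins by mean |Pearson r| with the class over stratified folds.

    With ``cross_validate=False`` the merit is the single full-data |r|
    (no-CV comparison mode).  Fold shuffling is seeded from
    ``config.rng_seed``; exact merit ties break by canonical protein order.
    """
    config = config or RunConfig()
    labels = labels.aligned_to(panel)
    y = labels.indicator()
    if config.cv_folds > panel.n_samples:
        raise DomainError("cv_folds may not exceed the number of samples")
    x = panel.values
    if not cross_validate:
        merits = _abs_pearson(x, y)
    else:
        rng = np.random.default_rng(config.rng_seed)
        fold = _stratified_folds(y, config.cv_folds, rng)
        per_fold = []
        for f in range(config.cv_folds):
            train = fold != f
            if train.sum() < 2 or len(np.unique(y[train])) < 2:
                continue  # degenerate training portion carries no signal
            per_fold.append(_abs_pearson(x[train], y[train]))
        merits = np.mean(per_fold, axis=0)
    if np.any(merits == 0):
        dead = [panel.protein_ids[j] for j in np.flatnonzero(merits == 0)]
        warnings.warn(f"protein(s) with zero merit (constant in training portions?): {dead}")
    logger.info("merit ranking of %d proteins (%d folds, seed %d)",
                panel.n_proteins, config.cv_folds, config.rng_seed)
    return MeritRanking(panel.protein_ids, merits, config.rng_seed, config.cv_folds)


@dataclass(frozen=True)
class ReductionStep:
    proteins: tuple[str, ...]
    loocv_accuracy: float
    training_accuracy: float


@dataclass(frozen=True)
class ReductionCurve:
    """Accuracy trajectory of the iterative panel reduction.

    ``steps[0]`` is the full panel; each subsequent step drops the
    lowest-ranked remaining protein.  ``selected`` is the smallest protein
    set whose LOOCV accuracy is within ``reduction_tolerance`` of the
    full-panel accuracy.
    """

    steps: tuple[ReductionStep, ...]
    selected: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_proteins": [len(s.proteins) for s in self.steps],
                "loocv_accuracy": [s.loocv_accuracy for s in self.steps],
                "training_accuracy": [s.training_accuracy for s in self.steps],
                "proteins": [";".join(s.proteins) for s in self.steps],
            }
        )


def reduce_predictor(panel: ExpressionPanel, labels: ResponseTable,
                     ranking: MeritRanking, config: RunConfig | None = None) -> ReductionCurve:
    """Iteratively drop the lowest-merit protein, re-running LOOCV each time.

    The retained-component cap follows the panel size down
    (``n_pcs_max = min(config.n_pcs_max, current protein count)``), and the
    selected subset is the smallest one whose LOOCV accuracy is at least the
    full-panel accuracy minus ``config.reduction_tolerance``.
    """
    config = config or RunConfig()
    if set(ranking.protein_ids) != set(panel.protein_ids):
        raise DomainError("ranking does not cover the panel's proteins")
    labels = labels.aligned_to(panel)
    # highest merit first; we drop from the tail
    remaining = list(ranking.order)
    steps: list[ReductionStep] = []
    while len(remaining) >= config.reduction_min_proteins:
        sub = panel.subset(remaining)
        sub_config = config.with_(n_pcs_max=min(config.n_pcs_max, len(remaining)))
        report = loocv(sub, labels, sub_config)
        training = train_predictor(sub, labels, sub_config).training_accuracy()
        steps.append(ReductionStep(tuple(remaining), report.accuracy, training))
        remaining.pop()  # lowest-ranked remaining protein
    full_accuracy = steps[0].loocv_accuracy
    selected = steps[0].proteins
    for step in steps:
        if step.loocv_accuracy >= full_accuracy - config.reduction_tolerance:
            selected = step.proteins
    logger.info("reduction: %d -> %d proteins selected", panel.n_proteins, len(selected))
    return ReductionCurve(tuple(steps), selected)
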