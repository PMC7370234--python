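"""The PCA/LDA response predictor.

The predictor is built from a training panel of protein quantities and the
matching two-class response labels, in three steps:

1. **Standardization** — each protein is mean-centred and divided by its
   sample standard deviation (n-1 denominator), putting immunoblot
   intensities and receptor counts on a common dimensionless scale.
2. **PCA** — an eigendecomposition of the proteins' correlation matrix
   (computed as an SVD of the standardized matrix, which is numerically
   equivalent and stable).  Components with eigenvalue > 1 (Kaiser
   criterion) are retained, capped at six.
3. **LDA** — a two-class linear discriminant with pooled within-class
   covariance segments the retained-PC space into a synergistic-response and
   a low-response region.

A new sample is classified by standardizing it with the *training*
parameters, projecting it onto the retained components, and reading off the
side of the discriminant hyperplane it lands on.

The module follows the model/results idiom: :class:`ResponsePredictor` holds
the data and configuration, ``fit()`` returns a :class:`PredictorResults`
carrying the fitted parameters, diagnostics, ``predict`` and ``summary``.
Thin functional wrappers (``standardize``, ``fit_pca``, ``fit_lda``,
``train_predictor``, ``predict``) expose each step independently.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import ExpressionPanel, ResponseTable
from .errors import CoverageError, DegenerateError, DimensionError
from .vocabulary import LOW, SYNERGISTIC, canonical_protein, canonical_sort_key

logger = logging.getLogger("trailstrat")

SERIALIZATION_VERSION = 1


# ------------------------------------------------------------- standardization

@dataclass(frozen=True)
class StandardizationParams:
    """Per-protein mean and standard deviation of the training panel."""

    protein_ids: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        if not (len(self.protein_ids) == self.means.size == self.sds.size):
            raise DimensionError("standardization parameter lengths disagree")
        if np.any(self.sds <= 0):
            raise DegenerateError("standard deviations must be > 0")


def standardize(panel: ExpressionPanel) -> tuple[np.ndarray, StandardizationParams]:
    """Mean-centre and scale each protein to unit sample standard deviation."""
    means = panel.values.mean(axis=0)
    sds = panel.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise DegenerateError(
            f"zero-variance protein(s): {[panel.protein_ids[j] for j in zero]}"
        )
    z = (panel.values - means) / sds
    return z, StandardizationParams(panel.protein_ids, means, sds)


def _as_series(sample, protein_ids: Sequence[str]) -> np.ndarray:
    """Coerce a sample profile to the protein order of ``protein_ids``."""
    if isinstance(sample, pd.Series):
        mapping = {canonical_protein(str(k)): float(v) for k, v in sample.items()}
    elif isinstance(sample, Mapping):
        mapping = {canonical_protein(str(k)): float(v) for k, v in sample.items()}
    else:
        arr = np.asarray(sample, dtype=float)
        if arr.shape != (len(protein_ids),):
            raise DimensionError(
                f"expected a profile of length {len(protein_ids)}, got shape {arr.shape}"
            )
        return arr
    missing = [p for p in protein_ids if p not in mapping]
    if missing:
        raise CoverageError(f"sample does not cover required proteins: {missing}")
    return np.array([mapping[p] for p in protein_ids], dtype=float)


def apply_standardization(sample, params: StandardizationParams) -> np.ndarray:
    """Standardize one sample profile with *training* parameters only."""
    x = _as_series(sample, params.protein_ids)
    return (x - params.means) / params.sds


# ------------------------------------------------------------------------ PCA

@dataclass(frozen=True)
class PCAModel:
    """Correlation-matrix PCA of a standardized panel.

    ``loadings`` has one column per computed component (min(n, p) columns);
    ``eigenvalues`` is padded with zeros to length p so the trace identity
    (eigenvalue sum = protein count) holds exactly in expectation.
    """

    protein_ids: tuple[str, ...]
    loadings: np.ndarray
    eigenvalues: np.ndarray
    n_retained: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "loadings", np.asarray(self.loadings, dtype=float))
        object.__setattr__(self, "eigenvalues", np.asarray(self.eigenvalues, dtype=float))

    @property
    def retained_loadings(self) -> np.ndarray:
        return self.loadings[:, : self.n_retained]

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / len(self.protein_ids)

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_fractions)


def fit_pca(z: np.ndarray, config: RunConfig | None = None,
            protein_ids: Sequence[str] | None = None) -> PCAModel:
    """Eigendecompose the correlation matrix of a standardized panel via SVD.

    Retention follows the Kaiser rule (eigenvalue > ``kaiser_threshold``)
    capped at ``n_pcs_max``; if no eigenvalue clears the threshold a single
    component is retained with a warning.  Each loading column is sign-fixed
    so its largest-magnitude entry is positive.
    """
    config = config or RunConfig()
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    if n < 2:
        raise DegenerateError("PCA needs at least 2 samples")
    if protein_ids is None:
        protein_ids = tuple(f"P{j+1}" for j in range(p))
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    eigenvalues = np.zeros(p)
    eigenvalues[: s.size] = s**2 / (n - 1)
    loadings = vt.T  # p x min(n, p), columns ordered by descending eigenvalue
    # deterministic sign convention: largest-|entry| of each column positive
    for j in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, j]))
        if loadings[pivot, j] < 0:
            loadings[:, j] = -loadings[:, j]
    n_retained = int(np.sum(eigenvalues > config.kaiser_threshold))
    if n_retained == 0:
        warnings.warn("no eigenvalue exceeds the Kaiser threshold; retaining 1 component")
        n_retained = 1
    n_retained = min(n_retained, config.n_pcs_max, loadings.shape[1])
    return PCAModel(tuple(protein_ids), loadings, eigenvalues, n_retained)


def variance_explained(model: PCAModel) -> pd.DataFrame:
    """Per-component and cumulative fractions of total variance."""
    k = model.eigenvalues.size
    return pd.DataFrame(
        {
            "component": np.arange(1, k + 1),
            "eigenvalue": model.eigenvalues,
            "fraction": model.variance_fractions,
            "cumulative": model.cumulative_variance,
        }
    )


def project(z: np.ndarray, model: PCAModel) -> np.ndarray:
    """Coordinates of standardized profile(s) on the retained components."""
    z = np.asarray(z, dtype=float)
    p = len(model.protein_ids)
    if z.shape[-1] != p:
        raise DimensionError(f"expected standardized vectors of length {p}, got {z.shape}")
    return z @ model.retained_loadings


# ------------------------------------------------------------------------ LDA

@dataclass(frozen=True)
class LDAModel:
    """Two-class linear discriminant in retained-PC space.

    Class order is (low, synergistic); the discriminant
    ``d(x) = weights . x + offset`` is positive on the synergistic side, and
    the posterior probability of the synergistic class is ``sigmoid(d)``.
    """

    class_means: np.ndarray        # 2 x r, rows (low, synergistic)
    pooled_cov: np.ndarray         # r x r
    priors: np.ndarray             # (low, synergistic), sums to 1
    weights: np.ndarray            # r
    offset: float
    ridge: float = 0.0

    def discriminant(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.weights + self.offset

    def posterior_synergistic(self, x) -> np.ndarray:
        d = self.discriminant(x)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-d))


def fit_lda(scores: np.ndarray, labels: ResponseTable, config: RunConfig | None = None) -> LDAModel:
    """Fit the two-class discriminant on PC scores with pooled covariance.

    A singular pooled covariance is ridge-regularized
    (``eps * I, eps = 1e-6 * trace / dim``) with a warning rather than
    failing: 15-sample training folds in a 6-PC space can be ill-conditioned.
    """
    config = config or RunConfig()
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y = labels.indicator()
    if scores.shape[0] != y.size:
        raise DimensionError("scores and labels differ in length")
    n, r = scores.shape
    counts = labels.class_counts()
    if counts[SYNERGISTIC] == 0 or counts[LOW] == 0:
        raise DegenerateError("LDA requires both response classes in the training labels")
    mask_syn = y == 1
    mu_low = scores[~mask_syn].mean(axis=0)
    mu_syn = scores[mask_syn].mean(axis=0)
    resid = scores.copy()
    resid[mask_syn] -= mu_syn
    resid[~mask_syn] -= mu_low
    dof = max(n - 2, 1)
    cov = resid.T @ resid / dof
    ridge = 0.0
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() <= 1e-10 * max(eigvals.max(), 1.0):
        ridge = 1e-6 * max(np.trace(cov) / r, np.finfo(float).tiny)
        cov = cov + ridge * np.eye(r)
        warnings.warn(f"singular pooled covariance; ridge {ridge:.3g} applied")
    if config.lda_priors == "empirical":
        priors = np.array([counts[LOW] / n, counts[SYNERGISTIC] / n])
    else:
        priors = np.array([0.5, 0.5])
    weights = np.linalg.solve(cov, mu_syn - mu_low)
    offset = float(-0.5 * (mu_syn + mu_low) @ weights + np.log(priors[1] / priors[0]))
    return LDAModel(
        class_means=np.vstack([mu_low, mu_syn]),
        pooled_cov=cov,
        priors=priors,
        weights=weights,
        offset=offset,
        ridge=ridge,
    )


# -------------------------------------------------------------- model/results

@dataclass(frozen=True)
class Prediction:
    """One sample's classification: label, posterior of the synergistic
    class, and its coordinates on the retained components."""

    sample_id: str
    label: str
    posterior: float
    scores: np.ndarray


class ResponsePredictor:
    """PCA/LDA response-classification model built from a training panel.

    Parameters
    ----------
    panel
        Training :class:`ExpressionPanel` (protein columns are reordered to
        the canonical vocabulary order, so fitting is invariant to input
        column order).
    labels
        :class:`ResponseTable` with one ``synergistic``/``low`` label per
        panel sample (any order; realigned to the panel).
    config
        :class:`RunConfig`; defaults applied when omitted.
    """

    def __init__(self, panel: ExpressionPanel, labels: ResponseTable,
                 config: RunConfig | None = None):
        config = config or RunConfig()
        ordered = sorted(panel.protein_ids, key=canonical_sort_key)
        self.panel = panel.subset(ordered)
        self.labels = labels.aligned_to(self.panel)
        counts = self.labels.class_counts()
        if counts[SYNERGISTIC] == 0 or counts[LOW] == 0:
            raise DegenerateError("training labels must contain both response classes")
        self.config = config

    @classmethod
    def from_files(cls, panel_path, labels_path, config: RunConfig | None = None,
                   orientation: str = "samples-in-rows") -> "ResponsePredictor":
        from .io import read_panel, read_responses

        return cls(read_panel(panel_path, orientation), read_responses(labels_path), config)

    def fit(self) -> "PredictorResults":
        z, params = standardize(self.panel)
        pca = fit_pca(z, self.config, self.panel.protein_ids)
        scores = project(z, pca)
        lda = fit_lda(scores, self.labels, self.config)
        logger.info(
            "trained predictor: %d samples x %d proteins, %d PCs retained, config %s",
            *self.panel.shape, pca.n_retained, self.config.config_hash,
        )
        return PredictorResults(
            proteins=self.panel.protein_ids,
            standardization=params,
            pca=pca,
            lda=lda,
            config=self.config,
            training_sample_ids=self.panel.sample_ids,
            training_scores=scores,
            training_labels=self.labels,
        )


@dataclass(frozen=True)
class PredictorResults:
    """A fitted PCA/LDA predictor: the deployable object.

    Carries the standardization parameters, PC loadings/eigenvalues, the
    discriminant, and (when fitted in-session) the training scores for
    diagnostics.  Serializes to a single versioned JSON document.
    """

    proteins: tuple[str, ...]
    standardization: StandardizationParams
    pca: PCAModel
    lda: LDAModel
    config: RunConfig
    training_sample_ids: tuple[str, ...] | None = None
    training_scores: np.ndarray | None = None
    training_labels: ResponseTable | None = None

    # ------------------------------------------------------------- inference
    @property
    def n_retained(self) -> int:
        return self.pca.n_retained

    def transform(self, sample) -> np.ndarray:
        """Standardize with training parameters and project onto retained PCs."""
        return project(apply_standardization(sample, self.standardization), self.pca)

    def _label_from_posterior(self, post: float) -> str:
        if post == 0.5:
            return self.config.tie_policy
        return SYNERGISTIC if post > 0.5 else LOW

    def predict(self, sample, sample_id: str = "sample") -> Prediction:
        """Classify one sample profile (Series, mapping or aligned vector)."""
        coords = self.transform(sample)
        post = float(self.lda.posterior_synergistic(coords))
        return Prediction(sample_id, self._label_from_posterior(post), post, coords)

    def predict_panel(self, panel: ExpressionPanel) -> list[Prediction]:
        sub = panel.subset(self.proteins)
        out = []
        for i, sid in enumerate(sub.sample_ids):
            out.append(self.predict(sub.values[i], sample_id=sid))
        return out

    # ----------------------------------------------------------- diagnostics
    def training_predictions(self) -> list[Prediction]:
        if self.training_scores is None:
            raise ValueError("model was deserialized without training data")
        posts = self.lda.posterior_synergistic(self.training_scores)
        return [
            Prediction(sid, self._label_from_posterior(float(p)), float(p), row)
            for sid, p, row in zip(self.training_sample_ids, posts, self.training_scores)
        ]

    def training_accuracy(self) -> float:
        """Training-set separation accuracy (fraction on the correct side)."""
        preds = self.training_predictions()
        truth = dict(zip(self.training_labels.sample_ids, self.training_labels.labels))
        correct = sum(p.label == truth[p.sample_id] for p in preds)
        return correct / len(preds)

    def variance_explained(self) -> pd.DataFrame:
        return variance_explained(self.pca)

    def summary(self) -> str:
        lines = ["PCA/LDA response predictor", "=" * 40]
        lines.append(f"proteins: {len(self.proteins)}")
        lines.append(f"retained components (Kaiser > {self.config.kaiser_threshold:g},"
                     f" cap {self.config.n_pcs_max}): {self.n_retained}")
        cum = self.pca.cumulative_variance[self.n_retained - 1]
        lines.append(f"variance captured by retained components: {100 * cum:.1f}%")
        ev = ", ".join(f"{e:.3f}" for e in self.pca.eigenvalues[: self.n_retained])
        lines.append(f"retained eigenvalues: {ev}")
        lines.append(f"LDA priors ({self.config.lda_priors}): "
                     f"low {self.lda.priors[0]:.3f}, synergistic {self.lda.priors[1]:.3f}")
        if self.training_scores is not None:
            n = len(self.training_sample_ids)
            acc = self.training_accuracy()
            lines.append(f"training samples: {n}")
            lines.append(f"training separation accuracy: {acc * n:.0f}/{n} ({100 * acc:.0f}%)")
        lines.append(f"config hash: {self.config.config_hash}")
        return "\n".join(lines)

    # ---------------------------------------------------------- serialization
    def to_json(self) -> str:
        from dataclasses import asdict

        doc = {
            "version": SERIALIZATION_VERSION,
            "proteins": list(self.proteins),
            "means": self.standardization.means.tolist(),
            "sds": self.standardization.sds.tolist(),
            "loadings": self.pca.loadings.tolist(),
            "eigenvalues": self.pca.eigenvalues.tolist(),
            "n_retained": self.pca.n_retained,
            "lda": {
                "means": self.lda.class_means.tolist(),
                "pooled_cov": self.lda.pooled_cov.tolist(),
                "priors": self.lda.priors.tolist(),
                "weights": self.lda.weights.tolist(),
                "offset": self.lda.offset,
                "ridge": self.lda.ridge,
            },
            "config": asdict(self.config),
            "config_hash": self.config.config_hash,
        }
        return json.dumps(doc, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "PredictorResults":
        doc = json.loads(text)
        if doc.get("version") != SERIALIZATION_VERSION:
            raise ValueError(f"unsupported predictor version {doc.get('version')!r}")
        proteins = tuple(doc["proteins"])
        config = RunConfig(**doc["config"])
        params = StandardizationParams(proteins, doc["means"], doc["sds"])
        pca = PCAModel(proteins, np.array(doc["loadings"]), np.array(doc["eigenvalues"]),
                       int(doc["n_retained"]))
        l = doc["lda"]
        lda = LDAModel(np.array(l["means"]), np.array(l["pooled_cov"]),
                       np.array(l["priors"]), np.array(l["weights"]),
                       float(l["offset"]), float(l.get("ridge", 0.0)))
        return cls(proteins, params, pca, lda, config)

    @classmethod
    def load(cls, path) -> "PredictorResults":
        return cls.from_json(Path(path).read_text())


# ------------------------------------------------------- functional interface

def train_predictor(panel: ExpressionPanel, labels: ResponseTable,
                    config: RunConfig | None = None) -> PredictorResults:
    """standardize -> fit_pca -> project -> fit_lda, as one call."""
    return ResponsePredictor(panel, labels, config).fit()


def predict(results: PredictorResults, sample, sample_id: str = "sample") -> Prediction:
    return results.predict(sample, sample_id)
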