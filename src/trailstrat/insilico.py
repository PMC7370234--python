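"""In silico cohort trial: mRNA-to-protein interpolation and prevalence.

Cohort transcriptomes arrive on the log2(FPKM-UQ+1) scale.  For each
predictor protein, a *standard curve* is drawn as the straight line through
two points: (cohort minimum back-transformed mRNA, panel minimum protein
quantity) and (cohort maximum mRNA, panel maximum protein quantity).  A
patient's protein profile is estimated by back-transforming each gene's
value (2^v - 1) and reading it off that line; profiles are then classified
with a trained predictor, and the predicted-synergistic fraction is the
estimated response prevalence.

This min-max interpolation assumes only that protein abundance increases
monotonically with transcript abundance over the observed range; it makes no
claim about the slope being biologically calibrated, which is why estimates
are clamped to the measured panel range before classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionPanel
from .errors import CoverageError, DegenerateError, DimensionError, DomainError, FormatError
from .predictor import PredictorResults
from .vocabulary import SYNERGISTIC, canonical_protein

logger = logging.getLogger("trailstrat")

#: Gene symbol -> panel protein name for the 11-protein reduced predictor.
#: The full 19-protein panel is not mapped by default (cFLIP and the TRAIL
#: receptors have isoform/paralog ambiguities a user must resolve).
DEFAULT_GENE_MAP: dict[str, str] = {
    "XIAP": "XIAP",
    "CASP3": "Procaspase 3",
    "CYCS": "Cytochrome C",
    "MCL1": "Mcl-1",
    "BIRC2": "cIAP1",
    "BAX": "Bax",
    "BID": "Bid",
    "BCL2L1": "Bcl-xL",
    "DIABLO": "Smac",
    "FADD": "FADD",
    "BAK1": "Bak",
}


@dataclass(frozen=True)
class CohortMatrix:
    """Patients x genes matrix on the log2(FPKM-UQ+1) scale (>= 0)."""

    patient_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "patient_ids", tuple(str(p) for p in self.patient_ids))
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.patient_ids), len(self.gene_ids)):
            raise DimensionError("cohort matrix shape does not match id lists")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise FormatError("duplicate patient ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise DomainError("cohort values must be finite and >= 0 (log2(FPKM-UQ+1))")
        values = values.copy()
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def gene_column(self, gene: str) -> np.ndarray:
        try:
            return self.values[:, self.gene_ids.index(gene)]
        except ValueError:
            raise CoverageError(f"gene {gene!r} not in cohort") from None


def back_transform(v):
    """Invert log2(FPKM-UQ+1): returns ``2**v - 1`` on the linear scale."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0) or not np.all(np.isfinite(v)):
        raise DomainError("log2(FPKM-UQ+1) values must be finite and >= 0")
    out = np.exp2(v) - 1.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class InterpolationMap:
    """Per-protein min-max standard curves from linear mRNA to protein scale.

    ``table`` rows: protein, gene, mrna_min, mrna_max (back-transformed
    linear scale), prot_min, prot_max (training panel), slope, intercept.
    Endpoints map exactly by construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "table", self.table.set_index("protein", drop=False))

    def row(self, protein: str) -> pd.Series:
        protein = canonical_protein(protein)
        if protein not in self.table.index:
            raise CoverageError(f"no interpolation curve for protein {protein!r}")
        return self.table.loc[protein]

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(self.table["protein"])


def fit_interpolation(panel: ExpressionPanel, cohort: CohortMatrix,
                      gene_map: dict[str, str] | None = None) -> InterpolationMap:
    """Point-to-point standard curves: cohort mRNA range -> panel protein range."""
    gene_map = gene_map if gene_map is not None else DEFAULT_GENE_MAP
    rows = []
    panel_df = panel.to_dataframe()
    for gene, protein in gene_map.items():
        protein = canonical_protein(protein)
        if protein not in panel.protein_ids:
            raise CoverageError(f"mapped protein {protein!r} not in panel")
        mrna = back_transform(cohort.gene_column(gene))
        mrna_min, mrna_max = float(mrna.min()), float(mrna.max())
        if mrna_max <= mrna_min:
            raise DegenerateError(f"gene {gene!r}: zero mRNA range in cohort")
        prot = panel_df[protein]
        prot_min, prot_max = float(prot.min()), float(prot.max())
        if prot_max <= prot_min:
            raise DegenerateError(f"protein {protein!r}: zero expression range in panel")
        slope = (prot_max - prot_min) / (mrna_max - mrna_min)
        rows.append(dict(protein=protein, gene=gene, mrna_min=mrna_min, mrna_max=mrna_max,
                         prot_min=prot_min, prot_max=prot_max, slope=slope,
                         intercept=prot_min - slope * mrna_min))
    return InterpolationMap(pd.DataFrame(rows))


def estimate_profiles(cohort: CohortMatrix, imap: InterpolationMap,
                      gene_map: dict[str, str] | None = None) -> ExpressionPanel:
    """Estimate patient protein profiles on the training panel's scale.

    Values falling outside the panel range (possible when the map was fitted
    on a different cohort) are clamped to [prot_min, prot_max]; the number of
    clamped cells is logged.
    """
    gene_map = gene_map if gene_map is not None else DEFAULT_GENE_MAP
    proteins = []
    columns = []
    clamped = 0
    for gene, protein in gene_map.items():
        protein = canonical_protein(protein)
        row = imap.row(protein)
        est = row["slope"] * back_transform(cohort.gene_column(gene)) + row["intercept"]
        lo, hi = row["prot_min"], row["prot_max"]
        clamped += int(np.sum((est < lo) | (est > hi)))
        proteins.append(protein)
        columns.append(np.clip(est, lo, hi))
    if clamped:
        logger.info("estimate_profiles: clamped %d cells to the panel range", clamped)
    return ExpressionPanel(cohort.patient_ids, tuple(proteins), np.column_stack(columns))


@dataclass(frozen=True)
class TrialResult:
    """Per-patient predictions and the estimated response prevalence."""

    table: pd.DataFrame  # patient, predicted, posterior

    @property
    def n_patients(self) -> int:
        return len(self.table)

    @property
    def n_responders(self) -> int:
        return int((self.table["predicted"] == SYNERGISTIC).sum())

    @property
    def prevalence(self) -> float:
        return self.n_responders / self.n_patients

    def summary(self) -> str:
        return (
            f"In silico trial: {self.n_responders}/{self.n_patients} patients "
            f"({100 * self.prevalence:.1f}%) predicted to respond synergistically"
        )


def run_trial(model: PredictorResults, cohort: CohortMatrix,
              imap: InterpolationMap, gene_map: dict[str, str] | None = None) -> TrialResult:
    """Estimate cohort protein profiles and classify every patient."""
    gene_map = gene_map if gene_map is not None else DEFAULT_GENE_MAP
    mapped = {canonical_protein(p) for p in gene_map.values()}
    missing = [p for p in model.proteins if p not in mapped]
    if missing:
        raise CoverageError(f"gene map does not cover predictor proteins: {missing}")
    profiles = estimate_profiles(cohort, imap, gene_map)
    predictions = model.predict_panel(profiles)
    table = pd.DataFrame(
        dict(patient=[p.sample_id for p in predictions],
             predicted=[p.label for p in predictions],
             posterior=[p.posterior for p in predictions])
    )
    result = TrialResult(table)
    logger.info("%s", result.summary())
    return result
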