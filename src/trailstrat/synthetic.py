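"""Synthetic data generators emulating the statistical structure of the
three experimental inputs, so every pipeline stage is testable end-to-end
without external data.

* :func:`gen_panel` — two-class expression panels from a low-rank Gaussian
  factor model in log space: informative proteins receive an opposite-sign
  class-mean shift (in within-class sd units), columns are exponentiated
  (log-normal marginals, as immunoblot quantities are positive and
  right-skewed) and multiplied by heterogeneous per-protein baselines so
  values span orders of magnitude, as real panels mixing blot intensities
  with receptor counts do.
* :func:`gen_grid` — factorial dose-response grids (3+3 monotherapies,
  9 combinations) whose combination conditions carry an injected
  super-independence boost plus replicate noise.
* :func:`gen_cohort` — cohort mRNA matrices produced by drawing protein
  profiles from class-conditional log-normal generators fitted to a panel,
  inverting the min-max interpolation map, and re-applying the
  log2(FPKM-UQ+1) transform with optional measurement noise.

All generators are pure functions of (spec, seed).  True class labels are
emitted alongside cohorts for recovery tests but never consumed by the
pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DoseResponseGrid, ExpressionPanel, ResponseTable
from .errors import DomainError
from .insilico import DEFAULT_GENE_MAP, CohortMatrix, InterpolationMap
from .synergy import webb_expected
from .vocabulary import CANONICAL_PANEL, LOW, SYNERGISTIC, canonical_protein

import pandas as pd


@dataclass(frozen=True)
class PanelSpec:
    """Study-condition parameters for synthetic panels.

    Defaults mirror the experimental design the pipeline targets: 16 samples
    (12 synergistic + 4 low responders) by the 19-protein apoptosis panel,
    with 11 informative proteins carrying a 2-sd class shift on a rank-4
    shared covariance structure and one decade of per-protein scale spread.
    """

    n_synergistic: int = 12
    n_low: int = 4
    n_proteins: int = 19
    n_informative: int = 11
    effect_size: float = 2.0
    latent_rank: int = 4
    latent_share: float = 0.5
    scale_heterogeneity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_synergistic, self.n_low, self.n_proteins, self.latent_rank) < 1:
            raise DomainError("all counts must be >= 1")
        if not (0 <= self.n_informative <= self.n_proteins):
            raise DomainError("n_informative must lie in [0, n_proteins]")
        if self.effect_size < 0:
            raise DomainError("effect_size must be >= 0")
        if not (0 <= self.latent_share < 1):
            raise DomainError("latent_share must lie in [0, 1)")
        if self.n_synergistic + self.n_low < 3:
            raise DomainError("need at least 3 samples in total")


def gen_panel(spec: PanelSpec) -> tuple[ExpressionPanel, ResponseTable]:
    """Draw a two-class panel; deterministic for a fixed spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_synergistic + spec.n_low
    p = spec.n_proteins
    labels = (SYNERGISTIC,) * spec.n_synergistic + (LOW,) * spec.n_low
    y = np.array([1.0 if l == SYNERGISTIC else 0.0 for l in labels])

    # shared low-rank structure + idiosyncratic noise, unit within-class sd
    factor_load = rng.normal(size=(p, spec.latent_rank))
    factor_load /= np.linalg.norm(factor_load, axis=1, keepdims=True)
    factors = rng.normal(size=(n, spec.latent_rank))
    noise = rng.normal(size=(n, p))
    x = np.sqrt(spec.latent_share) * factors @ factor_load.T + np.sqrt(1 - spec.latent_share) * noise

    # class-mean shift on informative proteins, alternating direction to mimic
    # pro- vs anti-apoptotic association
    shift = np.zeros(p)
    signs = np.where(np.arange(spec.n_informative) % 2 == 0, 1.0, -1.0)
    shift[: spec.n_informative] = spec.effect_size * signs
    x = x + np.outer(y - 0.5, shift)

    # positive values spanning orders of magnitude
    scales = 10.0 ** rng.normal(2.0, spec.scale_heterogeneity, size=p)
    values = scales * np.exp(x)

    if p == len(CANONICAL_PANEL):
        proteins = CANONICAL_PANEL
    else:
        proteins = tuple(f"P{j+1:02d}" for j in range(p))
    samples = tuple(f"S{i+1:02d}" for i in range(n))
    return ExpressionPanel(samples, proteins, values), ResponseTable(samples, labels)


def gen_grid(
    f_a_series=(0.05, 0.15, 0.30),
    f_b_series=(0.05, 0.10, 0.20),
    synergy_boost: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_id: str = "S",
    dose_a_series=(0.01, 0.1, 1.0),
    dose_b_series=(0.1, 0.33, 1.0),
) -> DoseResponseGrid:
    """Factorial grid: monotherapy series plus all combinations (15 conditions).

    Combination fractions are ``clip(webb_expected(f_a, f_b) + boost + noise)``;
    monotherapy fractions get independent noise of the same sd (replicate
    variability), which leaves the recovered synergy score unbiased.
    """
    f_a_series = np.asarray(f_a_series, dtype=float)
    f_b_series = np.asarray(f_b_series, dtype=float)
    for f, name in ((f_a_series, "f_a_series"), (f_b_series, "f_b_series")):
        if np.any(f < 0) or np.any(f > 1):
            raise DomainError(f"{name} values must lie in [0, 1]")
    if not -1 <= synergy_boost <= 1:
        raise DomainError("synergy_boost must lie in [-1, 1]")
    if len(dose_a_series) != f_a_series.size or len(dose_b_series) != f_b_series.size:
        raise DomainError("dose series and fraction series lengths must match")
    rng = np.random.default_rng(seed)
    dose_a, dose_b, f_dead = [], [], []
    for da, fa in zip(dose_a_series, f_a_series):
        dose_a.append(da); dose_b.append(0.0)
        f_dead.append(np.clip(fa + noise_sd * rng.normal(), 0, 1))
    for db, fb in zip(dose_b_series, f_b_series):
        dose_a.append(0.0); dose_b.append(db)
        f_dead.append(np.clip(fb + noise_sd * rng.normal(), 0, 1))
    for da, fa in zip(dose_a_series, f_a_series):
        for db, fb in zip(dose_b_series, f_b_series):
            f = webb_expected(fa, fb) + synergy_boost + noise_sd * rng.normal()
            dose_a.append(da); dose_b.append(db)
            f_dead.append(np.clip(f, 0, 1))
    return DoseResponseGrid(sample_id, np.array(dose_a), np.array(dose_b), np.array(f_dead))


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus the ground truth needed for recovery tests."""

    cohort: CohortMatrix
    true_labels: tuple[str, ...]   # per patient: synergistic/low/anchor
    imap: InterpolationMap         # the map that was inverted
    profiles: ExpressionPanel      # the protein profiles that were drawn


def gen_cohort(
    panel: ExpressionPanel,
    labels: ResponseTable,
    n_patients: int = 365,
    responder_fraction: float = 0.3,
    noise_sd: float = 0.0,
    seed: int = 0,
    gene_map: dict[str, str] | None = None,
    mrna_log_range: tuple[float, float] = (2.0, 8.0),
    anchors: bool = True,
) -> SyntheticCohort:
    """Generate cohort mRNA data consistent with a panel's protein structure.

    Protein profiles are drawn per patient from the class-conditional
    log-normal fit to the panel (clipped to the panel range so the min-max
    map is invertible), mapped to the linear mRNA scale by inverting the
    per-protein standard curve, and re-expressed as log2(FPKM-UQ+1) plus
    optional Gaussian measurement noise of sd ``noise_sd`` (log2 units).

    With ``anchors=True`` two extra patients carrying the exact panel
    minimum and maximum profiles are appended, so that re-fitting the
    interpolation from the generated cohort reproduces ``imap`` exactly.
    """
    gene_map = gene_map if gene_map is not None else DEFAULT_GENE_MAP
    if not 0 <= responder_fraction <= 1:
        raise DomainError("responder_fraction must lie in [0, 1]")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    lo, hi = mrna_log_range
    if not hi > lo >= 0:
        raise DomainError("mrna_log_range must satisfy 0 <= lo < hi")
    labels = labels.aligned_to(panel)
    rng = np.random.default_rng(seed)

    genes = list(gene_map.keys())
    proteins = [canonical_protein(gene_map[g]) for g in genes]
    df = panel.to_dataframe()[proteins]
    logv = np.log(df.to_numpy())
    y = labels.indicator().astype(bool)
    prot_min = df.min(axis=0).to_numpy()
    prot_max = df.max(axis=0).to_numpy()
    if np.any(prot_max <= prot_min):
        raise DomainError("panel has zero range for a mapped protein")

    stats = {}
    for cls, mask in ((SYNERGISTIC, y), (LOW, ~y)):
        sub = logv[mask]
        sd = sub.std(axis=0, ddof=1) if mask.sum() > 1 else np.zeros(len(proteins))
        stats[cls] = (sub.mean(axis=0), sd)

    n_resp = int(round(n_patients * responder_fraction))
    truth = [SYNERGISTIC] * n_resp + [LOW] * (n_patients - n_resp)
    profiles = np.empty((n_patients, len(proteins)))
    for i, cls in enumerate(truth):
        mean, sd = stats[cls]
        draw = np.exp(mean + sd * rng.normal(size=len(proteins)))
        profiles[i] = np.clip(draw, prot_min, prot_max)
    ids = [f"PT{i+1:04d}" for i in range(n_patients)]
    if anchors:
        profiles = np.vstack([profiles, prot_min, prot_max])
        ids += ["ANCHOR-MIN", "ANCHOR-MAX"]
        truth += ["anchor", "anchor"]

    # per-protein standard curve (linear mRNA scale), then invert it
    mrna_min = np.full(len(proteins), 2.0**lo - 1.0)
    mrna_max = np.full(len(proteins), 2.0**hi - 1.0)
    slope = (prot_max - prot_min) / (mrna_max - mrna_min)
    intercept = prot_min - slope * mrna_min
    mrna_lin = (profiles - intercept) / slope
    values = np.log2(mrna_lin + 1.0)
    if noise_sd > 0:
        values = values + noise_sd * rng.normal(size=values.shape)
    values = np.clip(values, 0.0, None)

    imap = InterpolationMap(pd.DataFrame(
        dict(protein=proteins, gene=genes, mrna_min=mrna_min, mrna_max=mrna_max,
             prot_min=prot_min, prot_max=prot_max, slope=slope, intercept=intercept)
    ))
    cohort = CohortMatrix(tuple(ids), tuple(genes), values)
    profile_panel = ExpressionPanel(tuple(ids), tuple(proteins), profiles)
    return SyntheticCohort(cohort, tuple(truth), imap, profile_panel)
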