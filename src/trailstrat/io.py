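"""Delimited-text readers and writers for panels, labels, grids and cohorts.

Tab-separated is the canonical output format; comma-separated input is
accepted on read (delimiter sniffed).  Missing values are rejected rather
than imputed — the pipeline has no imputation step, and a silent NaN would
corrupt standardization downstream.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import DoseResponseGrid, ExpressionPanel, ResponseTable
from .errors import FormatError, PanelValueError, VocabularyError
from .vocabulary import RESPONSE_LABELS

logger = logging.getLogger("trailstrat")

ORIENTATIONS = ("samples-in-rows", "proteins-in-rows")


def _sniff_sep(path: Path) -> str:
    sample = path.read_text().splitlines()
    head = "\n".join(sample[:10])
    try:
        return csv.Sniffer().sniff(head, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty matrix")
    return df


def _validate_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(coerced.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise PanelValueError(
            f"{path}: non-numeric or missing value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return coerced


def read_panel(path: str | Path, orientation: str = "samples-in-rows") -> ExpressionPanel:
    """Read an expression panel, normalising orientation to samples-in-rows."""
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    path = Path(path)
    df = _validate_numeric(_read_matrix(path), path)
    if orientation == "proteins-in-rows":
        df = df.T
    panel = ExpressionPanel.from_dataframe(df)
    logger.info("read panel %s: %d samples x %d proteins", path, *panel.shape)
    return panel


def write_panel(panel: ExpressionPanel, path: str | Path) -> None:
    panel.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def read_responses(path: str | Path) -> ResponseTable:
    """Read a two-column (sample id, label) table; header row optional."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (sample id, label)")
    first_label = str(raw.iloc[0, 1]).strip().lower()
    if first_label not in RESPONSE_LABELS:
        # treat the first row as a header; the labels themselves are validated
        # by ResponseTable, so a genuinely bad label still raises below
        raw = raw.iloc[1:]
        if raw.empty:
            raise FormatError(f"{path}: no data rows")
    try:
        return ResponseTable(tuple(raw.iloc[:, 0]), tuple(raw.iloc[:, 1]))
    except VocabularyError as exc:
        raise VocabularyError(f"{path}: {exc}") from None


def write_responses(table: ResponseTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tlabel\n")
        for s, l in zip(table.sample_ids, table.labels):
            fh.write(f"{s}\t{l}\n")


# ---------------------------------------------------------------- predictions

def write_predictions(predictions: Sequence, path: str | Path) -> None:
    """Write per-sample predictions: id, label, posterior, PC coordinates.

    ``predictions`` is a sequence of :class:`trailstrat.predictor.Prediction`.
    The file round-trips losslessly at the printed precision (17 significant
    digits, i.e. exact for float64).
    """
    predictions = list(predictions)
    if not predictions:
        raise FormatError("refusing to write an empty prediction table")
    k = len(predictions[0].scores)
    with open(path, "w") as fh:
        header = ["sample", "predicted_label", "posterior"] + [f"PC{i+1}" for i in range(k)]
        fh.write("\t".join(header) + "\n")
        for p in predictions:
            row = [p.sample_id, p.label, format(p.posterior, ".17g")]
            row += [format(x, ".17g") for x in p.scores]
            fh.write("\t".join(row) + "\n")


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "predicted_label" not in df.columns:
        raise FormatError(f"{path}: not a prediction table")
    return df


# --------------------------------------------------------------------- grids

def read_grids(path: str | Path) -> dict[str, DoseResponseGrid]:
    """Read dose-response grids (columns: sample, dose_a_nM, dose_b_uM, f_dead)."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    required = {"sample", "dose_a_nM", "dose_b_uM", "f_dead"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    grids: dict[str, DoseResponseGrid] = {}
    for sample, sub in df.groupby("sample", sort=False):
        grids[str(sample)] = DoseResponseGrid(
            sample_id=str(sample),
            dose_a=sub["dose_a_nM"].to_numpy(float),
            dose_b=sub["dose_b_uM"].to_numpy(float),
            f_dead=sub["f_dead"].to_numpy(float),
        )
    return grids


def write_grids(grids: Iterable[DoseResponseGrid], path: str | Path) -> None:
    pd.concat([g.to_dataframe() for g in grids], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


# -------------------------------------------------------------------- cohort

def read_cohort(path: str | Path, orientation: str = "samples-in-rows"):
    """Read a cohort mRNA matrix (patients x genes, log2(FPKM-UQ+1) scale)."""
    from .insilico import CohortMatrix

    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    path = Path(path)
    df = _validate_numeric(_read_matrix(path), path)
    if orientation == "proteins-in-rows":
        df = df.T
    return CohortMatrix(
        tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(float)
    )


def write_cohort(cohort, path: str | Path) -> None:
    pd.DataFrame(
        cohort.values, index=list(cohort.patient_ids), columns=list(cohort.gene_ids)
    ).to_csv(path, sep="\t", index_label="patient")
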