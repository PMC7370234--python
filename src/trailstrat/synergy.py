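"""Drug-combination synergy scoring by the fractional-product (Bliss
independence) method, and the derived two-class response labelling.

For two agents killing fractions ``f_a`` and ``f_b`` of cells on their own,
the independence expectation for the combination is

    f_exp = f_a + f_b - f_a * f_b

(the fractional product: surviving fractions multiply).  The synergy score of
a combination condition is the excess of the observed fraction affected over
this expectation, ``S = f_obs - f_exp``, bounded in [-1, 1].  A sample whose
mean score over all combination conditions exceeds a threshold is labelled a
synergistic responder, otherwise a low responder.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DoseResponseGrid, ResponseTable
from .errors import DegenerateError, DomainError
from .vocabulary import LOW, SYNERGISTIC

logger = logging.getLogger("trailstrat")

CONTROL_CORRECTIONS = ("none", "normalize-to-control")


def webb_expected(f_a, f_b):
    """Independence expectation ``f_a + f_b - f_a*f_b`` on the fraction-affected scale.

    Accepts scalars or arrays; inputs must lie in [0, 1].  The result is
    symmetric in its arguments, >= max(f_a, f_b) and <= 1.
    """
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    for f, name in ((f_a, "f_a"), (f_b, "f_b")):
        if not np.all(np.isfinite(f)) or np.any(f < 0) or np.any(f > 1):
            raise DomainError(f"{name} must lie in [0, 1]")
    out = f_a + f_b - f_a * f_b
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class SynergyResult:
    """Per-combination synergy records and their mean for one sample.

    ``records`` has one row per combination condition (dose_a > 0 and
    dose_b > 0) with columns dose_a, dose_b, f_a, f_b, f_obs, f_exp, score.
    """

    sample_id: str
    records: pd.DataFrame
    mean_score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", self.records.reset_index(drop=True))


def _normalize(f: np.ndarray, f_ctrl: float) -> np.ndarray:
    """Correct for spontaneous death: (f - f_ctrl) / (1 - f_ctrl), clipped."""
    if f_ctrl >= 1.0:
        raise DegenerateError("control condition killed all cells (f_ctrl = 1)")
    corrected = (f - f_ctrl) / (1.0 - f_ctrl)
    if np.any(corrected < 0) or np.any(corrected > 1):
        warnings.warn("control-normalized fractions clipped to [0, 1]", stacklevel=3)
    return np.clip(corrected, 0.0, 1.0)


def score_grid(grid: DoseResponseGrid, control_correction: str = "none") -> SynergyResult:
    """Score every combination condition of a grid against independence."""
    if control_correction not in CONTROL_CORRECTIONS:
        raise ValueError(f"control_correction must be one of {CONTROL_CORRECTIONS}")
    f = grid.f_dead
    if control_correction == "normalize-to-control":
        f_ctrl = grid.control()
        if f_ctrl is None:
            raise DegenerateError(
                f"grid {grid.sample_id!r}: normalize-to-control requires a (0, 0) condition"
            )
        f = _normalize(np.asarray(f), f_ctrl)
    mono_a = {a: fv for a, b, fv in zip(grid.dose_a, grid.dose_b, f) if a > 0 and b == 0}
    mono_b = {b: fv for a, b, fv in zip(grid.dose_a, grid.dose_b, f) if a == 0 and b > 0}
    rows = []
    for a, b, f_obs in zip(grid.dose_a, grid.dose_b, f):
        if a > 0 and b > 0:
            f_a, f_b = mono_a[a], mono_b[b]  # presence guaranteed by grid invariant
            f_exp = webb_expected(f_a, f_b)
            rows.append(
                dict(dose_a=a, dose_b=b, f_a=f_a, f_b=f_b, f_obs=f_obs,
                     f_exp=f_exp, score=f_obs - f_exp)
            )
    if not rows:
        raise DegenerateError(f"grid {grid.sample_id!r} has no combination conditions")
    records = pd.DataFrame(rows)
    return SynergyResult(grid.sample_id, records, float(records["score"].mean()))


def classify_response(result: SynergyResult, threshold: float = 0.1) -> str:
    """``synergistic`` when the mean synergy score exceeds ``threshold``, else ``low``."""
    return SYNERGISTIC if result.mean_score > threshold else LOW


def label_grids(
    grids: dict[str, DoseResponseGrid],
    threshold: float = 0.1,
    control_correction: str = "none",
) -> tuple[ResponseTable, pd.DataFrame]:
    """Score and classify a set of grids; returns labels plus a score table."""
    ids, labels, rows = [], [], []
    for sample_id, grid in grids.items():
        result = score_grid(grid, control_correction)
        label = classify_response(result, threshold)
        ids.append(sample_id)
        labels.append(label)
        rows.append(dict(sample=sample_id, mean_score=result.mean_score, label=label))
    logger.info("labelled %d grids at synergy threshold %.3g", len(ids), threshold)
    return ResponseTable(tuple(ids), tuple(labels)), pd.DataFrame(rows)
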