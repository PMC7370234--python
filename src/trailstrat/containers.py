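"""In-memory data containers shared by every pipeline stage.

The three core containers mirror the three experimental inputs:

* :class:`ExpressionPanel` — samples x proteins matrix of non-negative
  relative protein quantities (immunoblot fluorescence corrected for loading;
  surface receptors as molecules/cell).
* :class:`ResponseTable` — per-sample two-class responsiveness labels
  (``synergistic`` vs ``low``).
* :class:`DoseResponseGrid` — per-sample fractions of dead cells over a
  factorial design of two agents (monotherapy dose series + combinations).

Containers are immutable after construction and validate their invariants
eagerly so downstream numerics never see malformed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, DomainError, FormatError, PanelValueError, StructureError, VocabularyError
from .vocabulary import LOW, RESPONSE_LABELS, SYNERGISTIC, canonical_protein


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True, eq=False)
class ExpressionPanel:
    """Samples x proteins matrix of relative protein quantities (>= 0)."""

    sample_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    values: np.ndarray

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionPanel):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.protein_ids == other.protein_ids
            and np.array_equal(self.values, other.values)
        )

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(
            self, "protein_ids", tuple(canonical_protein(str(p)) for p in self.protein_ids)
        )
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise FormatError("expression values must form a 2-D matrix")
        if values.shape != (len(self.sample_ids), len(self.protein_ids)):
            raise DimensionError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.protein_ids)} proteins"
            )
        if len(self.sample_ids) < 2 or len(self.protein_ids) < 2:
            raise FormatError("an expression panel needs at least 2 samples and 2 proteins")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.protein_ids, "protein")
        bad = np.argwhere(~np.isfinite(values))
        if bad.size:
            r, c = bad[0]
            raise PanelValueError(
                f"non-finite value at sample {self.sample_ids[r]!r}, protein {self.protein_ids[c]!r}"
            )
        neg = np.argwhere(values < 0)
        if neg.size:
            r, c = neg[0]
            raise PanelValueError(
                f"negative quantity {values[r, c]!r} at sample {self.sample_ids[r]!r}, "
                f"protein {self.protein_ids[c]!r}"
            )
        values = values.copy()
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    # ------------------------------------------------------------------ views
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.protein_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionPanel":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(dtype=float))

    # -------------------------------------------------------------- selection
    def subset(self, proteins: Iterable[str]) -> "ExpressionPanel":
        """Panel restricted to ``proteins`` (canonicalised), in the given order."""
        wanted = [canonical_protein(p) for p in proteins]
        index = {p: j for j, p in enumerate(self.protein_ids)}
        missing = [p for p in wanted if p not in index]
        if missing:
            raise KeyError(f"proteins not in panel: {missing}")
        cols = [index[p] for p in wanted]
        return ExpressionPanel(self.sample_ids, tuple(wanted), self.values[:, cols])

    def drop_sample(self, sample_id: str) -> "ExpressionPanel":
        if sample_id not in self.sample_ids:
            raise KeyError(f"unknown sample {sample_id!r}")
        keep = [i for i, s in enumerate(self.sample_ids) if s != sample_id]
        return ExpressionPanel(
            tuple(self.sample_ids[i] for i in keep), self.protein_ids, self.values[keep]
        )

    def sample_vector(self, sample_id: str) -> pd.Series:
        """One sample's profile as a protein-indexed Series."""
        try:
            i = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None
        return pd.Series(self.values[i], index=list(self.protein_ids), name=sample_id)


@dataclass(frozen=True)
class ResponseTable:
    """Two-class responsiveness labels, one per sample."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        labels = tuple(str(l).strip().lower() for l in self.labels)
        if len(labels) != len(self.sample_ids):
            raise DimensionError("labels and sample ids differ in length")
        if len(labels) == 0:
            raise FormatError("empty response table")
        for lab in labels:
            if lab not in RESPONSE_LABELS:
                raise VocabularyError(
                    f"unknown response label {lab!r}; expected one of {RESPONSE_LABELS}"
                )
        _check_unique(self.sample_ids, "sample")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.sample_ids)

    def label_of(self, sample_id: str) -> str:
        try:
            return self.labels[self.sample_ids.index(sample_id)]
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def aligned_to(self, panel: ExpressionPanel) -> "ResponseTable":
        """Reorder to the panel's sample order; id sets must match exactly."""
        if set(self.sample_ids) != set(panel.sample_ids):
            raise FormatError("response table and panel sample ids do not match")
        return ResponseTable(panel.sample_ids, tuple(self.label_of(s) for s in panel.sample_ids))

    def indicator(self) -> np.ndarray:
        """Class indicator, synergistic = 1, low = 0."""
        return np.array([1.0 if l == SYNERGISTIC else 0.0 for l in self.labels])

    def drop_sample(self, sample_id: str) -> "ResponseTable":
        keep = [i for i, s in enumerate(self.sample_ids) if s != sample_id]
        if len(keep) == len(self.sample_ids):
            raise KeyError(f"unknown sample {sample_id!r}")
        return ResponseTable(
            tuple(self.sample_ids[i] for i in keep), tuple(self.labels[i] for i in keep)
        )

    def class_counts(self) -> dict[str, int]:
        return {
            SYNERGISTIC: sum(l == SYNERGISTIC for l in self.labels),
            LOW: sum(l == LOW for l in self.labels),
        }


@dataclass(frozen=True)
class DoseResponseGrid:
    """Fractions of dead cells for one sample over a two-agent factorial design.

    ``dose_a`` is the TRAIL-receptor agonist concentration (nM), ``dose_b``
    the IAP antagonist concentration (uM); ``f_dead`` the fraction of
    PI-positive cells at each condition.  For every combination condition
    (a > 0, b > 0) the matching monotherapy conditions (a, 0) and (0, b)
    must be present, otherwise the independence expectation is undefined.
    """

    sample_id: str
    dose_a: np.ndarray
    dose_b: np.ndarray
    f_dead: np.ndarray
    replicate_count: int = 1

    def __post_init__(self) -> None:
        da = np.asarray(self.dose_a, dtype=float)
        db = np.asarray(self.dose_b, dtype=float)
        f = np.asarray(self.f_dead, dtype=float)
        if not (da.shape == db.shape == f.shape) or da.ndim != 1:
            raise DimensionError("dose_a, dose_b and f_dead must be equal-length 1-D arrays")
        if da.size == 0:
            raise FormatError("empty dose-response grid")
        if not np.all(np.isfinite(da)) or np.any(da < 0) or not np.all(np.isfinite(db)) or np.any(db < 0):
            raise DomainError("doses must be finite and >= 0")
        if not np.all(np.isfinite(f)) or np.any(f < 0) or np.any(f > 1):
            raise DomainError("fractions of dead cells must lie in [0, 1]")
        if int(self.replicate_count) < 1:
            raise DomainError("replicate_count must be >= 1")
        for arr, name in ((da, "dose_a"), (db, "dose_b"), (f, "f_dead")):
            arr = arr.copy()
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "sample_id", str(self.sample_id))
        object.__setattr__(self, "replicate_count", int(self.replicate_count))
        # structural check: every combination has both monotherapy partners
        mono_a = {a for a, b in zip(da, db) if a > 0 and b == 0}
        mono_b = {b for a, b in zip(da, db) if a == 0 and b > 0}
        for a, b in zip(da, db):
            if a > 0 and b > 0:
                if a not in mono_a:
                    raise StructureError(
                        f"grid {self.sample_id!r}: combination (dose_a={a}, dose_b={b}) "
                        f"lacks monotherapy entry (dose_a={a}, 0)"
                    )
                if b not in mono_b:
                    raise StructureError(
                        f"grid {self.sample_id!r}: combination (dose_a={a}, dose_b={b}) "
                        f"lacks monotherapy entry (0, dose_b={b})"
                    )

    @property
    def n_conditions(self) -> int:
        return self.f_dead.size

    def monotherapy_a(self) -> dict[float, float]:
        return {a: f for a, b, f in zip(self.dose_a, self.dose_b, self.f_dead) if a > 0 and b == 0}

    def monotherapy_b(self) -> dict[float, float]:
        return {b: f for a, b, f in zip(self.dose_a, self.dose_b, self.f_dead) if a == 0 and b > 0}

    def control(self) -> float | None:
        """Fraction dead at the untreated (0, 0) condition, if measured."""
        for a, b, f in zip(self.dose_a, self.dose_b, self.f_dead):
            if a == 0 and b == 0:
                return float(f)
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "dose_a_nM": self.dose_a,
                "dose_b_uM": self.dose_b,
                "f_dead": self.f_dead,
            }
        )
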