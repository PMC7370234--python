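"""Run configuration shared across pipeline stages.

The handful of knobs that matter scientifically live here so that a single
YAML file pins an entire analysis: the Kaiser eigenvalue cutoff and component
cap for PCA retention, the LDA prior convention, the synergy-score class
threshold, fold count and seed for merit ranking, and the tie policy applied
on an exact posterior tie.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .errors import DomainError
from .vocabulary import LOW, SYNERGISTIC

_PRIOR_MODES = ("empirical", "equal")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration with documented defaults.

    kaiser_threshold
        Retain principal components whose correlation-matrix eigenvalue
        exceeds this value (Kaiser criterion). Default 1.0.
    n_pcs_max
        Hard cap on retained components; classification operates in the
        space of the first six PCs. Default 6.
    lda_priors
        ``empirical`` (class frequencies) or ``equal``.
    synergy_threshold
        Minimum mean synergy score (observed minus independence-expected
        fraction affected) for the synergistic class. Default 0.1.
    cv_folds
        Stratified fold count for merit ranking. Default 10.
    rng_seed
        Seed for every stochastic stage (fold shuffling). Default 20170101.
    tie_policy
        Label assigned on an exact posterior tie; conservative default
        ``low`` (do not call a responder on a knife edge).
    reduction_min_proteins
        Smallest panel size the iterative reduction descends to. Default 2.
    reduction_tolerance
        Allowed LOOCV accuracy loss (absolute) when picking the smallest
        protein subset from a reduction curve. Default 0.0.
    """

    kaiser_threshold: float = 1.0
    n_pcs_max: int = 6
    lda_priors: str = "empirical"
    synergy_threshold: float = 0.1
    cv_folds: int = 10
    rng_seed: int = 20170101
    tie_policy: str = LOW
    reduction_min_proteins: int = 2
    reduction_tolerance: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kaiser_threshold", "synergy_threshold", "reduction_tolerance"):
            v = float(getattr(self, name))
            if not (v == v and abs(v) != float("inf")):
                raise DomainError(f"{name} must be finite")
            object.__setattr__(self, name, v)
        if int(self.n_pcs_max) < 1:
            raise DomainError("n_pcs_max must be >= 1")
        if int(self.cv_folds) < 2:
            raise DomainError("cv_folds must be >= 2")
        if int(self.reduction_min_proteins) < 2:
            raise DomainError("reduction_min_proteins must be >= 2")
        if self.lda_priors not in _PRIOR_MODES:
            raise DomainError(f"lda_priors must be one of {_PRIOR_MODES}")
        if self.tie_policy not in (LOW, SYNERGISTIC):
            raise DomainError(f"tie_policy must be {LOW!r} or {SYNERGISTIC!r}")
        object.__setattr__(self, "n_pcs_max", int(self.n_pcs_max))
        object.__setattr__(self, "cv_folds", int(self.cv_folds))
        object.__setattr__(self, "rng_seed", int(self.rng_seed))
        object.__setattr__(self, "reduction_min_proteins", int(self.reduction_min_proteins))

    # ------------------------------------------------------------------ io
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    @property
    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
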