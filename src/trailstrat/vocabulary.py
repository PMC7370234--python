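"""Canonical protein vocabulary for the apoptosis-pathway panel.

The pipeline profiles 19 regulators of extrinsic (TRAIL-receptor driven)
apoptosis: the death receptors and DISC components, the Bcl-2 family that
gates mitochondrial outer-membrane permeabilisation, the apoptosome, the
executioner caspase zymogens and the IAPs that restrain them.  Protein names
arriving from delimited files are normalised against this vocabulary so that
columns line up across pipeline stages regardless of capitalisation or the
common alias spellings (e.g. "SMAC/DIABLO" for Smac).  Names that are not in
the vocabulary (synthetic panels, user extensions) pass through untouched.
"""

from __future__ import annotations

CANONICAL_PANEL: tuple[str, ...] = (
    "TRAIL-R1",
    "TRAIL-R2",
    "Procaspase 8",
    "FADD",
    "cFLIP",
    "Bid",
    "Bcl-2",
    "Bcl-xL",
    "Mcl-1",
    "Bax",
    "Bak",
    "Smac",
    "Cytochrome C",
    "Apaf-1",
    "Procaspase 9",
    "Procaspase 3",
    "XIAP",
    "cIAP1",
    "cIAP2",
)

# Positive class label for the two-class response vocabulary.
SYNERGISTIC = "synergistic"
LOW = "low"
RESPONSE_LABELS: tuple[str, str] = (SYNERGISTIC, LOW)

_EXTRA_ALIASES: dict[str, str] = {
    "smac/diablo": "Smac",
    "diablo": "Smac",
    "dr4": "TRAIL-R1",
    "dr5": "TRAIL-R2",
    "trailr1": "TRAIL-R1",
    "trailr2": "TRAIL-R2",
    "caspase 8": "Procaspase 8",
    "caspase 9": "Procaspase 9",
    "caspase 3": "Procaspase 3",
    "procaspase8": "Procaspase 8",
    "procaspase9": "Procaspase 9",
    "procaspase3": "Procaspase 3",
    "cytochrome c": "Cytochrome C",
    "cyt c": "Cytochrome C",
    "bcl2": "Bcl-2",
    "bclxl": "Bcl-xL",
    "bcl xl": "Bcl-xL",
    "mcl1": "Mcl-1",
    "apaf1": "Apaf-1",
    "flip": "cFLIP",
}


def _norm(name: str) -> str:
    """Fold case and collapse separators so aliases compare equal."""
    return " ".join(name.strip().lower().replace("-", " ").replace("_", " ").split())


_ALIAS_TABLE: dict[str, str] = {_norm(p): p for p in CANONICAL_PANEL}
for alias, target in _EXTRA_ALIASES.items():
    _ALIAS_TABLE.setdefault(_norm(alias), target)


def canonical_protein(name: str) -> str:
    """Map a protein name to its canonical panel spelling.

    Unknown names are returned stripped but otherwise unchanged, so panels
    with non-canonical (e.g. synthetic) features remain usable.
    """
    return _ALIAS_TABLE.get(_norm(name), name.strip())


def canonical_sort_key(name: str) -> tuple[int, str]:
    """Deterministic ordering: canonical panel order first, then lexicographic.

    Used to break exact ties (merit ranking, serialization) reproducibly.
    """
    canon = canonical_protein(name)
    try:
        return (CANONICAL_PANEL.index(canon), canon)
    except ValueError:
        return (len(CANONICAL_PANEL), canon)
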