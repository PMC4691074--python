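"""Consensus VQ-motif scanning and typing.

The family-defining motif is the 10-residue consensus FxxxVQxL/F/VTG.
Window positions (1-based): F at 1, V at 5, Q at 6 (H in some species),
T at 9 in all types reported for Chinese cabbage; the three residues at
positions 8-10 (e.g. LTG, FTG, LTV) subclassify proteins into motif types.

Patterns are PROSITE-like strings ('F-x-x-x-V-Q-x-x-T-x'), so the scanner
generalizes to other short-consensus families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_io import ProteinRecord

__all__ = [
    "MotifHit",
    "MotifCensus",
    "STRICT_PATTERN",
    "RELAXED_PATTERN",
    "prosite_to_regex",
    "scan_vq",
    "classify_census",
]

#: All six motif types reported for Chinese cabbage share T at position 9.
STRICT_PATTERN = "F-x-x-x-V-Q-x-x-T-x"
#: Cross-species scan: allows H at position 6 and any residue at position 9.
RELAXED_PATTERN = "F-x-x-x-V-[QH]-x-x-x-x"

_AA = "ACDEFGHIKLMNPQRSTVWY"


def prosite_to_regex(pattern: str) -> str:
    """Translate a PROSITE-like dash-separated pattern to a Python regex.

    Elements: a single residue letter, 'x' (any residue), '[ABC]'
    (alternatives), '{AB}' (exclusions), and 'x(n)' repeats.
    """
    parts = []
    for elem in pattern.split("-"):
        m = re.fullmatch(r"(.+)\((\d+)\)", elem)
        rep = ""
        if m:
            elem, rep = m.group(1), "{%s}" % m.group(2)
        if elem == "x":
            parts.append(f"[{_AA}]" + rep)
        elif elem.startswith("[") and elem.endswith("]"):
            parts.append(elem + rep)
        elif elem.startswith("{") and elem.endswith("}"):
            parts.append(f"[^{elem[1:-1]}]" + rep)
        elif len(elem) == 1 and elem.isalpha():
            parts.append(elem.upper() + rep)
        else:
            raise ValueError(f"cannot parse pattern element {elem!r}")
    return "".join(parts)


@dataclass(frozen=True)
class MotifHit:
    """One matched 10-mer: anchor position, window, and 3-letter type code."""

    protein_id: str
    start: int  # 1-based position of the F anchor
    window: str
    type_code: str  # residues at window positions 8-10
    variant_q6: str  # residue at window position 6 (normally Q)

    def __post_init__(self) -> None:
        if len(self.window) != 10:
            raise ValueError("motif window must be 10 residues")


@dataclass
class MotifCensus:
    """Per-type counts of proteins, typed by each protein's best hit."""

    counts: dict[str, int] = field(default_factory=dict)
    n_proteins_with_hit: int = 0
    n_proteins_scanned: int = 0

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_proteins_with_hit:
            raise ValueError("census counts do not sum to n_proteins_with_hit")
        if self.n_proteins_with_hit > self.n_proteins_scanned:
            raise ValueError("more hits than proteins scanned")


def _coerce(protein: ProteinRecord | tuple[str, str]) -> tuple[str, str]:
    if isinstance(protein, ProteinRecord):
        return protein.id, protein.sequence
    return protein[0], protein[1].upper()


def scan_vq(
    protein: ProteinRecord | tuple[str, str],
    relaxed: bool = False,
    pattern: str | None = None,
) -> list[MotifHit]:
    """Report every (possibly overlapping) consensus-motif window, left to right.

    Strict mode requires Q at position 6 and T at position 9; relaxed mode
    admits the VH variant and frees position 9. Sequences shorter than the
    window yield an empty list.
    """
    pid, seq = _coerce(protein)
    if not seq:
        raise ValueError(f"{pid}: empty sequence")
    pat = pattern if pattern is not None else (RELAXED_PATTERN if relaxed else STRICT_PATTERN)
    rx = re.compile("(?=(" + prosite_to_regex(pat) + "))")
    hits = []
    for m in rx.finditer(seq):
        window = m.group(1)
        hits.append(
            MotifHit(
                protein_id=pid,
                start=m.start() + 1,
                window=window,
                type_code=window[7:10],
                variant_q6=window[5],
            )
        )
    return hits


def classify_census(
    proteins: Sequence[ProteinRecord | tuple[str, str]],
    relaxed: bool = False,
    pattern: str | None = None,
) -> MotifCensus:
    """Type each protein by its leftmost strict hit and tally types.

    Exactly one type is assigned per protein (the leftmost hit; a protein may
    contain several windows but family censuses count proteins, not windows).
    Proteins with no hit contribute to n_proteins_scanned only.
    """
    if not proteins:
        raise ValueError("empty protein list")
    counts: dict[str, int] = {}
    n_hit = 0
    for p in proteins:
        hits = scan_vq(p, relaxed=relaxed, pattern=pattern)
        if hits:
            n_hit += 1
            code = hits[0].type_code
            counts[code] = counts.get(code, 0) + 1
    return MotifCensus(counts=counts, n_proteins_with_hit=n_hit, n_proteins_scanned=len(proteins))


def all_hits(
    proteins: Iterable[ProteinRecord | tuple[str, str]],
    relaxed: bool = False,
    pattern: str | None = None,
) -> list[MotifHit]:
    """Flat list of every hit in every protein (the 'all hits' view)."""
    out: list[MotifHit] = []
    for p in proteins:
        out.extend(scan_vq(p, relaxed=relaxed, pattern=pattern))
    return out
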