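"""Protein length, average molecular weight, and theoretical isoelectric point.

Mass and pKa constants live in versioned TSV assets under ``vqfam/data`` so
that exactness disputes are data edits, not code changes. The default pKa set
is the Bjellqvist table used by the ExPASy ProtParam pI calculator; an EMBOSS
set ships alongside for sensitivity checks.

Unknown residue X counts toward length, contributes zero mass, and is
excluded from ionizable groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

WATER_DA = 18.0153

__all__ = [
    "PkaTable",
    "load_masses",
    "load_pka",
    "protein_length_from_cds",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
]


@dataclass(frozen=True)
class PkaTable:
    """pKa values for ionizable side chains and the two chain termini.

    ``nterm``/``cterm`` hold residue-specific terminus overrides applied when
    the chain starts/ends with that residue (part of the Bjellqvist
    calibration; empty for pKa sets that lack them).
    """

    acids: dict[str, float]  # includes 'Cterm'
    bases: dict[str, float]  # includes 'Nterm'
    nterm: dict[str, float] | None = None
    cterm: dict[str, float] | None = None

    def __post_init__(self) -> None:
        required_acids = {"D", "E", "C", "Y", "Cterm"}
        required_bases = {"K", "R", "H", "Nterm"}
        if not required_acids <= set(self.acids) or not required_bases <= set(self.bases):
            raise ValueError("pKa table missing required groups")
        for v in list(self.acids.values()) + list(self.bases.values()):
            if not 0 < v < 14:
                raise ValueError(f"pKa {v} outside (0, 14)")


def _data_path(name: str):
    return resources.files("vqfam.data").joinpath(name)


@lru_cache(maxsize=None)
def load_masses() -> dict[str, float]:
    """Average residue masses (Da), ExPASy convention."""
    with resources.as_file(_data_path("average_masses.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return dict(zip(df["residue"], df["mass_da"]))


@lru_cache(maxsize=None)
def load_pka(name: str = "bjellqvist") -> PkaTable:
    with resources.as_file(_data_path(f"pka_{name}.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    def sel(kind):
        return dict(df.loc[df["kind"] == kind, ["group", "pka"]].itertuples(index=False))

    return PkaTable(acids=sel("acid"), bases=sel("base"), nterm=sel("nterm"), cterm=sel("cterm"))


def protein_length_from_cds(cds_length: int) -> int:
    """Protein length in residues from CDS length in bp (stop codon excluded)."""
    if cds_length <= 0 or cds_length % 3:
        raise ValueError(f"CDS length {cds_length} is not a positive multiple of 3")
    return cds_length // 3 - 1


def molecular_weight(sequence: str, masses: dict[str, float] | None = None) -> float:
    """Average molecular weight in daltons: sum of residue masses plus one water."""
    masses = masses if masses is not None else load_masses()
    seq = sequence.upper()
    total = WATER_DA
    for ch in seq:
        if ch not in masses:
            raise ValueError(f"illegal residue {ch!r} in sequence")
        total += masses[ch]
    return total


def net_charge(sequence: str, ph: float, pka: PkaTable | None = None) -> float:
    """Net charge at a given pH via Henderson-Hasselbalch.

    Positive groups contribute 1/(1+10^(pH-pKa)); negative groups contribute
    -1/(1+10^(pKa-pH)). Each ionizable side chain counts once per occurrence;
    both termini always count.
    """
    pka = pka if pka is not None else load_pka()
    seq = sequence.upper()
    q = 0.0
    counts: dict[str, int] = {}
    for ch in seq:
        counts[ch] = counts.get(ch, 0) + 1
    for group, val in pka.bases.items():
        if group == "Nterm":
            n, val = 1, (pka.nterm or {}).get(seq[0], val)
        else:
            n = counts.get(group, 0)
        q += n / (1.0 + 10.0 ** (ph - val))
    for group, val in pka.acids.items():
        if group == "Cterm":
            n, val = 1, (pka.cterm or {}).get(seq[-1], val)
        else:
            n = counts.get(group, 0)
        q -= n / (1.0 + 10.0 ** (val - ph))
    return q


def isoelectric_point(
    sequence: str,
    pka: PkaTable | None = None,
    tol_q: float = 1e-4,
    tol_ph: float = 0.001,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so bisection converges
    unconditionally; iteration stops at |Q| < tol_q or interval < tol_ph.
    """
    if not sequence:
        raise ValueError("empty sequence")
    pka = pka if pka is not None else load_pka()
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka)
        if abs(q) < tol_q or (hi - lo) < tol_ph:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
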