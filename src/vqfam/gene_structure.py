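"""Intron/exon structure from gene models.

When an exon list is available the intron count is exact (#exons - 1).
With catalogue-style data only (span + CDS length), "span == CDS length" is
used as the intronless criterion: exact for genes whose catalogued span
covers the CDS without UTRs, and it makes the family-level intronless census
reproducible without the genome. A span exceeding the CDS implies at least
one intron but not how many; such genes report an unknown count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_io import GeneModel

__all__ = ["IntronStatus", "intron_count", "intronless_census"]


@dataclass(frozen=True)
class IntronStatus:
    """Intron count for one gene; count is None when only '>= 1' is known."""

    gene_name: str
    count: int | None
    inferred: bool  # True when derived from span/CDS rather than an exon list

    @property
    def intronless(self) -> bool:
        return self.count == 0


def intron_count(g: GeneModel) -> IntronStatus:
    """Exact intron count from exons, or span-based inference without them."""
    if g.exons is not None:
        return IntronStatus(g.gene_name, len(g.exons) - 1, inferred=False)
    if g.span == g.cds_length:
        return IntronStatus(g.gene_name, 0, inferred=True)
    return IntronStatus(g.gene_name, None, inferred=True)


def intronless_census(genes: Sequence[GeneModel]) -> tuple[int, int]:
    """(number of intronless genes, total genes)."""
    if not genes:
        raise ValueError("empty gene list")
    n0 = sum(1 for g in genes if intron_count(g).intronless)
    return n0, len(genes)
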