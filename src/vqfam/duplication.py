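"""Ortholog naming, chromosome census, duplication typing, subgenome tallies.

Synteny (the locus groups) is taken as input, not recomputed: block detection
against the ancestral karyotype comes from an external synteny service.
Within each multi-member locus group, a pair is called tandem when both genes
sit on the same chromosome within a small intergenic gap (default 25 kb);
every other grouped gene with at least one counterpart is segmental. Members
of a tandem pair are excluded from the segmental gene count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .core_io import GeneModel, LocusGroup, ProteinRecord
from .phylo import global_align

__all__ = [
    "OrthologAssignment",
    "DuplicationCall",
    "assign_names",
    "chromosome_census",
    "classify_duplications",
    "subgenome_tabulate",
]

TANDEM_MAX_GAP = 25_000  # bp


@dataclass(frozen=True)
class OrthologAssignment:
    br_gene: str
    ref_gene: str
    similarity_pct: float
    assigned_name: str


@dataclass(frozen=True)
class DuplicationCall:
    gene_a: str
    gene_b: str
    mode: str  # "tandem" | "segmental"
    chrom_a: str
    chrom_b: str
    gap_bp: int | None  # None when on different chromosomes
    group: str


def assign_names(
    br_proteins: Sequence[ProteinRecord | tuple[str, str]],
    ref_proteins: Sequence[ProteinRecord | tuple[str, str]],
    new_prefix: str = "Br",
    ref_prefix: str = "At",
) -> list[OrthologAssignment]:
    """Name each query protein after its best-aligning reference protein.

    Queries sharing a reference get "-1..n" suffixes ordered by descending
    similarity (ties by query id); a sole hit keeps the bare family name.
    """

    def coerce(p):
        return (p.id, p.sequence) if isinstance(p, ProteinRecord) else (p[0], p[1])

    br = [coerce(p) for p in br_proteins]
    ref = [coerce(p) for p in ref_proteins]
    if not br or not ref:
        raise ValueError("empty proteome")

    best: dict[str, tuple[str, float, float]] = {}  # br id -> (ref id, score, similarity)
    for bid, bseq in br:
        top = None
        for rid, rseq in ref:
            _, _, sim = global_align(bseq, rseq)
            # score by similarity; deterministic tie-break on ref id
            if top is None or sim > top[2] or (sim == top[2] and rid < top[0]):
                top = (rid, sim, sim)
        best[bid] = top

    by_ref: dict[str, list[tuple[str, float]]] = {}
    for bid, (rid, _, sim) in best.items():
        by_ref.setdefault(rid, []).append((bid, sim))

    out = []
    for rid, members in by_ref.items():
        base = re.sub(rf"^{re.escape(ref_prefix)}", new_prefix, rid.split()[0])
        members.sort(key=lambda t: (-t[1], t[0]))
        for i, (bid, sim) in enumerate(members, start=1):
            name = base if len(members) == 1 else f"{base}-{i}"
            out.append(
                OrthologAssignment(br_gene=bid, ref_gene=rid, similarity_pct=sim, assigned_name=name)
            )
    out.sort(key=lambda a: a.br_gene)
    return out


def chromosome_census(genes: Sequence[GeneModel]) -> dict[str, int]:
    """Gene counts per chromosome (scaffolds appear under their own names)."""
    if not genes:
        raise ValueError("empty gene list")
    counts: dict[str, int] = {}
    for g in genes:
        counts[g.chrom] = counts.get(g.chrom, 0) + 1
    return dict(sorted(counts.items()))


def _gap_bp(a: GeneModel, b: GeneModel) -> int:
    """Intergenic distance between two genes on one chromosome (0 if overlapping)."""
    if a.start > b.start:
        a, b = b, a
    return max(0, b.start - a.end - 1)


def classify_duplications(
    locus_groups: Sequence[LocusGroup],
    genes: Sequence[GeneModel],
    tandem_max_gap: int = TANDEM_MAX_GAP,
) -> tuple[list[DuplicationCall], dict[str, str]]:
    """Type duplicate pairs within locus groups as tandem or segmental.

    Returns (pair calls, per-gene labels). A gene participating in any
    tandem pair is labelled "tandem"; other genes with >= 1 counterpart are
    "segmental". Genes in single-member groups get no label.
    """
    by_name = {g.gene_name: g for g in genes}
    calls: list[DuplicationCall] = []
    tandem_genes: set[str] = set()
    grouped_genes: set[str] = set()
    for grp in locus_groups:
        members = grp.gene_names
        if len(members) < 2:
            continue
        missing = [m for m in members if m not in by_name]
        if missing:
            raise ValueError(f"locus group {grp.ref_locus or grp.block!r}: no coordinates for {missing}")
        grouped_genes.update(members)
        for na, nb in combinations(sorted(members), 2):
            ga, gb = by_name[na], by_name[nb]
            same_chrom = ga.chrom == gb.chrom
            gap = _gap_bp(ga, gb) if same_chrom else None
            mode = "tandem" if same_chrom and gap <= tandem_max_gap else "segmental"
            if mode == "tandem":
                tandem_genes.update((na, nb))
            calls.append(
                DuplicationCall(
                    gene_a=na,
                    gene_b=nb,
                    mode=mode,
                    chrom_a=ga.chrom,
                    chrom_b=gb.chrom,
                    gap_bp=gap,
                    group=grp.ref_locus or grp.block,
                )
            )
    labels = {
        name: ("tandem" if name in tandem_genes else "segmental") for name in grouped_genes
    }
    return calls, labels


def subgenome_tabulate(
    locus_groups: Sequence[LocusGroup],
) -> tuple[dict[str, int], dict[int, int]]:
    """(genes per subgenome, copy-number histogram over anchored loci).

    The histogram counts members per reference locus; groups without a
    reference anchor are excluded from the histogram but their members still
    count toward the subgenome totals.
    """
    if not locus_groups:
        raise ValueError("no locus groups")
    sub_counts: dict[str, int] = {}
    histogram: dict[int, int] = {}
    for grp in locus_groups:
        for _, sub in grp.members:
            sub_counts[sub] = sub_counts.get(sub, 0) + 1
        if grp.ref_locus:
            n = len(grp.members)
            histogram[n] = histogram.get(n, 0) + 1
    return dict(sorted(sub_counts.items())), dict(sorted(histogram.items()))
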