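"""Domain types and readers/writers for the formats the pipeline touches.

Coordinates are 1-based inclusive throughout (GFF3 native convention; the
gene-catalogue span convention satisfies end - start + 1 = CDS length for
intronless genes). Strand affects reporting only: protein-level computations
take amino-acid sequences as given.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import skbio
from skbio.tree import TreeNode

__all__ = [
    "GeneModel",
    "ProteinRecord",
    "LocusGroup",
    "CtTable",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_gff3",
    "read_synteny_table",
    "write_synteny_table",
    "read_ct_table",
    "read_newick",
    "write_newick",
]

SUBGENOMES = ("LF", "MF1", "MF2", "unassigned")

# IUPAC amino acids plus ambiguity/gap characters tolerated on input.
_SEQ_CHARS = set("ACDEFGHIKLMNPQRSTVWYXN*-BZJUO")


@dataclass
class GeneModel:
    """One gene: coordinates, strand, CDS length and optional exon layout."""

    gene_name: str
    locus_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_length: int
    exons: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.strand in ("−", "–"):  # unicode minus / en-dash
            self.strand = "-"
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_name}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_name}: start {self.start} > end {self.end}")
        if self.cds_length <= 0:
            raise ValueError(f"{self.gene_name}: CDS length must be positive")
        if self.cds_length % 3:
            warnings.warn(
                f"{self.gene_name}: CDS length {self.cds_length} is not a multiple of 3",
                stacklevel=2,
            )
        if self.exons is not None:
            self._check_exons()

    def _check_exons(self) -> None:
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_name}: overlapping exons {s1}-{e1}, {s2}-{e2}")
        if exons[0][0] < self.start or exons[-1][1] > self.end:
            raise ValueError(f"{self.gene_name}: exons outside gene span")
        total = sum(e - s + 1 for s, e in exons)
        if total != self.cds_length:
            raise ValueError(
                f"{self.gene_name}: exon lengths sum to {total}, CDS length is {self.cds_length}"
            )
        self.exons = exons

    @property
    def span(self) -> int:
        """Genomic footprint in bp, 1-based inclusive."""
        return self.end - self.start + 1


@dataclass
class ProteinRecord:
    """A protein sequence with its derived physico-chemical properties."""

    id: str
    sequence: str
    mw_da: float | None = None
    pi: float | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass
class LocusGroup:
    """Genes sharing one ancestral locus, labelled by retained subgenome."""

    block: str
    tpck_chrom: str
    ref_locus: str  # empty string when no reference-species anchor exists
    members: list[tuple[str, str]] = field(default_factory=list)  # (gene, subgenome)

    def __post_init__(self) -> None:
        names = [g for g, _ in self.members]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate member gene in locus group {self.ref_locus or self.block!r}")
        for g, sub in self.members:
            if sub not in SUBGENOMES:
                raise ValueError(f"{g}: unknown subgenome label {sub!r}")

    @property
    def gene_names(self) -> list[str]:
        return [g for g, _ in self.members]


@dataclass
class CtTable:
    """qPCR raw Ct values: one row per (gene, condition, timepoint, replicate)."""

    data: pd.DataFrame

    COLUMNS = ("gene", "condition", "timepoint", "replicate", "ct_target", "ct_reference")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        ct = self.data[["ct_target", "ct_reference"]].to_numpy(dtype=float)
        import numpy as np

        if not np.all(np.isfinite(ct)) or (ct <= 0).any():
            raise ValueError("Ct values must be finite and > 0")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs.

    Sequences are uppercased, whitespace is stripped, order is preserved, and
    the id is the first whitespace-delimited token after '>'. Duplicate ids
    and characters outside the amino-acid/nucleotide alphabet are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    current: list[str] | None = None
    cur_id = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    records.append((cur_id, "".join(current)))
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                if not cur_id:
                    raise ValueError(f"line {lineno}: empty record id")
                if cur_id in seen:
                    raise ValueError(f"duplicate record id {cur_id!r}")
                seen.add(cur_id)
                current = []
            else:
                if current is None:
                    raise ValueError(f"line {lineno}: sequence data before first '>' header")
                chunk = line.upper().replace(" ", "")
                bad = set(chunk) - _SEQ_CHARS
                if bad:
                    raise ValueError(
                        f"line {lineno}: illegal sequence character(s) {sorted(bad)}"
                    )
                current.append(chunk)
    if current is not None:
        records.append((cur_id, "".join(current)))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene tables

_RANGE_SEPS = re.compile(r"[–—−-]")  # en/em dash, minus, hyphen


def _parse_location(text: str) -> tuple[int, int]:
    cleaned = str(text).replace(",", "").replace(" ", "")
    parts = [p for p in _RANGE_SEPS.split(cleaned) if p]
    if len(parts) != 2:
        raise ValueError(f"cannot parse location {text!r}")
    return int(parts[0]), int(parts[1])


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a TSV gene catalogue into GeneModel records.

    Accepts either a 'location' column formatted "start–end" (hyphen or
    en-dash, optional thousands separators) or explicit 'start'/'end'
    columns. CDS lengths that are not positive multiples of 3 produce a
    warning; the row is kept.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    genes = []
    for _, row in df.iterrows():
        if "location" in df.columns and pd.notna(row.get("location")):
            start, end = _parse_location(row["location"])
        else:
            start, end = int(str(row["start"]).replace(",", "")), int(
                str(row["end"]).replace(",", "")
            )
        genes.append(
            GeneModel(
                gene_name=row["gene_name"].strip(),
                locus_id=str(row.get("locus_id", "")).strip(),
                chrom=str(row["chrom"]).strip(),
                strand=str(row["strand"]).strip(),
                start=start,
                end=end,
                cds_length=int(row["cds_length"]),
            )
        )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_name": [g.gene_name for g in genes],
            "locus_id": [g.locus_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "cds_length": [g.cds_length for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3: one GeneModel per mRNA, exons from CDS rows.

    CDS intervals are sorted by start; cds_length is their summed length.
    A CDS feature without a Parent attribute, or overlapping CDS intervals
    under one mRNA, are errors.
    """
    mrnas: dict[str, dict] = {}
    cds_by_parent: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {lineno}: expected 9 GFF3 columns")
            seqid, _, ftype, start, end, _, strand, _, attrs = fields
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "mRNA":
                mid = attr.get("ID")
                if mid is None:
                    raise ValueError(f"line {lineno}: mRNA without ID")
                mrnas[mid] = {
                    "chrom": seqid,
                    "strand": strand,
                    "start": int(start),
                    "end": int(end),
                    "name": attr.get("Name", mid),
                    "locus": attr.get("Parent", ""),
                }
            elif ftype == "CDS":
                parent = attr.get("Parent")
                if parent is None:
                    raise ValueError(f"line {lineno}: CDS without Parent attribute")
                cds_by_parent.setdefault(parent, []).append((int(start), int(end)))
    genes = []
    for mid, info in mrnas.items():
        exons = sorted(cds_by_parent.get(mid, []))
        if not exons:
            continue
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{mid}: overlapping CDS intervals {s1}-{e1}, {s2}-{e2}")
        genes.append(
            GeneModel(
                gene_name=info["name"],
                locus_id=info["locus"] or mid,
                chrom=info["chrom"],
                strand=info["strand"],
                start=info["start"],
                end=info["end"],
                cds_length=sum(e - s + 1 for s, e in exons),
                exons=exons,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Synteny / locus-group tables


def read_synteny_table(path: str | Path) -> list[LocusGroup]:
    """Read a per-member synteny TSV into LocusGroup records.

    Rows sharing a non-empty ref_locus form one group; each row with an empty
    ref_locus is its own (unanchored) group.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    groups: dict[str, LocusGroup] = {}
    out: list[LocusGroup] = []
    for _, row in df.iterrows():
        ref = row["ref_locus"].strip()
        member = (row["gene_name"].strip(), row["subgenome"].strip() or "unassigned")
        if ref:
            if ref not in groups:
                groups[ref] = LocusGroup(
                    block=row["block"].strip(),
                    tpck_chrom=row["tpck_chrom"].strip(),
                    ref_locus=ref,
                )
                out.append(groups[ref])
            groups[ref].members.append(member)
        else:
            out.append(
                LocusGroup(
                    block=row["block"].strip(),
                    tpck_chrom=row["tpck_chrom"].strip(),
                    ref_locus="",
                    members=[member],
                )
            )
    for g in out:
        g.__post_init__()  # re-validate uniqueness after incremental fill
    return out


def write_synteny_table(groups: Sequence[LocusGroup], path: str | Path) -> None:
    rows = []
    for g in groups:
        for gene, sub in g.members:
            rows.append((g.block, g.tpck_chrom, g.ref_locus, gene, sub))
    pd.DataFrame(
        rows, columns=["block", "tpck_chrom", "ref_locus", "gene_name", "subgenome"]
    ).to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> CtTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    return CtTable(df)


# ---------------------------------------------------------------------------
# Newick


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string (branch lengths, integer support labels)."""
    try:
        return TreeNode.read(io.StringIO(text), format="newick", convert_underscores=False)
    except (skbio.io.FormatIdentificationWarning, Exception) as exc:  # noqa: BLE001
        raise ValueError(f"Newick parse error: {exc}") from exc


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
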