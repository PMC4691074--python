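"""Synthetic gene families with planted ground truth, plus packaged catalogues.

The generator emulates the statistical structure of a triplicated-genome
gene family: ancestral loci retain 1-3 copies across three subgenomes
(LF/MF1/MF2), each protein carries exactly one planted consensus motif of a
drawn type, copies diverge by point substitution with the motif window
protected, a small fraction of multi-copy loci place two copies in tandem
(within 5 kb) while all other copies land far apart or on other
chromosomes, and qPCR Ct tables are simulated under planted log2
fold-changes with Gaussian replicate noise. Every planted quantity is
recorded in a truth dictionary; runs are fully reproducible by seed.

Also ships the transcribed published gene catalogue (57 genes) and synteny
table as packaged TSV fixtures.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .core_io import (
    CtTable,
    GeneModel,
    LocusGroup,
    ProteinRecord,
    read_gene_table,
    read_synteny_table,
    write_fasta,
    write_gene_table,
    write_synteny_table,
)
from .motif_scan import scan_vq

__all__ = [
    "SimulationConfig",
    "SimulatedFamily",
    "simulate_family",
    "table1_fixture",
    "table2_fixture",
    "load_catalogue_genes",
    "load_catalogue_table",
    "load_synteny_groups",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"

# Default study-like conditions: 28 ancestral loci with retained-copy
# distribution 10/11/7 (1/2/3 copies) and the observed motif-type mix.
_COPY_DIST = {1: 10 / 28, 2: 11 / 28, 3: 7 / 28}
_TYPE_DIST = {
    "LTG": 43 / 57,
    "FTG": 8 / 57,
    "VTG": 3 / 57,
    "LTS": 1 / 57,
    "LTV": 1 / 57,
    "YTG": 1 / 57,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_ref_loci: int = 28
    copy_distribution: dict[int, float] = field(default_factory=lambda: dict(_COPY_DIST))
    motif_type_distribution: dict[str, float] = field(default_factory=lambda: dict(_TYPE_DIST))
    #: fraction of multi-copy loci whose first two copies sit in tandem
    tandem_fraction: float = 1 / 18
    n_chromosomes: int = 10
    chromosome_length: int = 30_000_000
    protein_length_range: tuple[int, int] = (93, 300)
    #: per-site substitution probability between locus copies
    substitution_rate: float = 0.1
    n_intron_genes: int = 3
    conditions: tuple[str, ...] = ("CK", "PEG", "NaCl")
    timepoints: tuple[str, ...] = ("0h", "3h", "24h")
    n_replicates: int = 3
    ct_noise_sd: float = 0.2
    calibrator: str = "CK:0h"
    #: explicit planted log2 fold-changes {gene: {"cond:tp": fc}}; drawn when None
    expression_log2fc: dict[str, dict[str, float]] | None = None
    #: allow substitutions inside the motif window (robustness testing)
    motif_erosion: bool = False

    def __post_init__(self) -> None:
        for dist in (self.copy_distribution, self.motif_type_distribution):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("distribution must sum to 1")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution rate must be in [0, 1)")


@dataclass
class SimulatedFamily:
    proteins: list[tuple[str, str]]
    cds: list[tuple[str, str]]
    genes: list[GeneModel]
    locus_groups: list[LocusGroup]
    ct_table: CtTable
    truth: dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, out / "proteins.faa")
        write_fasta(self.cds, out / "cds.fna")
        write_gene_table(self.genes, out / "gene_table.tsv")
        write_synteny_table(self.locus_groups, out / "synteny.tsv")
        self.ct_table.data.to_csv(out / "ct_table.tsv", sep="\t", index=False)
        _write_gff3(self.genes, out / "genes.gff3")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=str)
        return out


def _write_gff3(genes: list[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            exons = g.exons or [(g.start, g.end)]
            attr_gene = f"ID=gene:{g.locus_id};Name={g.gene_name}"
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attr_gene}\n"
            )
            mid = f"mRNA:{g.locus_id}"
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mid};Parent=gene:{g.locus_id};Name={g.gene_name}\n"
            )
            for s, e in exons:
                fh.write(
                    f"{g.chrom}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tParent={mid}\n"
                )


def _first_codon_table() -> dict[str, str]:
    """Deterministic back-translation: alphabetically first codon per residue."""
    fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
    by_aa: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        by_aa.setdefault(aa, []).append(codon)
    return {aa: sorted(codons)[0] for aa, codons in by_aa.items()}


def _plant_protein(rng: np.random.Generator, length: int, type_code: str) -> tuple[str, int]:
    """Random protein with exactly one strict motif window of the given type."""
    for _ in range(200):
        seq = list(rng.choice(list(_AA), size=length))
        pos = int(rng.integers(0, length - 10 + 1))
        window = (
            "F"
            + "".join(rng.choice(list(_AA), size=3))
            + "VQ"
            + str(rng.choice(list(_AA)))
            + type_code
        )
        seq[pos : pos + 10] = list(window)
        s = "".join(seq)
        hits = scan_vq(("tmp", s))
        if len(hits) == 1 and hits[0].start == pos + 1:
            return s, pos + 1
    raise RuntimeError("could not plant a unique motif (length too short?)")


def _mutate_copy(
    rng: np.random.Generator,
    seq: str,
    motif_start: int,
    rate: float,
    erode: bool,
    type_code: str,
) -> str:
    """Point-substituted copy; the motif window is protected unless eroding."""
    protected = set(range(motif_start - 1, motif_start + 9))
    for _ in range(200):
        chars = list(seq)
        for i in range(len(chars)):
            if not erode and i in protected:
                continue
            if rng.random() < rate:
                choices = [a for a in _AA if a != chars[i]]
                chars[i] = str(rng.choice(choices))
        s = "".join(chars)
        if erode:
            return s
        hits = scan_vq(("tmp", s))
        if len(hits) == 1 and hits[0].start == motif_start and hits[0].type_code == type_code:
            return s
    raise RuntimeError("mutation kept creating spurious motif windows")


def simulate_family(cfg: SimulationConfig, out_dir: str | Path | None = None) -> SimulatedFamily:
    """Generate a full synthetic dataset with planted ground truth.

    See the module docstring for the generative model. When ``out_dir`` is
    given, all artifacts (FASTA, GFF3, TSV tables, truth.json) are written
    there as well.
    """
    rng = np.random.default_rng(cfg.seed)
    codon = _first_codon_table()
    subgenomes = ["LF", "MF1", "MF2"]

    copy_ns = list(cfg.copy_distribution)
    copy_ps = [cfg.copy_distribution[k] for k in copy_ns]
    type_codes = list(cfg.motif_type_distribution)
    type_ps = [cfg.motif_type_distribution[t] for t in type_codes]

    proteins: list[tuple[str, str]] = []
    cds: list[tuple[str, str]] = []
    groups: list[LocusGroup] = []
    placements: list[dict] = []  # gene name, chrom, span, tandem partner info
    truth_types: dict[str, str] = {}
    truth_pos: dict[str, int] = {}
    tandem_pairs: list[tuple[str, str]] = []
    dup_labels: dict[str, str] = {}

    lo, hi = cfg.protein_length_range
    for locus_idx in range(1, cfg.n_ref_loci + 1):
        n_copies = int(rng.choice(copy_ns, p=copy_ps))
        t_code = str(rng.choice(type_codes, p=type_ps))
        length = int(rng.integers(lo, hi + 1))
        anc, motif_start = _plant_protein(rng, length, t_code)
        ref = f"RefVQ{locus_idx} (REF{locus_idx:04d})"
        subs = list(rng.permutation(subgenomes))[:n_copies]
        tandem_locus = n_copies >= 2 and rng.random() < cfg.tandem_fraction
        members = []
        names = (
            [f"SimVQ{locus_idx}"]
            if n_copies == 1
            else [f"SimVQ{locus_idx}-{i + 1}" for i in range(n_copies)]
        )
        for i, name in enumerate(names):
            seq = (
                anc
                if i == 0
                else _mutate_copy(
                    rng, anc, motif_start, cfg.substitution_rate, cfg.motif_erosion, t_code
                )
            )
            proteins.append((name, seq))
            cds.append((name, "".join(codon[a] for a in seq) + "TAA"))
            truth_types[name] = t_code
            truth_pos[name] = motif_start
            members.append((name, subs[i]))
            placements.append(
                {
                    "name": name,
                    "aa_len": len(seq),
                    "tandem_with_prev": tandem_locus and i == 1,
                }
            )
            if n_copies >= 2:
                dup_labels[name] = "segmental"
        if tandem_locus:
            tandem_pairs.append((names[0], names[1]))
            dup_labels[names[0]] = dup_labels[names[1]] = "tandem"
        groups.append(
            LocusGroup(block="S", tpck_chrom=f"tPCK{1 + locus_idx % 7}", ref_locus=ref, members=members)
        )

    # --- genomic placement -------------------------------------------------
    intron_genes = set(
        rng.choice([p["name"] for p in placements], size=min(cfg.n_intron_genes, len(placements)), replace=False)
    )
    cursors = {
        f"A{c + 1:02d}": int(rng.integers(10_000, 50_000)) for c in range(cfg.n_chromosomes)
    }
    chrom_names = list(cursors)
    genes: list[GeneModel] = []
    truth_introns: dict[str, int] = {}
    prev_chrom: str | None = None
    prev_end = 0
    for p in placements:
        cds_len = 3 * (p["aa_len"] + 1)
        if p["name"] in intron_genes:
            n_ex = int(rng.integers(2, 5))
        else:
            n_ex = 1
        intron_lens = [int(rng.integers(100, 1001)) for _ in range(n_ex - 1)]
        span = cds_len + sum(intron_lens)
        if p["tandem_with_prev"] and prev_chrom is not None:
            chrom = prev_chrom
            start = prev_end + 1 + int(rng.integers(500, 5001))
        else:
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            start = cursors[chrom]
        end = start + span - 1
        if end > cfg.chromosome_length:
            raise ValueError(f"infeasible placement: {p['name']} exceeds chromosome length")
        cursors[chrom] = max(cursors[chrom], end) + int(rng.integers(50_001, 200_000))
        # exon layout: split CDS into n_ex parts separated by the introns
        cuts = sorted(rng.choice(np.arange(1, cds_len // 3), size=n_ex - 1, replace=False)) if n_ex > 1 else []
        bounds = [0, *[3 * c for c in cuts], cds_len]
        exons = []
        cursor = start
        for k in range(n_ex):
            ex_len = bounds[k + 1] - bounds[k]
            exons.append((cursor, cursor + ex_len - 1))
            if k < n_ex - 1:
                cursor += ex_len + intron_lens[k]
        genes.append(
            GeneModel(
                gene_name=p["name"],
                locus_id=p["name"],
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=end,
                cds_length=cds_len,
                exons=exons if n_ex > 1 else None,
            )
        )
        truth_introns[p["name"]] = n_ex - 1
        prev_chrom, prev_end = chrom, end

    # --- expression --------------------------------------------------------
    gene_names = [g.gene_name for g in genes]
    fc_levels = [-3.0, -2.0, 0.0, 2.0, 3.0]  # clear effects or null; see methods note
    planted: dict[str, dict[str, float]] = {}
    for name in gene_names:
        planted[name] = {}
        for cond in cfg.conditions:
            for tp in cfg.timepoints:
                key = f"{cond}:{tp}"
                if key == cfg.calibrator:
                    planted[name][key] = 0.0
                elif cfg.expression_log2fc is not None:
                    planted[name][key] = float(
                        cfg.expression_log2fc.get(name, {}).get(key, 0.0)
                    )
                else:
                    planted[name][key] = float(rng.choice(fc_levels))

    rows = []
    for name in gene_names:
        base_dct = float(rng.uniform(2.0, 8.0))
        for cond in cfg.conditions:
            for tp in cfg.timepoints:
                fc = planted[name][f"{cond}:{tp}"]
                for rep in range(1, cfg.n_replicates + 1):
                    ct_ref = float(20.0 + rng.normal(0.0, 0.1))
                    dct = base_dct - fc + float(rng.normal(0.0, cfg.ct_noise_sd))
                    rows.append(
                        {
                            "gene": name,
                            "condition": cond,
                            "timepoint": tp,
                            "replicate": rep,
                            "ct_target": ct_ref + dct,
                            "ct_reference": ct_ref,
                        }
                    )
    ct = CtTable(pd.DataFrame(rows))

    calls = {
        name: {
            key: ("up" if fc >= 1 else "down" if fc <= -1 else "ns")
            for key, fc in per.items()
        }
        for name, per in planted.items()
    }
    census: dict[str, int] = {}
    for t in truth_types.values():
        census[t] = census.get(t, 0) + 1
    chrom_census: dict[str, int] = {}
    for g in genes:
        chrom_census[g.chrom] = chrom_census.get(g.chrom, 0) + 1
    sub_counts: dict[str, int] = {}
    hist: dict[int, int] = {}
    for grp in groups:
        hist[len(grp.members)] = hist.get(len(grp.members), 0) + 1
        for _, s in grp.members:
            sub_counts[s] = sub_counts.get(s, 0) + 1

    truth = {
        "config": {k: v for k, v in asdict(cfg).items() if k != "expression_log2fc"},
        "n_genes": len(genes),
        "motif_types": truth_types,
        "motif_positions": truth_pos,
        "motif_census": census,
        "intron_counts": truth_introns,
        "n_intronless": sum(1 for v in truth_introns.values() if v == 0),
        "tandem_pairs": [list(p) for p in tandem_pairs],
        "duplication_labels": dup_labels,
        "subgenome_counts": sub_counts,
        "copy_histogram": {str(k): v for k, v in sorted(hist.items())},
        "chromosome_census": chrom_census,
        "expression_log2fc": planted,
        "expression_calls": calls,
    }
    fam = SimulatedFamily(
        proteins=proteins, cds=cds, genes=genes, locus_groups=groups, ct_table=ct, truth=truth
    )
    if out_dir is not None:
        fam.write(out_dir)
    return fam


# ---------------------------------------------------------------------------
# Packaged published-catalogue fixtures


def _fixture(name: str, dest: str | Path | None) -> Path:
    src = resources.files("vqfam.data").joinpath(name)
    with resources.as_file(src) as p:
        if dest is None:
            return Path(p)
        dest = Path(dest)
        if dest.is_dir():
            dest = dest / name
        shutil.copy(p, dest)
        return dest


def table1_fixture(dest: str | Path | None = None) -> Path:
    """Path to (or copy of) the packaged 57-gene catalogue TSV."""
    return _fixture("table1_genes.tsv", dest)


def table2_fixture(dest: str | Path | None = None) -> Path:
    """Path to (or copy of) the packaged synteny/subgenome TSV."""
    return _fixture("table2_synteny.tsv", dest)


def load_catalogue_genes() -> list[GeneModel]:
    """The 57 published gene models (coordinates, strand, CDS length)."""
    return read_gene_table(table1_fixture())


def load_catalogue_table() -> pd.DataFrame:
    """The catalogue with the published derived columns (aa, kDa, pI)."""
    return pd.read_csv(table1_fixture(), sep="\t", comment="#")


def load_synteny_groups() -> list[LocusGroup]:
    """The published locus groups with subgenome labels."""
    return read_synteny_table(table2_fixture())


def synthetic_catalogue_proteome(seed: int = 0) -> list[tuple[str, str]]:
    """SYNTHETIC stand-in for the family's 57 proteins.

    The real protein sequences live in the study's supplementary material and
    are not redistributed here; this generates 57 random proteins whose
    lengths equal the catalogue's published aa lengths and whose planted
    motif types follow the published type census exactly (LTG 43, FTG 8,
    VTG 3, LTS 1, LTV 1, YTG 1). Useful for exercising the scanner and the
    property calculators at the study's scale; the sequences themselves carry
    no biological signal.
    """
    rng = np.random.default_rng(seed)
    table = load_catalogue_table()
    type_pool = ["LTG"] * 43 + ["FTG"] * 8 + ["VTG"] * 3 + ["LTS", "LTV", "YTG"]
    assert len(type_pool) == len(table)
    order = rng.permutation(len(type_pool))
    out = []
    for (_, row), k in zip(table.iterrows(), order):
        seq, _ = _plant_protein(rng, int(row["aa_printed"]), type_pool[k])
        out.append((row["gene_name"], seq))
    return out
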