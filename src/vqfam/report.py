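"""Headline-tally summary over stage outputs.

The report is a pure function of already-computed stage outputs: it never
re-runs scanning, phylogeny, or classification. Any subset of inputs may be
supplied; tallies for absent stages are simply omitted.
"""

from __future__ import annotations

import json
from typing import Sequence

import pandas as pd

from .core_io import GeneModel, LocusGroup, ProteinRecord
from .gene_structure import intronless_census
from .motif_scan import MotifCensus
from .protein_props import protein_length_from_cds
from .duplication import chromosome_census, subgenome_tabulate

__all__ = ["build_report", "report_text"]

SMALL_PROTEIN_AA = 300


def build_report(
    genes: Sequence[GeneModel] | None = None,
    locus_groups: Sequence[LocusGroup] | None = None,
    motif_census: MotifCensus | None = None,
    protein_props: pd.DataFrame | None = None,  # columns id, length_aa, mw_kda, pi
    duplication_labels: dict[str, str] | None = None,
) -> dict:
    """Collect headline tallies from whichever stage outputs are present."""
    if all(x is None for x in (genes, locus_groups, motif_census, protein_props, duplication_labels)):
        raise ValueError("no stage outputs supplied")
    rep: dict = {}
    if genes is not None:
        n0, n = intronless_census(genes)
        lengths = [protein_length_from_cds(g.cds_length) for g in genes if g.cds_length % 3 == 0]
        rep["n_genes"] = n
        rep["n_intronless"] = n0
        rep["n_proteins_le_300aa"] = sum(1 for L in lengths if L <= SMALL_PROTEIN_AA)
        rep["protein_length_range_aa"] = [min(lengths), max(lengths)]
        rep["chromosome_census"] = chromosome_census(genes)
    if motif_census is not None:
        rep["motif_census"] = dict(sorted(motif_census.counts.items(), key=lambda kv: -kv[1]))
        rep["n_proteins_with_motif"] = motif_census.n_proteins_with_hit
        rep["n_proteins_scanned"] = motif_census.n_proteins_scanned
    if locus_groups is not None:
        sub, hist = subgenome_tabulate(locus_groups)
        rep["subgenome_counts"] = sub
        rep["copy_number_histogram"] = {str(k): v for k, v in hist.items()}
        rep["n_anchored_genes"] = sum(
            len(g.members) for g in locus_groups if g.ref_locus
        )
        rep["n_grouped_genes"] = sum(len(g.members) for g in locus_groups)
    if duplication_labels is not None:
        rep["n_tandem_genes"] = sum(1 for v in duplication_labels.values() if v == "tandem")
        rep["n_segmental_genes"] = sum(1 for v in duplication_labels.values() if v == "segmental")
    if protein_props is not None:
        rep["mw_range_kda"] = [
            round(float(protein_props["mw_kda"].min()), 2),
            round(float(protein_props["mw_kda"].max()), 2),
        ]
        rep["pi_range"] = [
            round(float(protein_props["pi"].min()), 2),
            round(float(protein_props["pi"].max()), 2),
        ]
    return rep


def report_text(rep: dict) -> str:
    """Human-readable rendering of a report dictionary."""
    lines = ["# family summary"]
    for key, val in rep.items():
        if isinstance(val, dict):
            body = ", ".join(f"{k}:{v}" for k, v in val.items())
            lines.append(f"{key}: {body}")
        else:
            lines.append(f"{key}: {val}")
    return "\n".join(lines)


def report_json(rep: dict) -> str:
    return json.dumps(rep, indent=1)
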