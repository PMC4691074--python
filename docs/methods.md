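# Methods

## Scope and data model

The pipeline characterizes a gene family from four inputs: protein (and
optionally CDS) FASTA, gene models (GFF3 or a catalogue-style TSV with
chromosome, strand, genomic span and CDS length), a synteny table mapping
member genes to ancestral-locus groups with subgenome labels (LF/MF1/MF2),
and qPCR Ct tables. Coordinates are 1-based inclusive throughout; GFF3 is
native in that convention and the catalogue satisfies
`end − start + 1 = CDS` for intronless genes, so no conversion is applied
anywhere. Strand is carried for reporting only — all sequence-level
computations take the supplied protein sequences as given.

Two published tables ship as packaged TSV fixtures: the 57-gene catalogue
and the synteny/subgenome table. Four catalogue `Location` cells carry
misplaced thousands separators in the source; the cells are transcribed
verbatim and the reader strips all separators before parsing, which in each
case recovers a span consistent with the CDS length. The protein sequences
themselves are not redistributed; where a family-scale proteome is needed
(tests, demonstrations) a generator produces a stand-in explicitly labelled
synthetic, with catalogue lengths and planted motif types at the published
frequencies.

## Motif scanning

The scanner matches a PROSITE-like consensus over a 10-residue window with
the F anchor at position 1, V at 5 and Q at 6. Strict mode additionally
fixes T at position 9, shared by all six motif types observed in this
family (LTG, FTG, VTG, LTS, LTV, YTG); relaxed mode admits H at position 6
and frees position 9 for cross-species scans (e.g. the LTD and VHxVTG
variants seen elsewhere). All overlapping windows are reported left to
right. For the family census each protein contributes exactly one type —
that of its **leftmost** strict hit. Published censuses assign one type per
protein without stating a tie rule; leftmost is deterministic and exposed
alongside an all-hits view. Patterns are plain strings, so the module
generalizes to any short-consensus family.

## Protein properties

- **Length from CDS**: aa = bp/3 − 1 (stop codon excluded); non-triplet CDS
  lengths are an error here and a recorded warning at parse time.
- **Molecular weight**: sum of average (isotope-weighted) residue masses
  plus one water (18.0153 Da). The mass table is a versioned data asset;
  the unknown residue X counts toward length, adds zero mass, and joins no
  ionizable group — a conservative, explicit convention.
- **Isoelectric point**: bisection on [0, 14] for the zero of the
  Henderson–Hasselbalch net charge, stopping at |Q| < 1e−4 or an interval
  below 0.001 pH. Q(pH) is strictly decreasing, so bisection is
  unconditionally convergent (Newton is unnecessary). The default pKa set
  is the Bjellqvist table used by the ProtParam tool, including its
  residue-specific N/C-terminal overrides (e.g. a C-terminal Asp raises the
  Cterm pKa to 4.55); an EMBOSS set ships alongside for sensitivity checks.
  Both live in editable data files. Published pI values for this family are
  matched to about ±0.2 pH — the printing source's exact constants are not
  stated, so agreement is contracted at that tolerance, not bit-exactness.

## Gene structure

With exon lists the intron count is exact (#exons − 1). With
catalogue-style data only, `span == CDS` is the intronless criterion: the
catalogued spans exclude UTRs for these genes, so the criterion is exact on
every intronless row, and a span exceeding the CDS implies "at least one
intron" without fixing the count (reported as unknown). The family-level
census counts genes whose status resolves to zero introns under either
route.

## Phylogeny

Pairwise alignment is global Needleman–Wunsch with affine gaps via a
standard aligner (BLOSUM62, gap open 10, extend 0.5 — needle-style
defaults). Identity is identical pairs over all alignment columns;
similarity additionally counts positive-scoring pairs. The progressive MSA
is intentionally simple and fully deterministic: NJ guide tree over
pairwise identity distances, then leaf-to-root profile–profile DP merging
on mean column-pair substitution scores with a linear per-column gap cost
of 8. No iterative refinement is attempted — downstream analyses here need
a reasonable, reproducible alignment, not an optimal one.

Distances are p-distance (default) or Poisson-corrected −ln(1 − p), with
pairwise or complete gap deletion; the source method names only
"neighbor-joining", so the model is a flag rather than a guess. NJ follows
Saitou–Nei agglomeration with the Studier–Keppler Q criterion. Two
under-specified details are fixed deterministically: Q ties break on the
lexicographically smallest pair of cluster representative (minimum leaf)
names, and negative branch lengths are clamped to zero with the deficit
moved to the sibling edge, conserving path lengths — common NJ practice.
On additive matrices the implementation inverts the generating tree
exactly (tested up to 12 taxa, and cross-checked against an independent NJ
implementation).

Bootstrap resamples alignment columns with replacement per replicate,
rebuilds distances and the NJ tree, and scores each internal edge of the
full-data tree by the percentage of replicates containing the same
bipartition; a single seed drives all replicates. Subgroup extraction cuts
the k−1 longest internal edges (ties by higher support, then by smallest
descendant leaf name), falling back to terminal edges only when internal
edges run out; published subgroup boundaries were drawn manually, so the
cut is parameterized by k rather than hard-coded.

## Duplication analysis

Ortholog naming aligns each query protein against the reference proteome
and names it after its best hit (similarity score, ties by reference id);
co-orthologs of one reference gene get "-1..n" suffixes in descending
similarity order, ties by query id, and singletons keep the bare name.

Synteny is an input: locus groups arrive from an external service's block
assignments. Within each multi-member group every unordered pair is typed:
**tandem** if on the same chromosome with intergenic gap ≤ `tandem_max_gap`
(default 25 kb), else **segmental**. The default threshold is conventional
and uncritical here: in the published family the sole tandem pair sits
2.4 kb apart while the nearest same-chromosome segmental pair is >7 Mb
apart, so any cutoff in that span gives the same answer (the synthetic
tests sweep the threshold to confirm this robustness). Genes in a tandem
pair are labelled tandem and excluded from the segmental gene count — under
this reading the catalogue yields 41 segmental genes plus the one tandem
pair, consistent with the published split. Subgenome tallies count members
per LF/MF1/MF2 label; the copy-number histogram counts members per
anchored reference locus (unanchored groups are excluded from the
histogram but not the totals). The packaged table yields histogram
{1: 10, 2: 11, 3: 7} over 28 anchored loci; the source text prints a
different single/double split (13/11) that is inconsistent with its own
table, so the tabulator reports what the input implies.

## Expression analysis

Per replicate, ΔCt = Ct_target − Ct_reference; per cell (gene × condition ×
timepoint), ΔΔCt is the difference of mean ΔCt against the calibrator cell
and rq = 2^−ΔΔCt (amplification efficiency fixed at 2.0; efficiency-
corrected modes are out of scope). The calibrator is addressed as a
"condition:timepoint" key and may be overridden per gene, since published
panels sometimes calibrate individual genes against a different sample.
Significance is a two-sided Welch t-test on replicate ΔCt versus the
calibrator replicates (no equal-variance assumption; a pooled-variance
flag exists). A call requires both criteria: `up` needs rq ≥ fold_threshold
(default 2) and p < α (default 0.05); `down` mirrors it at 1/threshold;
stars are * for p < 0.05 and ** for p < 0.01. No multiple-testing
correction drives calls — matching per-gene annotation practice — but a
Benjamini–Hochberg column is emitted for transparency. With a single
replicate the fold change is reported and the test marked unavailable.

## Synthetic-data generator

The generator emulates the statistical structure of a WGT-shaped family —
it is the ground-truth harness for every stage, not a biological simulator.
Defaults mirror the study's observed structure: 28 ancestral loci with
copy-number mix 10/11/7 (one/two/three copies), motif types drawn at the
published frequencies (LTG 43/57, FTG 8/57, VTG 3/57, LTS/LTV/YTG 1/57
each), protein lengths uniform on 93–300 aa (the observed minimum and the
"small protein" mode of the family), 10 chromosomes of 30 Mb, a per-site
substitution rate of 0.1 between copies, 3 genes with planted introns, and
a 1/18 tandem fraction (one expected tandem pair among the multi-copy
loci). Expression designs default to 3 conditions × 3 timepoints × 3
replicates with 0.2-cycle Gaussian replicate noise — a typical qPCR
technical spread. Planted log2 fold-changes are either null or clear
(|log2FC| ≥ 2): effects exactly at the two-fold boundary make the truth
call ill-defined under noise, so the default design avoids them; explicit
per-cell effects (any magnitude) can be planted via the config for
bias/recovery studies.

Mechanics chosen for exact recoverability: each ancestral protein carries
exactly one planted motif window (rejection-sampled against accidental
matches); copies diverge by point substitution with the window protected
(an erosion flag lifts this for robustness testing); back-translation uses
the alphabetically first codon per residue so CDS fixtures are
deterministic; tandem copies are placed 0.5–5 kb apart while all other
placements advance a per-chromosome cursor by ≥50 kb, so any tandem
threshold between 5 and 50 kb recovers the planted labels. `truth.json`
records every planted quantity.

What the generator does **not** emulate: real substitution processes
(no rate heterogeneity, no indels beyond the planted case), codon usage,
UTRs, pseudogenization, expression correlation structure, or primer
efficiency variation. Passing recovery tests therefore demonstrates the
pipeline's correctness on data satisfying its assumptions, not performance
on real genomes.

## Problem sizes and determinism

The test suite and analysis scripts run at desk scale by design: simulated
families of ~20–60 genes, bootstrap with 50–200 replicates in tests (the
CLI defaults to 1000 for real use), 100–200 simulation repeats for
error-rate and bias checks. Every stochastic component takes an explicit
seed; identical seeds reproduce identical families, trees and tables.

## Known limitations

- The intronless inference is only as good as the catalogue convention
  (span excluding UTRs); catalogues that include UTRs would need exon
  lists.
- The progressive MSA has no refinement and a linear profile gap cost; it
  is not a substitute for a production aligner on divergent families.
- NJ tie-breaking and negative-branch handling are deterministic choices
  among several defensible ones; trees from other NJ implementations may
  differ on non-additive matrices.
- Ortholog naming uses global-alignment similarity, not reciprocal-best
  BLAST; for distant references the two can disagree.
- The expression module assumes perfect doubling per cycle and
  approximately normal replicate ΔCt.
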