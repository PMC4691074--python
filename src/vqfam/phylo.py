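"""Alignment, distances, neighbor-joining with bootstrap, and subgroup cuts.

Pairwise alignment is global Needleman-Wunsch with affine gaps (BLOSUM62 by
default). The multiple alignment is deliberately simple and deterministic:
an NJ guide tree over pairwise identity distances, then leaf-to-root
profile-profile merging. NJ follows Saitou-Nei agglomeration with the
Studier-Keppler Q criterion; Q ties break on the lexicographically smallest
pair of cluster representative names, and negative branch lengths are
clamped to zero with the deficit moved to the sibling edge (path lengths
are conserved). Bootstrap supports are bipartition frequencies over
column-resampled replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import TreeNode

__all__ = [
    "Alignment",
    "global_align",
    "progressive_msa",
    "distance_matrix",
    "nj_tree",
    "bootstrap",
    "cut_subgroups",
]

GAP = "-"


@dataclass
class Alignment:
    """Ordered (id, gapped sequence) rows of equal length."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError("gapped sequences differ in length")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1])

    def ungapped(self, rid: str) -> str:
        for i, s in self.rows:
            if i == rid:
                return s.replace(GAP, "")
        raise KeyError(rid)

    def subset_columns(self, idx: Sequence[int]) -> "Alignment":
        return Alignment([(i, "".join(s[c] for c in idx)) for i, s in self.rows])


def _load_matrix(name: str):
    return substitution_matrices.load(name)


def global_align(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[Alignment, float, float]:
    """Optimal global alignment of two sequences with affine gap costs.

    Returns (alignment, identity %, similarity %): identity counts identical
    pairs over all alignment columns; similarity additionally counts pairs
    with a positive substitution score.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    matrix = _load_matrix(matrix_name)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(a.upper(), b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    n_cols = len(ga)
    ident = sim = 0
    for x, y in zip(ga, gb):
        if x == GAP or y == GAP:
            continue
        if x == y:
            ident += 1
            sim += 1
        elif matrix[x, y] > 0:
            sim += 1
    return (
        Alignment([("a", ga), ("b", gb)]),
        100.0 * ident / n_cols,
        100.0 * sim / n_cols,
    )


# ---------------------------------------------------------------------------
# Progressive multiple alignment


def _profile_align(
    pa: list[tuple[str, str]],
    pb: list[tuple[str, str]],
    matrix,
    gap_cost: float = 8.0,
) -> list[tuple[str, str]]:
    """Merge two profiles by global DP on mean column-pair substitution score."""
    ca = [tuple(s[k] for _, s in pa) for k in range(len(pa[0][1]))] if pa[0][1] else []
    cb = [tuple(s[k] for _, s in pb) for k in range(len(pb[0][1]))]
    n, m = len(ca), len(cb)

    def col_score(ci, cj) -> float:
        total = 0.0
        k = 0
        for x in ci:
            for y in cj:
                if x == GAP or y == GAP:
                    continue
                total += matrix[x, y]
                k += 1
        return total / k if k else 0.0

    score = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up (gap in b), 2 left
    score[:, 0] = -gap_cost * np.arange(n + 1)
    score[0, :] = -gap_cost * np.arange(m + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = score[i - 1, j - 1] + col_score(ca[i - 1], cb[j - 1])
            u = score[i - 1, j] - gap_cost
            l = score[i, j - 1] - gap_cost
            best = max(d, u, l)
            score[i, j] = best
            ptr[i, j] = 0 if best == d else (1 if best == u else 2)
    # traceback
    out_a: list[list[str]] = [[] for _ in pa]
    out_b: list[list[str]] = [[] for _ in pb]
    i, j = n, m
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0 and i > 0 and j > 0:
            for r, (_, s) in enumerate(pa):
                out_a[r].append(s[i - 1])
            for r, (_, s) in enumerate(pb):
                out_b[r].append(s[j - 1])
            i, j = i - 1, j - 1
        elif move == 1 and i > 0:
            for r, (_, s) in enumerate(pa):
                out_a[r].append(s[i - 1])
            for r in range(len(pb)):
                out_b[r].append(GAP)
            i -= 1
        else:
            for r in range(len(pa)):
                out_a[r].append(GAP)
            for r, (_, s) in enumerate(pb):
                out_b[r].append(s[j - 1])
            j -= 1
    merged = [(rid, "".join(reversed(cols))) for (rid, _), cols in zip(pa, out_a)]
    merged += [(rid, "".join(reversed(cols))) for (rid, _), cols in zip(pb, out_b)]
    return merged


def progressive_msa(
    seqs: Sequence[tuple[str, str]],
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Alignment:
    """Progressive multiple alignment along an NJ guide tree.

    Deterministic given input order: pairwise NW identity distances build the
    guide tree, and profiles merge leaf-to-root. Two sequences reduce to the
    pairwise alignment.
    """
    if len(seqs) < 2:
        raise ValueError("need >= 2 sequences")
    ids = [i for i, _ in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    by_id = {i: s.upper() for i, s in seqs}
    matrix = _load_matrix(matrix_name)
    if len(seqs) == 2:
        aln, _, _ = global_align(seqs[0][1], seqs[1][1], matrix_name, gap_open, gap_extend)
        return Alignment([(ids[0], aln.rows[0][1]), (ids[1], aln.rows[1][1])])

    dist = np.zeros((len(seqs), len(seqs)))
    for (i, (_, sa)), (j, (_, sb)) in combinations(enumerate(seqs), 2):
        _, ident, _ = global_align(sa, sb, matrix_name, gap_open, gap_extend)
        dist[i, j] = dist[j, i] = 1.0 - ident / 100.0
    guide = nj_tree(DistanceMatrix(dist, ids))

    def merge(node: TreeNode) -> list[tuple[str, str]]:
        if node.is_tip():
            return [(node.name, by_id[node.name])]
        profile = merge(node.children[0])
        for child in node.children[1:]:
            profile = _profile_align(profile, merge(child), matrix)
        return profile

    rows = merge(guide)
    order = {rid: k for k, rid in enumerate(ids)}
    rows.sort(key=lambda r: order[r[0]])
    return Alignment(rows)


# ---------------------------------------------------------------------------
# Distances


def distance_matrix(
    al: Alignment,
    model: str = "p-distance",
    deletion: str = "pairwise",
) -> DistanceMatrix:
    """Pairwise evolutionary distances from an alignment.

    p-distance = mismatches / valid columns; Poisson correction is
    -ln(1 - p). Pairwise deletion drops columns where either row is gapped;
    complete deletion drops columns with a gap in any row.
    """
    if model not in ("p-distance", "p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    ids = al.ids
    arr = np.array([list(s) for _, s in al.rows])
    if deletion == "complete":
        keep = ~(arr == GAP).any(axis=0)
        arr = arr[:, keep]
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = arr[i], arr[j]
        valid = (a != GAP) & (b != GAP)
        nv = int(valid.sum())
        if nv == 0:
            raise ValueError(f"no valid columns between {ids[i]} and {ids[j]}")
        p = float((a[valid] != b[valid]).sum()) / nv
        if model == "poisson":
            if p >= 1.0:
                raise ValueError(f"saturated pair {ids[i]}, {ids[j]}: p = 1 (infinite distance)")
            p = -np.log(1.0 - p)
        d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids)


# ---------------------------------------------------------------------------
# Neighbor joining


def _min_leaf(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return min(t.name for t in node.tips())


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining under the Studier-Keppler Q criterion.

    Returns an unrooted tree represented with a trifurcating root. Q ties
    break on the lexicographically smallest (representative, representative)
    pair; negative branch lengths are clamped to zero with the deficit moved
    to the sibling edge.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    reps: list[str] = list(ids)
    d = dm.data.astype(float).copy()

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i, j in combinations(range(n), 2):
            q = (n - 2) * d[i, j] - r[i] - r[j]
            key = tuple(sorted((reps[i], reps[j])))
            if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and key < best[2]):
                best_q = q
                best = (i, j, key)
        i, j, _ = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent.append(ci)
        parent.append(cj)
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    root = TreeNode()
    for node, ln in ((a, la), (b, lb), (c, lc)):
        node.length = float(max(ln, 0.0))
        root.append(node)
    return root


# ---------------------------------------------------------------------------
# Bootstrap


def _bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Internal-edge bipartitions as the smaller/canonical leaf-name side."""
    all_leaves = frozenset(t.name for t in tree.tips())
    out: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_leaves - side
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out[canon] = node
    return out


def bootstrap(
    al: Alignment,
    n_reps: int,
    seed: int,
    model: str = "p-distance",
    deletion: str = "pairwise",
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement, rebuilds
    distances and the NJ tree; an edge's support is the percentage of
    replicates containing the same bipartition. Reproducible for fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if al.n_cols < 2:
        raise ValueError("alignment has fewer than 2 columns")
    full = nj_tree(distance_matrix(al, model=model, deletion=deletion))
    target = _bipartitions(full)
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, al.n_cols, size=al.n_cols)
        rep_al = al.subset_columns(idx.tolist())
        try:
            rep_tree = nj_tree(distance_matrix(rep_al, model=model, deletion=deletion))
        except ValueError:
            continue  # degenerate resample (no valid columns for some pair)
        rep_bps = set(_bipartitions(rep_tree))
        for bp in hits:
            if bp in rep_bps:
                hits[bp] += 1
    for bp, node in target.items():
        support = int(round(100.0 * hits[bp] / n_reps))
        node.support = support
        node.name = str(support)
    return full


# ---------------------------------------------------------------------------
# Subgroup extraction


def cut_subgroups(tree: TreeNode, k: int) -> list[set[str]]:
    """Partition leaves into k groups by removing the k-1 longest edges.

    Internal edges are preferred (longest first; ties by higher support,
    then by smallest descendant leaf name); terminal edges are cut only when
    internal edges run out. Edges are removed greedily until k non-empty
    leaf groups exist.
    """
    leaves = [t.name for t in tree.tips()]
    if not 1 <= k <= len(leaves):
        raise ValueError(f"k must be in [1, {len(leaves)}]")
    if k == 1:
        return [set(leaves)]
    if k == len(leaves):
        return [{name} for name in leaves]

    def sort_key(node: TreeNode):
        support = getattr(node, "support", None)
        return (
            -(node.length or 0.0),
            -(support if support is not None else -1),
            _min_leaf(node),
        )

    internal = sorted(tree.non_tips(include_self=False), key=sort_key)
    terminal = sorted(tree.tips(), key=sort_key)
    candidates = internal + terminal
    cut: set[int] = set()
    for node in candidates:
        cut.add(id(node))
        groups = _components(tree, cut)
        if len(groups) >= k:
            return groups
    return _components(tree, cut)


def _components(tree: TreeNode, cut: set[int]) -> list[set[str]]:
    groups: list[set[str]] = []

    def walk(node: TreeNode, comp: set[str]) -> None:
        if node.is_tip():
            comp.add(node.name)
            return
        for child in node.children:
            if id(child) in cut:
                new: set[str] = set()
                groups.append(new)
                walk(child, new)
            else:
                walk(child, comp)

    first: set[str] = set()
    groups.append(first)
    walk(tree, first)
    return [g for g in groups if g]
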