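"""Alignment, distances, NJ (with additive-matrix oracle), bootstrap, cuts."""

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj as skbio_nj

from vqfam.phylo import (
    Alignment,
    _bipartitions,
    bootstrap,
    cut_subgroups,
    distance_matrix,
    global_align,
    nj_tree,
    progressive_msa,
)

# ---------------------------------------------------------------------------
# pairwise alignment


def test_identical_sequences_full_identity():
    _, ident, sim = global_align("MKVQ", "MKVQ")
    assert ident == 100.0 and sim == 100.0


def test_one_mismatch_in_four():
    _, ident, _ = global_align("AAAA", "AACA")
    assert ident == pytest.approx(75.0)


def test_similarity_counts_positive_score_pairs():
    # L/I score positively in BLOSUM62 but are not identical
    _, ident, sim = global_align("MLML", "MIMI")
    assert sim > ident


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        global_align("", "MKV")


# ---------------------------------------------------------------------------
# multiple alignment


def test_msa_of_two_reduces_to_pairwise():
    al = progressive_msa([("a", "MKVQLL"), ("b", "MKVLL")])
    pair, _, _ = global_align("MKVQLL", "MKVLL")
    assert al.rows[0][1] == pair.rows[0][1] and al.rows[1][1] == pair.rows[1][1]


def test_msa_of_identical_sequences_is_gap_free():
    al = progressive_msa([("a", "MKVQLLW"), ("b", "MKVQLLW"), ("c", "MKVQLLW")])
    assert all("-" not in s for _, s in al.rows)


def test_msa_recovers_ungapped_inputs():
    seqs = [("a", "MKVQLLWDERA"), ("b", "MKVELLWDERA"), ("c", "MKVQLLWAERA")]
    al = progressive_msa(seqs)
    for rid, seq in seqs:
        assert al.ungapped(rid) == seq


def test_planted_insertion_appears_as_shared_gap_block():
    base = "MKVQLLWDERAGHTYPSNKMKVQLLWDERAGHTYPSNK"
    insert = base[:19] + "WWHHWW" + base[19:]
    seqs = [("a", base), ("b", base), ("c", base), ("ins", insert)]
    al = progressive_msa(seqs)
    rows = dict(al.rows)
    gap_cols = [
        k
        for k in range(al.n_cols)
        if rows["ins"][k] != "-" and all(rows[r][k] == "-" for r in "abc")
    ]
    assert len(gap_cols) == 6
    assert gap_cols == list(range(gap_cols[0], gap_cols[0] + 6))


# ---------------------------------------------------------------------------
# distances


def _al(*rows):
    return Alignment([(f"s{i}", r) for i, r in enumerate(rows)])


def test_identical_rows_zero_distance():
    dm = distance_matrix(_al("MKVQ", "MKVQ"))
    assert dm[0, 1] == 0.0


def test_p_distance_one_in_four():
    assert distance_matrix(_al("MKVQ", "MKVA"))[0, 1] == pytest.approx(0.25)


def test_poisson_correction():
    assert distance_matrix(_al("MKVQ", "MKVA"), model="poisson")[0, 1] == pytest.approx(
        0.2877, abs=1e-4
    )


def test_pairwise_deletion_skips_gapped_columns():
    dm = distance_matrix(_al("MK-Q", "MKVQ"))
    assert dm[0, 1] == 0.0


def test_all_gap_pair_rejected():
    with pytest.raises(ValueError, match="valid columns"):
        distance_matrix(_al("--AA", "AA--", "AAAA"))


def test_saturated_poisson_rejected():
    with pytest.raises(ValueError, match="[Ss]aturated|infinite"):
        distance_matrix(_al("AAAA", "CCCC"), model="poisson")


# ---------------------------------------------------------------------------
# neighbor joining


def test_three_taxon_star_branch_lengths():
    dm = DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ["A", "B", "C"])
    tree = nj_tree(dm)
    lengths = {c.name: c.length for c in tree.children}
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})


def test_fewer_than_three_taxa_rejected():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["A", "B"]))


def test_leaf_set_preserved():
    rng = np.random.default_rng(0)
    x = rng.random((5, 5))
    d = (x + x.T) / 2
    np.fill_diagonal(d, 0)
    ids = list("ABCDE")
    tree = nj_tree(DistanceMatrix(d, ids))
    assert sorted(t.name for t in tree.tips()) == ids


def _random_additive_tree(rng, n):
    nodes = [TreeNode(name=f"t{i:02d}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode()
        for k in (i, j):
            nodes[k].length = float(rng.uniform(0.05, 1.0))
            parent.append(nodes[k])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = TreeNode()
    for nd in nodes:
        nd.length = float(rng.uniform(0.05, 1.0))
        root.append(nd)
    return root


@pytest.mark.parametrize("n_taxa", [4, 5, 8, 12])
def test_nj_inverts_additive_matrices(n_taxa):
    """Tree -> path-distance matrix -> NJ recovers topology and distances."""
    rng = np.random.default_rng(100 + n_taxa)
    for _ in range(5):
        true_tree = _random_additive_tree(rng, n_taxa)
        dm = true_tree.tip_tip_distances()
        est = nj_tree(dm)
        est_dm = est.tip_tip_distances()
        for a, b in zip(dm.condensed_form(), est_dm.filter(dm.ids).condensed_form()):
            assert a == pytest.approx(b, abs=1e-8)
        assert set(_bipartitions(true_tree)) == set(_bipartitions(est))


def test_agrees_with_reference_nj_on_additive_matrix():
    rng = np.random.default_rng(11)
    true_tree = _random_additive_tree(rng, 8)
    dm = true_tree.tip_tip_distances()
    ours = nj_tree(dm)
    reference = skbio_nj(dm)
    assert set(_bipartitions(ours)) == set(_bipartitions(reference))


# ---------------------------------------------------------------------------
# bootstrap


def _split_alignment():
    a = "MKVQLLWDER" * 4
    b = "AGHTYPSNKC" * 4
    return Alignment([("A1", a), ("A2", a), ("B1", b), ("B2", b)])


def test_trivial_split_gets_full_support():
    tree = bootstrap(_split_alignment(), n_reps=50, seed=5)
    supports = [n.support for n in tree.non_tips(include_self=False)]
    assert supports == [100]


def test_bootstrap_reproducible_for_fixed_seed():
    t1 = bootstrap(_split_alignment(), n_reps=20, seed=9)
    t2 = bootstrap(_split_alignment(), n_reps=20, seed=9)
    s1 = sorted(n.support for n in t1.non_tips(include_self=False))
    s2 = sorted(n.support for n in t2.non_tips(include_self=False))
    assert s1 == s2


def test_zero_replicates_rejected():
    with pytest.raises(ValueError):
        bootstrap(_split_alignment(), n_reps=0, seed=1)


def test_planted_clades_get_strong_support():
    """Clearly diverged clades in a simulated family reach support >= 70."""
    rng = np.random.default_rng(21)
    motifs = ["MKVQLLWDER", "AGHTYPSNKC", "CCNNYYPPSS", "WWHHGGTTRR"]
    rows = []
    for ci, motif in enumerate(motifs):
        for j in range(2):
            seq = list(motif * 5)
            for k in rng.choice(len(seq), size=3, replace=False):
                seq[k] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
            rows.append((f"c{ci}_{j}", "".join(seq)))
    al = Alignment(rows)
    tree = bootstrap(al, n_reps=200, seed=3)
    clade_bps = {frozenset({f"c{ci}_0", f"c{ci}_1"}) for ci in range(4)}
    found = {
        frozenset(t.name for t in node.tips()): node.support
        for node in tree.non_tips(include_self=False)
    }
    for bp in clade_bps:
        assert bp in found and found[bp] >= 70


# ---------------------------------------------------------------------------
# subgroup cuts


def _seven_clade_tree():
    n_clades = 7
    ids = [f"g{c}_{i}" for c in range(n_clades) for i in range(2)]
    d = np.full((14, 14), 1.0)
    for c in range(n_clades):
        i, j = 2 * c, 2 * c + 1
        d[i, j] = d[j, i] = 0.05
    np.fill_diagonal(d, 0)
    return nj_tree(DistanceMatrix(d, ids)), ids


def test_cut_k1_and_singletons():
    tree, ids = _seven_clade_tree()
    assert cut_subgroups(tree, 1) == [set(ids)]
    assert sorted(map(sorted, cut_subgroups(tree, len(ids)))) == sorted([[i] for i in ids])


def test_cut_recovers_planted_clades():
    tree, ids = _seven_clade_tree()
    groups = cut_subgroups(tree, 7)
    expected = [{f"g{c}_0", f"g{c}_1"} for c in range(7)]
    assert sorted(map(sorted, groups)) == sorted(map(sorted, expected))


def test_cut_k_out_of_range():
    tree, ids = _seven_clade_tree()
    with pytest.raises(ValueError):
        cut_subgroups(tree, len(ids) + 1)
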