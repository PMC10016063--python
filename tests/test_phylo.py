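"""Distances, neighbor joining, midpoint rooting, and bootstrap support."""

import math

import numpy as np
import pytest

from carotscan.phylo import (
    BootstrapParams,
    DistanceMatrix,
    bootstrap_support,
    midpoint_root,
    nj_tree,
    pairwise_distance,
    tree_splits,
)
from carotscan.seqio import Alignment, SequenceRecord, read_newick
from treegen import (
    brute_force_min_max_depth,
    max_root_depth,
    patristic_matrix,
    random_tree,
    splits_of,
)


def _aln(pairs):
    return Alignment([SequenceRecord(i, s) for i, s in pairs])


# ------------------------------------------------------------------ distances

def test_identical_sequences_have_zero_distance():
    aln = _aln([("a", "MKVA"), ("b", "MKVA")])
    for model in ("p", "poisson"):
        assert pairwise_distance(aln, model).get("a", "b") == 0.0


def test_p_and_poisson_hand_example():
    aln = _aln([("a", "AAAA"), ("b", "AAAT")])
    assert pairwise_distance(aln, "p").get("a", "b") == pytest.approx(0.25)
    assert pairwise_distance(aln, "poisson").get("a", "b") == pytest.approx(
        -math.log(0.75), abs=1e-5
    )


def test_pairwise_deletion_rule():
    aln = _aln([("a", "A-AA"), ("b", "AGAT")])
    assert pairwise_distance(aln, "p").get("a", "b") == pytest.approx(1 / 3)


def test_no_comparable_columns_is_an_error():
    aln = _aln([("a", "A--"), ("b", "-GG"), ("c", "AGG")])
    with pytest.raises(ValueError, match="'a'.*'b'"):
        pairwise_distance(aln, "p")


def test_poisson_cap_keeps_saturated_pairs_finite():
    aln = _aln([("a", "AAAA"), ("b", "TTTT")])
    d = pairwise_distance(aln, "poisson").get("a", "b")
    assert d == pytest.approx(-math.log(1 - 0.999))


# ------------------------------------------------------------------------- NJ

QUARTET = DistanceMatrix(
    ("A", "B", "C", "D"),
    np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ], dtype=float),
)


def test_nj_recovers_the_additive_quartet_exactly():
    tree = nj_tree(QUARTET)
    assert splits_of(tree) == {frozenset({"C", "D"})}
    np.testing.assert_allclose(
        patristic_matrix(tree).values, QUARTET.values, atol=1e-9
    )


def test_nj_three_labels_closed_form():
    D = DistanceMatrix(("A", "B", "C"),
                       np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
    tree = nj_tree(D)
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})


def test_nj_is_invariant_to_label_order(rng):
    tree = random_tree(8, rng)
    D = patristic_matrix(tree)
    perm = rng.permutation(len(D.labels))
    D_perm = DistanceMatrix(
        tuple(D.labels[i] for i in perm), D.values[np.ix_(perm, perm)]
    )
    t1, t2 = nj_tree(D), nj_tree(D_perm)
    assert splits_of(t1) == splits_of(t2)
    np.testing.assert_allclose(
        patristic_matrix(t1).values, patristic_matrix(t2).values, atol=1e-12
    )


def test_nj_recovers_random_additive_matrices(rng):
    for _ in range(100):
        n = int(rng.integers(4, 13))
        tree = random_tree(n, rng)
        D = patristic_matrix(tree)
        est = nj_tree(D)
        assert splits_of(est) == splits_of(tree)
        np.testing.assert_allclose(patristic_matrix(est).values, D.values, atol=1e-9)


def test_nj_agrees_with_scikit_bio(rng):
    skbio = pytest.importorskip("skbio")
    for _ in range(10):
        n = int(rng.integers(5, 10))
        tree = random_tree(n, rng)
        D = patristic_matrix(tree)
        sk = skbio.tree.nj(skbio.DistanceMatrix(D.values, ids=list(D.labels)))
        sk_tree = read_newick(str(sk))
        assert splits_of(nj_tree(D)) == splits_of(sk_tree)


def test_nj_rejects_bad_matrices():
    with pytest.raises(ValueError):
        DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]], float))
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


# ------------------------------------------------------------- midpoint root

def test_midpoint_two_tips():
    tree = read_newick("(A:1,B:2);")  # A-B path length 3
    rooted = midpoint_root(tree)
    depths = {l.taxon.label: l.edge.length for l in rooted.leaf_node_iter()}
    assert depths["A"] == pytest.approx(1.5)
    assert depths["B"] == pytest.approx(1.5)


def test_midpoint_quartet_hand_example():
    # B<->D path length 7; midpoint 0.5 from v into the v-D edge
    tree = nj_tree(QUARTET)
    rooted = midpoint_root(tree)
    assert max_root_depth(rooted) == pytest.approx(3.5)
    d_leaf = next(l for l in rooted.leaf_node_iter() if l.taxon.label == "D")
    assert d_leaf.edge.length == pytest.approx(3.5)
    assert d_leaf.parent_node is rooted.seed_node


def test_midpoint_exactly_on_a_node():
    tree = read_newick("((A:1,B:1):1,C:2);")
    rooted = midpoint_root(tree)
    # longest path A<->C = 4; midpoint on the internal node
    kids = {frozenset(l.taxon.label for l in c.leaf_iter())
            for c in rooted.seed_node.child_nodes()}
    assert frozenset({"A", "B"}) in kids or frozenset({"C"}) in kids
    assert max_root_depth(rooted) == pytest.approx(2.0)


def test_midpoint_all_zero_lengths_is_an_error():
    tree = read_newick("((A:0,B:0):0,C:0);")
    with pytest.raises(ValueError, match="zero"):
        midpoint_root(tree)


def test_midpoint_matches_brute_force_on_random_trees(rng):
    for _ in range(50):
        tree = random_tree(8, rng, rooted=False)
        rooted = midpoint_root(tree)
        assert splits_of(rooted) == splits_of(tree)
        assert max_root_depth(rooted) == pytest.approx(
            brute_force_min_max_depth(tree), abs=1e-9
        )


# ------------------------------------------------------------------ bootstrap

def _perfect_split_alignment(n_cols=100):
    return _aln([("A", "A" * n_cols), ("B", "A" * n_cols),
                 ("C", "T" * n_cols), ("D", "T" * n_cols)])


def test_bootstrap_unanimous_alignment_gives_full_support():
    tree, report = bootstrap_support(
        _perfect_split_alignment(), "p", BootstrapParams(n_replicates=50, seed=3)
    )
    supports = [n.support for n in tree_splits(tree)]
    assert supports and all(s == 1.0 for s in supports)
    assert report["dropped_replicates"] == 0


def test_bootstrap_single_replicate_support_is_binary(rng):
    tree = random_tree(6, rng)
    aln = _random_alignment(tree_labels(tree), 40, rng)
    out, _ = bootstrap_support(aln, "p", BootstrapParams(n_replicates=1, seed=1))
    for node in tree_splits(out):
        assert node.support in (0.0, 1.0)


def tree_labels(tree):
    return [l.taxon.label for l in tree.leaf_node_iter()]


def _random_alignment(labels, n_cols, rng):
    return _aln([
        (lb, "".join(rng.choice(list("ACDEFG"), size=n_cols))) for lb in labels
    ])


def test_bootstrap_is_deterministic_under_seed(rng):
    aln = _random_alignment([f"t{i}" for i in range(6)], 60, rng)
    runs = []
    for _ in range(2):
        tree, _ = bootstrap_support(aln, "p", BootstrapParams(100, seed=42))
        runs.append({split: node.support
                     for node, split in tree_splits(tree).items()})
    assert runs[0] == runs[1]


def test_bootstrap_supports_in_unit_interval_and_tip_order_invariant(rng):
    labels = [f"t{i}" for i in range(7)]
    cols = {lb: "".join(rng.choice(list("ACDEFG"), size=80)) for lb in labels}
    aln1 = _aln([(lb, cols[lb]) for lb in labels])
    aln2 = _aln([(lb, cols[lb]) for lb in reversed(labels)])
    out = []
    for aln in (aln1, aln2):
        tree, _ = bootstrap_support(aln, "p", BootstrapParams(50, seed=9))
        sup = {}
        for node, split in tree_splits(tree).items():
            assert 0.0 <= node.support <= 1.0
            sup[split] = node.support
        out.append(sup)
    assert out[0] == out[1]
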