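"""Distances, neighbor joining, bootstrap, group extraction."""

import io

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj as skbio_nj

from tlpkit.phylogeny import (
    Alignment, DistanceMatrix, bipartitions, bootstrap_support,
    distance_matrix, extract_groups, nj_tree,
)
from tlpkit.synthetic_data import evolve_alignment


def _random_additive_tree(n_taxa: int, rng: np.random.Generator) -> TreeNode:
    """A random binary tree with positive branch lengths (additive
    distances by construction)."""
    nodes = [TreeNode(name=chr(ord("A") + i),
                      length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.extend([a, b])
        nodes.append(parent)
    root = TreeNode()
    root.extend(nodes)
    return root


def _path_length_matrix(root: TreeNode) -> DistanceMatrix:
    taxa = sorted(t.name for t in root.tips())
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = root.find(taxa[i]).distance(
                root.find(taxa[j]))
    return DistanceMatrix(tuple(taxa), d)


def _tree_bipartitions(root: TreeNode) -> set:
    taxa = frozenset(t.name for t in root.tips())
    ref = min(taxa)
    out = set()
    for node in root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            out.add(side if ref not in side else taxa - side)
    return out


class TestDistanceMatrix:
    def test_identical_sequences_zero(self):
        aln = Alignment(("a", "b"), ("AAAA", "AAAA"))
        assert distance_matrix(aln, "p-distance")["a", "b"] == 0

    def test_half_mismatch_p_distance(self):
        aln = Alignment(("a", "b"), ("AAAA", "AATT"))
        assert distance_matrix(aln, "p-distance")["a", "b"] == 0.5

    def test_pairwise_deletion(self):
        # gap column dropped for the pair: 3 comparable sites, 1 mismatch
        aln = Alignment(("a", "b"), ("AA-A", "AGCA"))
        assert distance_matrix(aln, "p-distance")["a", "b"] == \
            pytest.approx(1 / 3)

    def test_poisson_correction_dominates_p_distance(self):
        rng = np.random.default_rng(0)
        rows = tuple("".join(rng.choice(list("ACDEFG"), size=50))
                     for _ in range(4))
        aln = Alignment(("a", "b", "c", "d"), rows)
        p = distance_matrix(aln, "p-distance").values
        poisson = distance_matrix(aln, "poisson").values
        assert (poisson >= p).all()

    def test_saturated_pair_rejected_under_poisson(self):
        aln = Alignment(("a", "b"), ("AAAA", "TTTT"))
        with pytest.raises(ValueError, match=r"\(a, b\)"):
            distance_matrix(aln, "poisson")

    def test_all_gap_pair_rejected(self):
        aln = Alignment(("a", "b", "c"), ("A--A", "-AA-", "AAAA"))
        with pytest.raises(ValueError, match="no comparable sites"):
            distance_matrix(aln, "p-distance")

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]], float))


class TestNjTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"),
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                                     float))
        tree = nj_tree(dm)
        assert tree.path_length("A", "B") == pytest.approx(2.0)
        root = tree.root
        lengths = {t.name: t.length for t in root.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"),
                                   np.array([[0, 1], [1, 0]], float)))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_exact_recovery_of_additive_trees(self, n_taxa):
        """NJ on an additive matrix reproduces the generating topology
        and its path lengths (four-point condition fixtures)."""
        for seed in range(3):
            rng = np.random.default_rng(100 * n_taxa + seed)
            true = _random_additive_tree(n_taxa, rng)
            dm = _path_length_matrix(true)
            est = nj_tree(dm)
            assert bipartitions(est) == _tree_bipartitions(true)
            for i, a in enumerate(dm.taxa):
                for b in dm.taxa[i + 1:]:
                    assert est.path_length(a, b) == pytest.approx(
                        dm[a, b], abs=1e-9)

    def test_equal_distance_matrix_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        taxa = tuple("ABCDE")
        first = nj_tree(DistanceMatrix(taxa, d)).to_newick()
        second = nj_tree(DistanceMatrix(taxa, d)).to_newick()
        assert first == second
        assert sorted(t.name for t in
                      nj_tree(DistanceMatrix(taxa, d)).root.tips()) == \
            list(taxa)

    def test_negative_branch_clamped(self):
        # a non-additive matrix that forces a negative NJ length estimate
        d = np.array([
            [0.0, 5.0, 9.0, 9.0],
            [5.0, 0.0, 9.0, 9.0],
            [9.0, 9.0, 0.0, 0.1],
            [9.0, 9.0, 0.1, 0.0]])
        tree = nj_tree(DistanceMatrix(tuple("ABCD"), d))
        for node in tree.root.traverse(include_self=False):
            assert node.length >= 0

    def test_agrees_with_skbio_on_random_matrix(self):
        """Cross-check topology against the scikit-bio NJ implementation
        on a generic (tie-free) random matrix."""
        rng = np.random.default_rng(42)
        n = 7
        base = rng.uniform(0.2, 2.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0)
        taxa = tuple(chr(ord("A") + i) for i in range(n))
        mine = nj_tree(DistanceMatrix(taxa, d))
        theirs = skbio_nj(SkbioDM(d, ids=list(taxa)))
        assert bipartitions(mine) == _tree_bipartitions(theirs)


@pytest.fixture(scope="module")
def six_taxon_alignment():
    newick = ("((A:0.1,B:0.1):0.15,(C:0.1,D:0.1):0.15,"
              "(E:0.1,F:0.1):0.15);")
    tree = TreeNode.read(io.StringIO(newick))
    return tree, evolve_alignment(tree, seq_length=500, seed=21)


class TestBootstrap:

    def test_uniform_signal_gets_full_support(self):
        # every column supports the same AB|CD split
        aln = Alignment(("A", "B", "C", "D"),
                        ("AAAA", "AAAA", "TTTT", "TTTT"))
        tree = bootstrap_support(aln, n_reps=50, seed=3, model="p-distance")
        assert set(tree.supports.values()) == {100.0}

    def test_same_seed_reproducible(self, six_taxon_alignment):
        _, aln = six_taxon_alignment
        t1 = bootstrap_support(aln, n_reps=30, seed=5)
        t2 = bootstrap_support(aln, n_reps=30, seed=5)
        assert t1.supports == t2.supports
        assert t1.to_newick() == t2.to_newick()

    def test_true_bipartitions_rank_highest(self, six_taxon_alignment):
        """On data evolved along a known tree the true bipartitions must
        receive the maximal support among observed bipartitions."""
        true_tree, aln = six_taxon_alignment
        est = bootstrap_support(aln, n_reps=100, seed=9)
        true_bps = _tree_bipartitions(true_tree)
        assert bipartitions(est) == true_bps
        assert min(est.supports.values()) > 60.0

    def test_supports_invariant_to_taxon_order(self, six_taxon_alignment):
        _, aln = six_taxon_alignment
        order = [3, 1, 5, 0, 4, 2]
        shuffled = Alignment(tuple(aln.names[i] for i in order),
                             tuple(aln.rows[i] for i in order))
        t1 = bootstrap_support(aln, n_reps=40, seed=11)
        t2 = bootstrap_support(shuffled, n_reps=40, seed=11)
        assert t1.supports == t2.supports


@pytest.fixture(scope="module")
def tree():
    dm = DistanceMatrix(
        tuple("ABCDEF"),
        np.array([
            [0.0, 0.2, 3.0, 3.0, 3.2, 3.2],
            [0.2, 0.0, 3.0, 3.0, 3.2, 3.2],
            [3.0, 3.0, 0.0, 0.2, 3.2, 3.2],
            [3.0, 3.0, 0.2, 0.0, 3.2, 3.2],
            [3.2, 3.2, 3.2, 3.2, 0.0, 0.2],
            [3.2, 3.2, 3.2, 3.2, 0.2, 0.0]]))
    return nj_tree(dm)


class TestExtractGroups:

    def test_k_one_single_group(self, tree):
        groups = extract_groups(tree, 1)
        assert set(groups.values()) == {1}

    def test_k_equals_leaves_singletons(self, tree):
        groups = extract_groups(tree, 6)
        assert sorted(groups.values()) == [1, 2, 3, 4, 5, 6]

    def test_every_taxon_assigned_once(self, tree):
        for k in range(1, 7):
            groups = extract_groups(tree, k)
            assert sorted(groups) == sorted(tree.taxa)
            assert set(groups.values()) == set(range(1, k + 1))

    def test_long_edge_separates_clades(self):
        # caterpillar with one long internal edge: cutting k=2 must
        # recover its two sides
        newick = "((A:0.1,B:0.1):2.0,(C:0.1,(D:0.1,E:0.1):0.1):0.1);"
        dm = _path_length_matrix(TreeNode.read(io.StringIO(newick)))
        tree = nj_tree(dm)
        groups = extract_groups(tree, 2)
        sides = {frozenset(t for t, g in groups.items() if g == v)
                 for v in set(groups.values())}
        assert sides == {frozenset("AB"), frozenset("CDE")}

    def test_k_out_of_range(self, tree):
        with pytest.raises(ValueError):
            extract_groups(tree, 0)
        with pytest.raises(ValueError):
            extract_groups(tree, 7)
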