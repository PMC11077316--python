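"""Alignment, distance, NJ and bootstrap tests.

NJ consistency is checked against randomly generated additive matrices
(Robinson-Foulds distance computed with dendropy as the independent oracle)
and against scikit-bio's own nj implementation.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np
import pytest
from skbio import TreeNode

from regenscreen.trees import (
    DISTANCE_CAP,
    Msa,
    TreeError,
    bootstrap_supports,
    distance_matrix,
    is_separated_cluster,
    neighbor_joining,
    progressive_align,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n))


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    taxa = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=str(t1), schema="newick", taxon_namespace=taxa)
    d2 = dendropy.Tree.get(data=str(t2), schema="newick", taxon_namespace=taxa)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


def random_additive_tree(rng, n_taxa: int) -> tuple[TreeNode, list[str], np.ndarray]:
    """Random binary topology with branch lengths in [0.1, 1]; returns the
    tree, taxa order, and the implied additive distance matrix."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=t) for t in taxa]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        nodes.append(TreeNode(children=[a, b]))
    for nd in nodes:
        nd.length = float(rng.uniform(0.1, 1.0))
    tree = TreeNode(children=nodes)
    dm = np.zeros((n_taxa, n_taxa))
    tip = {t.name: t for t in tree.tips()}
    for i, a in enumerate(taxa):
        for j in range(i + 1, n_taxa):
            d = tip[a].distance(tip[taxa[j]])
            dm[i, j] = dm[j, i] = d
    return tree, taxa, dm


class TestProgressiveAlign:
    def test_identical_sequences_gapless(self):
        msa = progressive_align([("a", "MKVLA"), ("b", "MKVLA")])
        assert msa.rows == ["MKVLA", "MKVLA"]

    def test_single_gap_opposite_missing_residue(self):
        msa = progressive_align([("a", "ACDE"), ("b", "ACE")])
        assert msa.rows[0] == "ACDE"
        assert msa.rows[1] == "AC-E"

    def test_single_sequence_trivial(self):
        msa = progressive_align([("a", "MKV")])
        assert msa.taxa == ["a"] and msa.rows == ["MKV"]

    def test_ungapping_round_trip(self):
        rng = np.random.default_rng(2)
        seqs = [(f"s{i}", random_protein(rng, int(rng.integers(20, 60))))
                for i in range(6)]
        msa = progressive_align(seqs)
        for (t, s), row in zip(seqs, msa.rows):
            assert row.replace("-", "") == s
        assert len({len(r) for r in msa.rows}) == 1

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        seqs = [(f"s{i}", random_protein(rng, 40)) for i in range(5)]
        assert progressive_align(seqs).rows == progressive_align(seqs).rows


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        msa = Msa(["a", "b"], ["MKVLA", "MKVLA"])
        assert distance_matrix(msa)[0, 1] == 0.0

    def test_p_distance_before_correction(self):
        # 1 mismatch over 10 comparable sites: p = 0.1
        msa = Msa(["a", "b"], ["AAAAAAAAAA", "AAAAAAAAAC"])
        d = distance_matrix(msa)[0, 1]
        p = 0.1
        expected = -19 / 20 * math.log(1 - 20 * p / 19)
        assert d == pytest.approx(expected)

    def test_gap_columns_excluded_pairwise(self):
        msa = Msa(["a", "b"], ["AA-AA", "AACAA"])  # 4 comparable, 0 diffs
        assert distance_matrix(msa)[0, 1] == 0.0

    def test_no_comparable_columns_capped_with_warning(self):
        msa = Msa(["a", "b"], ["AA--", "--AA"])
        with pytest.warns(UserWarning):
            d = distance_matrix(msa)
        assert d[0, 1] == DISTANCE_CAP

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(4)
        msa = progressive_align(
            [(f"s{i}", random_protein(rng, 30)) for i in range(5)]
        )
        d = distance_matrix(msa)
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)


class TestNeighborJoining:
    def test_four_taxon_additive_example(self):
        # additive for ((A:1,B:2):1,(C:3,D:4))
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = neighbor_joining(d, ["A", "B", "C", "D"])
        # topology AB|CD
        assert is_separated_cluster(tree, {"A", "B"})
        assert not is_separated_cluster(tree, {"A", "C"})
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        # internal edge length 1 (the single non-tip child of the root)
        internal = [n for n in tree.non_tips(include_self=False)]
        assert len(internal) == 1 and internal[0].length == pytest.approx(1.0)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = neighbor_joining(d, ["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["B"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["C"] == pytest.approx((6 + 8 - 4) / 2)

    def test_all_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(d, list("ABCD"))
        t2 = neighbor_joining(d, list("ABCD"))
        assert str(t1) == str(t2)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
        with pytest.raises(TreeError):
            neighbor_joining(d, list("ABC"))

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            true_tree, taxa, dm = random_additive_tree(rng, n)
            est = neighbor_joining(dm, taxa)
            assert rf_distance(true_tree, est) == 0

    def test_agrees_with_skbio_nj(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(23)
        for _ in range(5):
            n = int(rng.integers(5, 8))
            _, taxa, dm = random_additive_tree(rng, n)
            mine = neighbor_joining(dm, taxa)
            ref = skbio_nj(DistanceMatrix(dm, taxa))
            assert rf_distance(mine, ref) == 0


def two_clade_msa(n_per_clade=3, n_cols=200, n_info=20) -> Msa:
    """Zero-homoplasy alignment: two clades separated at most columns, with a
    few within-clade-informative columns so distances are nondegenerate."""
    rows = []
    taxa = []
    for c, base in ((0, "A"), (1, "C")):
        for i in range(n_per_clade):
            row = []
            for j in range(n_cols):
                if j < n_info:  # within-clade variation
                    row.append("ILMV"[(i + c * n_per_clade) % 4] if j % n_per_clade == i else base)
                else:
                    row.append(base)
            taxa.append(f"clade{c}_{i}")
            rows.append("".join(row))
    return Msa(taxa, rows)


class TestBootstrap:
    def test_separating_edge_full_support(self):
        msa = two_clade_msa()
        tree = bootstrap_supports(msa, n_replicates=100, seed=1)
        focal = {t for t in msa.taxa if t.startswith("clade0")}
        assert is_separated_cluster(tree, focal)
        # find the separating edge's support
        from regenscreen.trees import _bipartitions

        leaves = frozenset(msa.taxa)
        ref = min(leaves)
        key = frozenset(focal) if ref not in focal else leaves - frozenset(focal)
        node = _bipartitions(tree)[key]
        assert node.support == 100.0

    def test_single_replicate_supports_binary(self):
        msa = two_clade_msa()
        tree = bootstrap_supports(msa, n_replicates=1, seed=3)
        sups = {n.support for n in tree.non_tips(include_self=False)
                if hasattr(n, "support")}
        assert sups <= {0.0, 100.0}

    def test_seed_reproducible(self):
        msa = two_clade_msa()
        t1 = bootstrap_supports(msa, n_replicates=25, seed=9)
        t2 = bootstrap_supports(msa, n_replicates=25, seed=9)
        assert str(t1) == str(t2)

    def test_supports_in_range(self):
        rng = np.random.default_rng(31)
        msa = progressive_align(
            [(f"s{i}", random_protein(rng, 60)) for i in range(5)]
        )
        tree = bootstrap_supports(msa, n_replicates=20, seed=0)
        for n in tree.non_tips(include_self=False):
            assert 0.0 <= n.support <= 100.0


class TestIsSeparatedCluster:
    def tree(self):
        return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])

    def test_clade_detected(self):
        assert is_separated_cluster(self.tree(), {"A", "B"})
        assert is_separated_cluster(self.tree(), {"C", "D"})

    def test_non_clade_rejected(self):
        assert not is_separated_cluster(self.tree(), {"A", "C"})

    def test_degenerate_focal_sets_rejected(self):
        with pytest.raises(TreeError):
            is_separated_cluster(self.tree(), set())
        with pytest.raises(TreeError):
            is_separated_cluster(self.tree(), {"A", "B", "C", "D"})

    def test_synthetic_family_orthologs_separate_from_paralogs(self, small_scenario,
                                                               scheme):
        # a planted paralog family: high-regenerative orthologs vs the
        # diverged copies carried by the low-regenerative species
        proteomes, truth = small_scenario
        fam = sorted(truth.paralog_family_ids)[0]
        seqs, focal = [], set()
        for sp, prot in sorted(proteomes.items()):
            for gene in (fam, f"{fam}_par"):
                if gene in prot.records:
                    seqs.append((f"{sp}|{gene}", prot.records[gene][0][1]))
                    if gene == fam:
                        focal.add(f"{sp}|{gene}")
        assert len(seqs) - len(focal) >= 2  # paralog side forms a clade
        msa = progressive_align(seqs, scheme)
        tree = neighbor_joining(distance_matrix(msa), msa.taxa)
        assert is_separated_cluster(tree, focal)
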