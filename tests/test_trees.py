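"""Neighbor joining, bootstrap support, bipartitions, newick round-trips."""

import numpy as np
import pytest

import coikit as ck
from coikit.distances import DistanceMatrix
from coikit.seqio import Alignment
from coikit.trees import (
    bipartitions,
    bootstrap_support,
    neighbor_joining,
    read_newick,
    split_support_map,
    write_newick,
)

from helpers import (
    make_record,
    newick_path_distances,
    random_binary_tree,
    tree_splits_via_edge_removal,
)


def dm(labels, arr, model="k2p"):
    return DistanceMatrix(labels, np.asarray(arr, dtype=float), model)


class TestNeighborJoining:
    def test_three_taxon_branch_lengths_exact(self):
        # three-point formulas: a=(dAB+dAC-dBC)/2 etc.
        tree = neighbor_joining(dm(["A", "B", "C"], [[0, 2, 3], [2, 0, 4], [3, 4, 0]]))
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((A:1,B:1):1,(C:1,D:1)) -> split {A,B}|{C,D}, internal branch 1
        d = [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]]
        tree = neighbor_joining(dm(list("ABCD"), d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        internal = [
            n.edge.length
            for n in tree.preorder_node_iter()
            if not n.is_leaf() and n is not tree.seed_node
        ]
        assert internal == pytest.approx([1.0])

    def test_zero_matrix_deterministic(self):
        t1 = neighbor_joining(dm(list("ABCDE"), np.zeros((5, 5))))
        t2 = neighbor_joining(dm(list("ABCDE"), np.zeros((5, 5))))
        assert all(
            (n.edge.length or 0) == 0
            for n in t1.preorder_node_iter()
            if n.parent_node is not None
        )
        assert bipartitions(t1) == bipartitions(t2)

    def test_undefined_entry_errors(self):
        d = [[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]]
        with pytest.raises(ValueError, match="undefined"):
            neighbor_joining(dm(list("ABC"), d))

    def test_fewer_than_three_taxa_errors(self):
        with pytest.raises(ValueError):
            neighbor_joining(dm(["A", "B"], [[0, 1], [1, 0]]))

    def test_nj_consistency_on_random_additive_matrices(self):
        """Recovers the generating bipartition set for additive distances
        (trees of 5-10 leaves, branch lengths U(0.05, 1))."""
        rng = np.random.default_rng(2024)
        for trial in range(30):
            n = int(rng.integers(5, 11))
            newick, labels = random_binary_tree(n, rng)
            d = newick_path_distances(newick, labels)
            tree = neighbor_joining(dm(labels, d))
            generating = tree_splits_via_edge_removal(read_tree(newick))
            assert bipartitions(tree) == generating, f"trial {trial}"

    def test_matches_scikit_bio_on_additive_matrices(self):
        """Independent cross-check: same topology as skbio's NJ."""
        import skbio

        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            newick, labels = random_binary_tree(n, rng)
            d = newick_path_distances(newick, labels)
            mine = bipartitions(neighbor_joining(dm(labels, d)))
            sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
            theirs = _skbio_splits(sk_tree, labels)
            assert mine == theirs

    def test_leaf_order_invariance(self, small_analysis):
        matrix = small_analysis["dm_k2p"]
        rng = np.random.default_rng(5)
        perm = list(rng.permutation(len(matrix.labels)))
        labels = [matrix.labels[i] for i in perm]
        shuffled = dm(labels, matrix.as_array()[np.ix_(perm, perm)])
        assert bipartitions(neighbor_joining(shuffled)) == bipartitions(
            neighbor_joining(matrix)
        )


def read_tree(newick: str):
    import dendropy

    return dendropy.Tree.get(data=newick, schema="newick")


def _skbio_splits(sk_tree, labels):
    anchor, n = min(labels), len(labels)
    full = frozenset(labels)
    splits = set()
    for node in sk_tree.traverse(include_self=False):
        if node.is_tip():
            continue
        below = frozenset(t.name for t in node.tips())
        side = full - below if anchor in below else below
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


class TestBipartitions:
    def test_four_leaf_tree_single_split(self):
        tree = read_tree("((A:1,B:1):1,(C:1,D:1):1);")
        assert len(bipartitions(tree)) == 1

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_binary_tree_has_n_minus_3_splits(self, n):
        rng = np.random.default_rng(n)
        newick, _ = random_binary_tree(n, rng)
        assert len(bipartitions(read_tree(newick))) == n - 3

    def test_agrees_with_edge_removal_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            newick, _ = random_binary_tree(n, rng)
            tree = read_tree(newick)
            assert bipartitions(tree) == tree_splits_via_edge_removal(tree)


class TestNewickIO:
    def test_round_trip_topology_lengths_supports(self, small_analysis, tmp_path):
        annotated = small_analysis["annotated"]
        write_newick(annotated, tmp_path / "t.nwk")
        back = read_newick(tmp_path / "t.nwk")
        assert bipartitions(back) == bipartitions(annotated)
        orig = split_support_map(annotated)
        reread = split_support_map(back)
        assert set(reread) == set(orig)
        for split, support in orig.items():
            assert reread[split] == pytest.approx(support, abs=1e-9)
        orig_lengths = sorted(
            n.edge.length for n in annotated.preorder_node_iter() if n.parent_node
        )
        back_lengths = sorted(
            n.edge.length for n in back.preorder_node_iter() if n.parent_node
        )
        assert back_lengths == pytest.approx(orig_lengths, abs=1e-9)

    def test_fifty_leaf_round_trip(self, tmp_path):
        rng = np.random.default_rng(50)
        newick, _ = random_binary_tree(50, rng)
        tree = read_tree(newick)
        write_newick(tree, tmp_path / "big.nwk")
        assert bipartitions(read_newick(tmp_path / "big.nwk")) == bipartitions(tree)

    def test_empty_file_errors(self, tmp_path):
        (tmp_path / "empty.nwk").write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_newick(tmp_path / "empty.nwk")

    def test_malformed_newick_errors(self, tmp_path):
        (tmp_path / "bad.nwk").write_text("((A:1,B:1;")
        with pytest.raises(ValueError, match="malformed"):
            read_newick(tmp_path / "bad.nwk")


class TestBootstrap:
    def _twin_alignment(self):
        rng = np.random.default_rng(0)
        base = "".join(rng.choice(list("ACGT"), 300))
        # outgroups form a chain of mutations so distances stay tree-like
        out1 = _mutate(base, 0.15, 1)
        out2 = _mutate(out1, 0.10, 2)
        out3 = _mutate(out2, 0.10, 3)
        recs = [
            make_record(id="twin1", seq=base, species="S a"),
            make_record(id="twin2", seq=base, species="S b"),
            make_record(id="out1", seq=out1),
            make_record(id="out2", seq=out2),
            make_record(id="out3", seq=out3),
        ]
        return Alignment(recs)

    def test_identical_twins_get_support_100(self):
        aln = self._twin_alignment()
        matrix = ck.distance_matrix(aln, model="k2p")
        tree = neighbor_joining(matrix)
        annotated, support, dropped = bootstrap_support(aln, "k2p", tree, 50, 11)
        assert support[frozenset({"twin1", "twin2"})] == 100.0
        assert dropped == 0

    def test_same_seed_identical_supports(self, small_dataset):
        alignment, _ = small_dataset
        matrix = ck.distance_matrix(alignment, model="k2p")
        tree = neighbor_joining(matrix)
        _, s1, _ = bootstrap_support(alignment, "k2p", tree, 20, 77)
        _, s2, _ = bootstrap_support(alignment, "k2p", tree, 20, 77)
        assert s1 == s2

    def test_supports_in_range(self, small_analysis):
        values = list(small_analysis["support"].values())
        assert values and all(0.0 <= v <= 100.0 for v in values)

    def test_zero_replicates_errors(self, small_analysis):
        with pytest.raises(ValueError):
            bootstrap_support(
                small_analysis["alignment"], "k2p", small_analysis["tree"], 0, 1
            )

    def test_long_internal_branch_support_saturates(self):
        """Two well-separated clades on a long internal branch approach
        support 100 for long alignments (length 5000, 200 replicates)."""
        cfg = ck.SimConfig(
            n_families=2, genera_per_family=1, species_per_genus=3,
            samples_per_species=1, seq_length=5000, seed=4,
        )
        aln, _ = ck.simulate_dataset(cfg)
        matrix = ck.distance_matrix(aln, model="k2p")
        tree = neighbor_joining(matrix)
        annotated, support, _ = bootstrap_support(aln, "k2p", tree, 200, 21)
        fam1 = frozenset(r.id for r in aln.records if r.family == "Family01")
        mono, s = ck.group_monophyly(annotated, fam1)
        assert mono and s >= 99.0


def _mutate(seq: str, rate: float, seed: int) -> str:
    rng = np.random.default_rng(seed)
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        else:
            out.append(c)
    return "".join(out)
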