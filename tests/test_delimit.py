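"""Sister pairs, family thresholds and candidate-species delimitation."""

import math

import numpy as np
import pytest

import coikit as ck
from coikit.delimit import (
    CandidateLineage,
    build_threshold_table,
    candidate_count,
    cluster_unidentified,
    find_sister_pairs,
    mean_interspecific_divergence,
    reference_records,
)
from coikit.distances import DistanceMatrix
from coikit.seqio import Alignment, Status
from coikit.trees import neighbor_joining

from helpers import make_record


def matrix_from(labels, arr, model="k2p"):
    return DistanceMatrix(labels, np.asarray(arr, dtype=float), model)


def toy_alignment(statuses=None):
    """Four single-record species in one family plus an optional query."""
    records = [
        make_record(id="a", seq="ACGTAC", species="G alpha", family="F1"),
        make_record(id="b", seq="ACGTAT", species="G beta", family="F1"),
        make_record(id="c", seq="ACGAAC", species="G gamma", family="F1"),
        make_record(id="d", seq="AGGTAC", species="G delta", family="F1"),
    ]
    if statuses:
        from dataclasses import replace

        records += [
            replace(make_record(id=i, seq="TTTTTT", species=f"G sp. {i}",
                                family="F1"), status=s)
            for i, s in statuses.items()
        ]
    return Alignment(records)


class TestMeanDivergence:
    def test_two_species_family_mean_is_their_distance(self):
        aln = Alignment(
            [
                make_record(id="a", species="G a", family="F"),
                make_record(id="b", species="G b", family="F"),
            ]
        )
        m = matrix_from(["a", "b"], [[0, 0.10], [0.10, 0]])
        assert mean_interspecific_divergence(aln, m, "F") == pytest.approx(0.10)

    def test_three_species_arithmetic_mean(self):
        aln = Alignment(
            [
                make_record(id="a", species="G a", family="F"),
                make_record(id="b", species="G b", family="F"),
                make_record(id="c", species="G c", family="F"),
            ]
        )
        m = matrix_from(list("abc"), [[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        assert mean_interspecific_divergence(aln, m, "F") == pytest.approx(0.2)

    def test_one_record_per_species_and_nominal_only(self):
        from dataclasses import replace

        recs = [
            make_record(id="a1", species="G a", family="F"),
            make_record(id="a2", species="G a", family="F"),  # duplicate species
            make_record(id="b", species="G b", family="F"),
            replace(make_record(id="q", species="G sp.", family="F"),
                    status=Status.CANDIDATE),
        ]
        refs = reference_records(Alignment(recs), "F")
        assert [r.id for r in refs] == ["a1", "b"]

    def test_matches_brute_force_on_synthetic_family(self, small_analysis):
        alignment = small_analysis["alignment"]
        matrix = small_analysis["dm_k2p"]
        family = alignment.records[0].family
        refs = reference_records(alignment, family)
        expected = np.mean(
            [
                matrix.get(refs[i].id, refs[j].id)
                for i in range(len(refs))
                for j in range(i + 1, len(refs))
            ]
        )
        got = mean_interspecific_divergence(alignment, matrix, family)
        assert got == pytest.approx(expected)

    def test_single_species_family_errors(self):
        aln = Alignment([make_record(id="a", species="G a", family="F")])
        with pytest.raises(ValueError):
            mean_interspecific_divergence(aln, matrix_from(["a"], [[0]]), "F")


class TestSisterPairs:
    def _tree_with_support(self, aln, matrix, supports):
        tree = neighbor_joining(matrix)
        from coikit.trees import _split_nodes

        for split, node in _split_nodes(tree).items():
            node.support = supports.get(split, 50.0)
        return tree

    def test_support_cutoff_strict(self):
        aln = toy_alignment()
        d = [
            [0, 0.05, 0.30, 0.30],
            [0.05, 0, 0.30, 0.30],
            [0.30, 0.30, 0, 0.08],
            [0.30, 0.30, 0.08, 0],
        ]
        k2p = matrix_from(list("abcd"), d)
        p = matrix_from(list("abcd"), d, model="p")
        # the NJ tree pairs (a,b) and (c,d); give them supports 95 and 65
        tree = self._tree_with_support(
            aln, k2p, {frozenset({"c", "d"}): 95.0}
        )
        # canonical split of cherry (a,b) is its complement {c,d}; to set
        # distinct supports use group identity: {c,d} edge == {a,b} edge here
        pairs = find_sister_pairs(tree, aln, k2p, p, min_support=70)
        assert {(p_.species_a, p_.species_b) for p_ in pairs} <= {
            ("G alpha", "G beta"), ("G gamma", "G delta")
        }
        for pair in pairs:
            assert pair.support > 70

    def test_cherry_with_non_nominal_record_excluded(self):
        aln = toy_alignment({"q": Status.UNIDENTIFIED})
        labels = ["a", "b", "c", "d", "q"]
        d = np.full((5, 5), 0.30)
        np.fill_diagonal(d, 0.0)
        d[0, 4] = d[4, 0] = 0.01  # query pairs with species a
        d[1, 2] = d[2, 1] = 0.05
        k2p = matrix_from(labels, d)
        tree = neighbor_joining(k2p)
        from coikit.trees import _split_nodes

        for node in _split_nodes(tree).values():
            node.support = 99.0
        pairs = find_sister_pairs(tree, aln, k2p, matrix_from(labels, d, "p"), 70)
        species_in_pairs = {s for p_ in pairs for s in (p_.species_a, p_.species_b)}
        assert "G sp. q" not in species_in_pairs

    def test_raising_min_support_never_adds_pairs(self, small_analysis):
        aln = small_analysis["alignment"]
        args = (small_analysis["annotated"], aln, small_analysis["dm_k2p"],
                small_analysis["dm_p"])
        n_pairs = [len(find_sister_pairs(*args, min_support=s)) for s in (0, 50, 70, 90)]
        assert n_pairs == sorted(n_pairs, reverse=True)


class TestThresholdTable:
    def _pair(self, family, k2p, p=None):
        from coikit.delimit import SisterPair

        return SisterPair("s1", "s2", family, 95.0, k2p, p if p is not None else k2p)

    def test_single_pair_threshold_is_its_distance(self):
        table = build_threshold_table([self._pair("Boidae-like", 0.066, 0.062)])
        assert table.threshold("Boidae-like", "k2p") == pytest.approx(0.066)
        assert table.threshold("Boidae-like", "p") == pytest.approx(0.062)
        assert table.n_pairs("Boidae-like") == 1

    def test_mean_of_two_pairs(self):
        table = build_threshold_table([self._pair("F", 0.04), self._pair("F", 0.06)])
        assert table.threshold("F", "k2p") == pytest.approx(0.05)

    def test_empty_pair_list_empty_table(self):
        table = build_threshold_table([])
        assert table.families() == []
        assert table.threshold("F", "k2p") is None


class TestClusterUnidentified:
    def _setup(self, query_distances, threshold=0.10):
        """One nominal species 'a' plus unidentified queries at given
        distances from it (queries mutually distant unless stated)."""
        from dataclasses import replace

        labels = ["a"] + list(query_distances)
        n = len(labels)
        d = np.full((n, n), 0.5)
        np.fill_diagonal(d, 0.0)
        for k, (q, dist) in enumerate(query_distances.items(), start=1):
            d[0, k] = d[k, 0] = dist
        recs = [make_record(id="a", species="G a", family="F")]
        recs += [
            replace(make_record(id=q, species=f"G sp. {q}", family="F"),
                    status=Status.UNIDENTIFIED)
            for q in query_distances
        ]
        table = ck.ThresholdTable({"F": (threshold, threshold, 1)})
        return Alignment(recs), matrix_from(labels, d), table, d

    def test_distant_query_flagged(self):
        aln, m, table, _ = self._setup({"q1": 0.20})
        lineages, unresolved = cluster_unidentified(m, aln, table)
        assert unresolved == []
        assert len(lineages) == 1 and lineages[0].flagged
        assert lineages[0].nn_distance == pytest.approx(0.20)

    def test_close_query_not_flagged(self):
        aln, m, table, _ = self._setup({"q1": 0.05})
        (lineage,), _ = cluster_unidentified(m, aln, table)
        assert not lineage.flagged

    def test_mutually_close_queries_merge_into_one_lineage(self):
        aln, m, table, d = self._setup({"q1": 0.30, "q2": 0.30})
        d[1, 2] = d[2, 1] = 0.05  # below threshold -> single linkage merges
        lineages, _ = cluster_unidentified(matrix_from(["a", "q1", "q2"], d), aln, table)
        assert len(lineages) == 1
        assert lineages[0].members == ("q1", "q2") and lineages[0].flagged

    def test_single_linkage_chain_matches_exhaustive_merge(self):
        # chain q1-q2-q3 linked pairwise below threshold merges transitively
        aln, m, table, d = self._setup({"q1": 0.30, "q2": 0.30, "q3": 0.30})
        d[1, 2] = d[2, 1] = 0.05
        d[2, 3] = d[3, 2] = 0.05
        d[1, 3] = d[3, 1] = 0.15  # above threshold but same chain
        lineages, _ = cluster_unidentified(
            matrix_from(["a", "q1", "q2", "q3"], d), aln, table
        )
        assert len(lineages) == 1 and set(lineages[0].members) == {"q1", "q2", "q3"}

    def test_family_without_threshold_reported_unresolved(self):
        aln, m, _, _ = self._setup({"q1": 0.20})
        empty = ck.ThresholdTable({})
        lineages, unresolved = cluster_unidentified(m, aln, empty)
        assert lineages == [] and unresolved == ["q1"]

    def test_lowering_threshold_never_reduces_flags(self):
        aln, m, _, _ = self._setup({"q1": 0.20, "q2": 0.08})
        flags = []
        for thr in (0.30, 0.15, 0.05):
            table = ck.ThresholdTable({"F": (thr, thr, 1)})
            lineages, _ = cluster_unidentified(m, aln, table)
            flags.append(sum(l.flagged for l in lineages))
        assert flags == sorted(flags)


class TestCandidateCount:
    def _lineage(self, members, model, flagged, family="F"):
        return CandidateLineage(
            members=tuple(members), family=family, nearest_nominal="a",
            nn_distance=0.2, threshold_used=0.1, flagged=flagged, model=model,
        )

    def test_agreement_gives_min_equals_max(self):
        k2p = [self._lineage(["q1"], "k2p", True)]
        p = [self._lineage(["q1"], "p", True)]
        assert candidate_count(k2p, p)[:2] == (1, 1)

    def test_model_disagreement_contributes_to_max_only(self):
        k2p = [self._lineage(["q1"], "k2p", True)]
        p = [self._lineage(["q1"], "p", False)]
        cmin, cmax, per_family = candidate_count(k2p, p)
        assert (cmin, cmax) == (0, 1)
        assert per_family["F"] == (0, 1)

    def test_min_never_exceeds_max(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            k2p = [
                self._lineage([f"q{i}"], "k2p", bool(rng.integers(2)))
                for i in range(5)
            ]
            p = [
                self._lineage([f"q{i}"], "p", bool(rng.integers(2)))
                for i in range(5)
            ]
            cmin, cmax, _ = candidate_count(k2p, p)
            assert cmin <= cmax

    def test_different_groupings_matched_by_member_overlap(self):
        # k2p merges q1+q2; p keeps them separate but flags both
        k2p = [self._lineage(["q1", "q2"], "k2p", True)]
        p = [self._lineage(["q1"], "p", True), self._lineage(["q2"], "p", True)]
        assert candidate_count(k2p, p)[:2] == (1, 1)
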