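"""Threshold-based candidate-species delimitation.

The procedure mirrors standard distance-threshold barcoding practice:

1. find well-supported sister-species pairs — two nominal species of the same
   family forming a two-leaf cherry with bootstrap support above a cutoff
   (default 70);
2. average the pairwise distances of those pairs per family, giving a
   family-specific divergence threshold (computed for K2p and p separately);
3. group candidate/unidentified records of each family into lineages by
   single-linkage at distances below the family threshold;
4. flag a lineage as a candidate species iff its minimum distance to any
   nominal-species record exceeds the threshold.

Running step 3-4 under the K2p and p thresholds separately yields a
min-max candidate count (flagged under both models vs under at least one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .seqio import Alignment, SequenceRecord, Status
from .trees import split_support_map

__all__ = [
    "SisterPair",
    "ThresholdTable",
    "CandidateLineage",
    "mean_interspecific_divergence",
    "reference_records",
    "find_sister_pairs",
    "build_threshold_table",
    "cluster_unidentified",
    "candidate_count",
]

DEFAULT_MIN_SUPPORT = 70.0  # sister pairs must exceed this bootstrap value


@dataclass(frozen=True)
class SisterPair:
    species_a: str
    species_b: str
    family: str
    support: float
    distance_k2p: float
    distance_p: float

    def distance(self, model: str) -> float:
        return self.distance_k2p if model == "k2p" else self.distance_p


@dataclass(frozen=True)
class ThresholdTable:
    """family -> (threshold_k2p, threshold_p, n_pairs)."""

    entries: dict[str, tuple[float, float, int]]

    def families(self) -> list[str]:
        return sorted(self.entries)

    def threshold(self, family: str, model: str) -> float | None:
        if family not in self.entries:
            return None
        k2p, p, _ = self.entries[family]
        return k2p if model == "k2p" else p

    def n_pairs(self, family: str) -> int:
        return self.entries[family][2] if family in self.entries else 0


@dataclass(frozen=True)
class CandidateLineage:
    members: tuple[str, ...]
    family: str
    nearest_nominal: str
    nn_distance: float
    threshold_used: float
    flagged: bool
    model: str


def reference_records(alignment: Alignment, family: str | None = None) -> list[SequenceRecord]:
    """One reference record per nominal species (first by input order)."""
    seen: set[str] = set()
    out = []
    for r in alignment.records:
        if r.status is not Status.NOMINAL:
            continue
        if family is not None and r.family != family:
            continue
        if r.species in seen:
            continue
        seen.add(r.species)
        out.append(r)
    return out


def mean_interspecific_divergence(
    alignment: Alignment, matrix: DistanceMatrix, family: str
) -> float:
    """Unweighted mean distance over between-species reference pairs of a family.

    Undefined (NaN) pairs are excluded. Requires at least 2 nominal species.
    """
    refs = reference_records(alignment, family)
    if len(refs) < 2:
        raise ValueError(f"family {family!r}: need >= 2 nominal reference species")
    values = []
    for i in range(len(refs) - 1):
        for j in range(i + 1, len(refs)):
            d = matrix.get(refs[i].id, refs[j].id)
            if not math.isnan(d):
                values.append(d)
    if not values:
        raise ValueError(f"family {family!r}: all pairwise distances undefined")
    return float(np.mean(values))


def find_sister_pairs(
    tree: dendropy.Tree,
    alignment: Alignment,
    matrix_k2p: DistanceMatrix,
    matrix_p: DistanceMatrix,
    min_support: float = DEFAULT_MIN_SUPPORT,
) -> list[SisterPair]:
    """Well-supported congeneric-family cherries between two nominal species.

    A pair qualifies iff its two leaves form a two-leaf bipartition (cherry)
    with bootstrap support strictly above ``min_support``, and both records
    are nominal species of the same family (different species).
    """
    by_id = {r.id: r for r in alignment.records}
    all_leaves = frozenset(by_id) & frozenset(
        leaf.taxon.label for leaf in tree.leaf_node_iter()
    )
    # a split may represent a cherry on either side (the canonical side is
    # the one excluding the smallest label), so check both
    cherries: list[tuple[frozenset, float | None]] = []
    for split, support in split_support_map(tree).items():
        if len(split) == 2:
            cherries.append((split, support))
        complement = all_leaves - split
        if len(complement) == 2:
            cherries.append((complement, support))
    pairs = []
    for split, support in sorted(cherries, key=lambda kv: sorted(kv[0])):
        if support is None or support <= min_support:
            continue
        id_a, id_b = sorted(split)
        ra, rb = by_id.get(id_a), by_id.get(id_b)
        if ra is None or rb is None:
            continue
        if ra.status is not Status.NOMINAL or rb.status is not Status.NOMINAL:
            continue
        if ra.family != rb.family or ra.species == rb.species:
            continue
        pairs.append(
            SisterPair(
                species_a=ra.species,
                species_b=rb.species,
                family=ra.family,
                support=support,
                distance_k2p=matrix_k2p.get(id_a, id_b),
                distance_p=matrix_p.get(id_a, id_b),
            )
        )
    return pairs


def build_threshold_table(pairs: list[SisterPair]) -> ThresholdTable:
    """Per-family arithmetic mean of sister-pair distances (K2p and p)."""
    by_family: dict[str, list[SisterPair]] = {}
    for pair in pairs:
        by_family.setdefault(pair.family, []).append(pair)
    entries = {}
    for family, fam_pairs in by_family.items():
        k2p = [p.distance_k2p for p in fam_pairs if not math.isnan(p.distance_k2p)]
        pd_ = [p.distance_p for p in fam_pairs if not math.isnan(p.distance_p)]
        if not k2p or not pd_:
            continue
        entries[family] = (float(np.mean(k2p)), float(np.mean(pd_)), len(fam_pairs))
    return ThresholdTable(entries)


def _single_linkage(ids: list[str], dist, cutoff: float) -> list[list[str]]:
    """Single-linkage components at distance < cutoff (exhaustive merge)."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = dist(a, b)
            if not math.isnan(d) and d < cutoff:
                parent[find(a)] = find(b)
    comps: dict[str, list[str]] = {}
    for i in ids:
        comps.setdefault(find(i), []).append(i)
    return [sorted(c) for c in comps.values()]


def cluster_unidentified(
    matrix: DistanceMatrix,
    alignment: Alignment,
    thresholds: ThresholdTable,
) -> tuple[list[CandidateLineage], list[str]]:
    """Group candidate/unidentified records into lineages and flag candidates.

    Records of a family are merged by single-linkage at distances below that
    family's threshold (for the matrix's model). Each lineage's nearest-
    neighbour distance is the minimum distance from any member to any
    nominal-species record in the whole dataset; the lineage is flagged iff
    that distance exceeds the threshold. Records in families without a
    threshold are returned in the unresolved list.
    """
    model = matrix.model
    nominal_ids = [r.id for r in alignment.records if r.status is Status.NOMINAL]
    query = [r for r in alignment.records if r.status is not Status.NOMINAL]
    lineages: list[CandidateLineage] = []
    unresolved: list[str] = []
    by_family: dict[str, list[SequenceRecord]] = {}
    for r in query:
        by_family.setdefault(r.family, []).append(r)
    for family in sorted(by_family):
        threshold = thresholds.threshold(family, model)
        if threshold is None:
            unresolved.extend(r.id for r in by_family[family])
            continue
        ids = [r.id for r in by_family[family]]
        for members in _single_linkage(ids, matrix.get, threshold):
            nn_id, nn_d = None, math.inf
            for m in members:
                for nom in nominal_ids:
                    d = matrix.get(m, nom)
                    if not math.isnan(d) and d < nn_d:
                        nn_id, nn_d = nom, d
            if nn_id is None:
                unresolved.extend(members)
                continue
            lineages.append(
                CandidateLineage(
                    members=tuple(members),
                    family=family,
                    nearest_nominal=nn_id,
                    nn_distance=nn_d,
                    threshold_used=threshold,
                    flagged=nn_d > threshold,
                    model=model,
                )
            )
    return lineages, unresolved


def candidate_count(
    lineages_k2p: list[CandidateLineage],
    lineages_p: list[CandidateLineage],
) -> tuple[int, int, dict[str, tuple[int, int]]]:
    """Min-max candidate-species count across the two distance models.

    Lineages from the two runs are matched by shared member records
    (connected components over member overlap). A component counts toward the
    minimum iff it is flagged under both models, and toward the maximum iff
    it is flagged under at least one. Returns
    ``(min_count, max_count, per_family {family: (min, max)})``.
    """
    all_lineages = list(lineages_k2p) + list(lineages_p)
    parent: dict[str, str] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for lin in all_lineages:
        for m in lin.members:
            parent.setdefault(m, m)
        first = lin.members[0]
        for m in lin.members[1:]:
            parent[find(m)] = find(first)

    comps: dict[str, list[CandidateLineage]] = {}
    for lin in all_lineages:
        comps.setdefault(find(lin.members[0]), []).append(lin)

    min_count = max_count = 0
    per_family: dict[str, tuple[int, int]] = {}
    for lins in comps.values():
        flag_k2p = any(l.flagged for l in lins if l.model == "k2p")
        flag_p = any(l.flagged for l in lins if l.model == "p")
        family = lins[0].family
        fam_min, fam_max = per_family.get(family, (0, 0))
        if flag_k2p and flag_p:
            min_count += 1
            fam_min += 1
        if flag_k2p or flag_p:
            max_count += 1
            fam_max += 1
        per_family[family] = (fam_min, fam_max)
    return min_count, max_count, per_family
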