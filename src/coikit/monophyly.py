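"""Monophyly and bootstrap support of named groups (genera, families).

On an unrooted tree a group is scored monophyletic iff its leaf set forms one
side of some bipartition (the convexity criterion). This is equivalent to
rooted monophyly for any root placed outside the group, and is invariant to
rerooting. Groups represented by a single leaf carry no topological signal
and are excluded from scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .trees import _leaf_labels, _split_nodes

__all__ = [
    "GroupScore",
    "group_monophyly",
    "score_all_groups",
    "summarize_scores",
    "reference_genus_check",
]

DEFAULT_HIGH_SUPPORT = 90.0  # "well supported" cutoff for bootstrap values

LEVEL_INDEX = {"species": 0, "genus": 1, "family": 2}


@dataclass(frozen=True)
class GroupScore:
    group: str
    level: str
    n_members: int
    monophyletic: bool | None  # None when excluded
    support: float | None  # present only for monophyletic groups on internal edges
    excluded: bool


def group_monophyly(
    tree: dendropy.Tree, leafset: set[str]
) -> tuple[bool, float | None]:
    """Is ``leafset`` one side of a bipartition, and with what support?

    Returns ``(monophyletic, support)``; support is None when the group spans
    the whole tree, sits on a pendant edge (complement of a single leaf), or
    the tree carries no bootstrap annotation.
    """
    leaves = set(_leaf_labels(tree))
    leafset = set(leafset)
    if not leafset <= leaves:
        raise ValueError(f"leafset not a subset of tree leaves: {sorted(leafset - leaves)}")
    if len(leafset) < 2:
        raise ValueError("leafset must contain at least 2 leaves")
    if leafset == leaves:
        return True, None  # whole tree: monophyletic by convention
    if len(leafset) == len(leaves) - 1:
        return True, None  # complement is a single leaf: trivial split
    anchor = min(leaves)
    side = frozenset(leaves - leafset) if anchor in leafset else frozenset(leafset)
    split_nodes = _split_nodes(tree)
    node = split_nodes.get(side)
    if node is None:
        return False, None
    return True, getattr(node, "support", None)


def score_all_groups(
    tree: dendropy.Tree,
    taxonomy: dict[str, tuple[str, str, str]],
    level: str,
) -> list[GroupScore]:
    """Score every group at ``level`` ('species', 'genus' or 'family')."""
    idx = LEVEL_INDEX[level]
    leaves = _leaf_labels(tree)
    groups: dict[str, set[str]] = {}
    for leaf in leaves:
        if leaf not in taxonomy:
            raise KeyError(f"leaf {leaf!r} missing from taxonomy")
        groups.setdefault(taxonomy[leaf][idx], set()).add(leaf)
    scores = []
    for name in sorted(groups):
        members = groups[name]
        if len(members) < 2:
            scores.append(GroupScore(name, level, len(members), None, None, True))
            continue
        mono, support = group_monophyly(tree, members)
        scores.append(
            GroupScore(name, level, len(members), mono, support if mono else None, False)
        )
    return scores


def summarize_scores(
    scores: list[GroupScore], support_threshold: float = DEFAULT_HIGH_SUPPORT
) -> dict[str, int]:
    """Counts of scored / monophyletic / well-supported groups."""
    scored = [s for s in scores if not s.excluded]
    return {
        "n_groups": len(scores),
        "n_scored": len(scored),
        "n_monophyletic": sum(1 for s in scored if s.monophyletic),
        "n_supported": sum(
            1
            for s in scored
            if s.monophyletic and s.support is not None and s.support > support_threshold
        ),
    }


def reference_genus_check(
    trees: list[dendropy.Tree],
    taxonomy: dict[str, tuple[str, str, str]],
    genus_list: list[str],
    support_threshold: float = DEFAULT_HIGH_SUPPORT,
) -> tuple[dict[str, float], float]:
    """Fraction of trees in which each reference genus is monophyletic with
    support >= ``support_threshold``.

    Trees where a genus has fewer than 2 members are skipped for that genus.
    Returns ``(per_genus_fraction, pooled_fraction)``; a genus never scorable
    gets fraction NaN.
    """
    if not genus_list:
        raise ValueError("genus_list must be non-empty")
    hits: dict[str, int] = {g: 0 for g in genus_list}
    trials: dict[str, int] = {g: 0 for g in genus_list}
    for tree in trees:
        leaves = _leaf_labels(tree)
        for genus in genus_list:
            members = {l for l in leaves if l in taxonomy and taxonomy[l][1] == genus}
            if len(members) < 2:
                continue
            trials[genus] += 1
            mono, support = group_monophyly(tree, members)
            if mono and support is not None and support >= support_threshold:
                hits[genus] += 1
    per_genus = {
        g: (hits[g] / trials[g]) if trials[g] else float("nan") for g in genus_list
    }
    total_trials = sum(trials.values())
    pooled = (sum(hits.values()) / total_trials) if total_trials else float("nan")
    return per_genus, pooled
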