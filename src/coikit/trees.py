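"""Neighbor-joining trees, nonparametric bootstrap support, newick I/O.

Neighbor joining follows the Saitou–Nei agglomeration with the
Studier–Keppler Q criterion

    Q(i, j) = (m - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

joining the pair minimising Q at each step. Ties break to the smallest
(i, j) index pair in the current label order, so the result is deterministic.
Negative branch-length estimates are clamped to zero.

Bootstrap support is the standard Felsenstein procedure: alignment columns
are resampled with replacement, the distance matrix and NJ tree are rebuilt
per replicate, and each internal edge of the reference tree is scored by the
percentage of replicate trees containing the same bipartition.

Trees are unrooted; :class:`dendropy.Tree` is the container, with bootstrap
support carried as internal node labels in newick output.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

from .distances import DistanceMatrix, pairwise_distance_array
from .seqio import Alignment

__all__ = [
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
    "split_support_map",
    "write_newick",
    "read_newick",
]


# ---------------------------------------------------------------------------
# NJ core
# ---------------------------------------------------------------------------

def _nj_core(d0: np.ndarray):
    """Run NJ agglomeration on a distance array.

    Returns ``(joins, final)`` where ``joins`` is a list of
    ``(node_a, node_b, len_a, len_b, new_node)`` events over node ids
    (leaves are 0..n-1, internal nodes n..2n-4) and ``final`` is
    ``([id_x, id_y, id_z], [len_x, len_y, len_z])`` for the terminal
    trifurcation.
    """
    n = d0.shape[0]
    d = d0.astype(np.float64).copy()
    active = list(range(n))
    joins = []
    next_id = n
    m = n
    while m > 3:
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major first minimum -> smallest (i, j)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        la = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lb = dij - la
        joins.append((active[i], active[j], max(la, 0.0), max(lb, 0.0), next_id))
        du = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = du
        d[:, i] = du
        d[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        d = d[np.ix_(keep, keep)]
        active[i] = next_id
        del active[j]
        next_id += 1
        m -= 1
    lx = max(0.0, 0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    ly = max(0.0, 0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    lz = max(0.0, 0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    return joins, (list(active), [lx, ly, lz])


def _nj_split_masks(d: np.ndarray) -> set[int]:
    """Non-trivial splits of the NJ tree as leaf bitmasks.

    Masks are canonicalised to the side not containing leaf 0.
    """
    n = d.shape[0]
    joins, _ = _nj_core(d)
    masks = {i: 1 << i for i in range(n)}
    full = (1 << n) - 1
    splits = set()
    for a, b, _, _, new in joins:
        mask = masks[a] | masks[b]
        masks[new] = mask
        side = (full ^ mask) if (mask & 1) else mask
        size = side.bit_count()
        if 2 <= size <= n - 2:
            splits.add(side)
    return splits


def neighbor_joining(matrix: DistanceMatrix) -> dendropy.Tree:
    """Build the unrooted NJ tree from a fully defined distance matrix."""
    labels = matrix.labels
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    arr = matrix.as_array()
    if np.isnan(arr).any():
        bad = [
            (labels[i], labels[j])
            for i, j in zip(*np.where(np.isnan(arr)))
            if i < j
        ]
        raise ValueError(f"undefined distance(s) for pair(s): {bad[:10]}")
    joins, (final_ids, final_lens) = _nj_core(arr)

    tns = dendropy.TaxonNamespace()
    nodes: dict[int, dendropy.Node] = {}
    for i, label in enumerate(labels):
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label)
        nodes[i] = node
    for a, b, la, lb, new in joins:
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        nodes[new] = parent
    seed = dendropy.Node()
    for node_id, length in zip(final_ids, final_lens):
        seed.add_child(nodes[node_id])
        nodes[node_id].edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = seed
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, one per internal edge.

    Each split is represented by the leaf-label set on the side *not*
    containing the lexicographically smallest label (canonical orientation);
    trivial splits (one leaf vs rest) are excluded.
    """
    return set(_split_nodes(tree))


def _split_nodes(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Map each non-trivial split to the child node of its defining edge."""
    labels = _leaf_labels(tree)
    n = len(labels)
    anchor = min(labels)
    full = frozenset(labels)
    out: dict[frozenset[str], dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = (full - below) if anchor in below else below
        if 2 <= len(side) <= n - 2:
            out[side] = node
    return out


def split_support_map(tree: dendropy.Tree) -> dict[frozenset[str], float | None]:
    """Split -> bootstrap support for an annotated tree (None if unannotated)."""
    return {
        split: getattr(node, "support", None)
        for split, node in _split_nodes(tree).items()
    }


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    alignment: Alignment,
    model: str,
    reference_tree: dendropy.Tree,
    n_reps: int,
    seed: int,
) -> tuple[dendropy.Tree, dict[frozenset[str], float], int]:
    """Felsenstein column-resampling bootstrap on the reference NJ tree.

    Returns ``(annotated_tree, split_support, n_dropped)``. The annotated tree
    is a deep copy of the reference with ``support`` attributes and labels on
    internal nodes. Replicates whose resampled matrix contains undefined
    distances are dropped and counted; more than 10% dropped is an error.
    Replicate ``r`` draws from a fresh generator seeded ``seed + r``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = alignment.ids
    ref_leaves = sorted(_leaf_labels(reference_tree))
    if sorted(labels) != ref_leaves:
        raise ValueError("alignment ids and reference tree leaves differ")

    index = {label: i for i, label in enumerate(labels)}
    full_mask = (1 << len(labels)) - 1

    def to_mask(split: frozenset[str]) -> int:
        mask = 0
        for label in split:
            mask |= 1 << index[label]
        return (full_mask ^ mask) if (mask & 1) else mask

    ref_splits = bipartitions(reference_tree)
    ref_masks = {split: to_mask(split) for split in ref_splits}
    counts = {split: 0 for split in ref_splits}

    enc = alignment.encoded()
    n_cols = enc.shape[1]
    dropped = 0
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, n_cols, size=n_cols)
        arr = pairwise_distance_array(enc[:, cols], model=model)
        if np.isnan(arr).any():
            dropped += 1
            continue
        rep_splits = _nj_split_masks(arr)
        for split, mask in ref_masks.items():
            if mask in rep_splits:
                counts[split] += 1
    if dropped > 0.1 * n_reps:
        raise RuntimeError(
            f"{dropped}/{n_reps} bootstrap replicates dropped (undefined distances)"
        )
    effective = n_reps - dropped
    support = {split: 100.0 * c / effective for split, c in counts.items()}

    annotated = reference_tree.clone(depth=1)
    for split, node in _split_nodes(annotated).items():
        node.support = support[split]
        node.label = f"{support[split]:g}"
    return annotated, support, dropped


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write newick with bootstrap supports as internal node labels."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    )
    Path(path).write_text(text)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a newick tree; internal node labels become ``support`` attributes."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty newick file: {path}")
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed newick in {path}: {exc}") from exc
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree
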