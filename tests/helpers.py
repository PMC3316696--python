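"""Shared helpers for the test suite (imported via pytest's rootdir path)."""

import numpy as np

from coikit.seqio import SequenceRecord, Status


def make_record(id="r1", seq="ATGGCA", species="Genus alpha", genus="Genus",
                family="Fam", status=Status.NOMINAL):
    return SequenceRecord(id=id, seq=seq, species=species, genus=genus,
                          family=family, status=status)


def random_binary_tree(n_leaves: int, rng: np.random.Generator, lo=0.05, hi=1.0):
    """Random unrooted binary tree as (newick string, labels).

    Built by random sequential joins with U(lo, hi) branch lengths; serves as
    the generating tree for additivity oracles.
    """
    labels = [f"t{i}" for i in range(n_leaves)]
    lengths = {l: rng.uniform(lo, hi) for l in labels}
    parts = [(labels[i], lengths[labels[i]]) for i in range(n_leaves)]
    while len(parts) > 3:
        i, j = sorted(rng.choice(len(parts), 2, replace=False))
        (sa, la), (sb, lb) = parts[i], parts[j]
        parts[i] = (f"({sa}:{la},{sb}:{lb})", rng.uniform(lo, hi))
        del parts[j]
    inner = ",".join(f"{s}:{l}" for s, l in parts)
    return f"({inner});", labels


def newick_path_distances(newick: str, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix computed independently via networkx."""
    import dendropy
    import networkx as nx

    tree = dendropy.Tree.get(data=newick, schema="newick")
    g = nx.Graph()
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            g.add_edge(id(node.parent_node), id(node), weight=node.edge.length or 0.0)
    leaf_ids = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    n = len(labels)
    d = np.zeros((n, n))
    paths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = paths[leaf_ids[a]][leaf_ids[labels[j]]]
    return d


def tree_splits_via_edge_removal(tree) -> set[frozenset[str]]:
    """Brute-force bipartitions: delete each edge from an adjacency graph and
    read off the leaf sets of the two components (canonical side excludes the
    lexicographically smallest leaf)."""
    import networkx as nx

    g = nx.Graph()
    leaf_of = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            leaf_of[id(node)] = node.taxon.label
        if node.parent_node is not None:
            g.add_edge(id(node.parent_node), id(node))
    leaves = sorted(leaf_of.values())
    anchor, n = leaves[0], len(leaves)
    splits = set()
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side_a = frozenset(l for nid, l in leaf_of.items() if nid in comp)
        side = frozenset(leaves) - side_a if anchor in side_a else side_a
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits
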