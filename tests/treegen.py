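"""Shared generators and independent oracles for the test suite.

Everything here is deliberately simple and independent of the package's own
tree algorithms: path lengths come from dendropy's patristic distance
matrix, splits from a direct traversal, and the midpoint oracle is an
exhaustive search over every edge position.
"""

from __future__ import annotations

import dendropy
import numpy as np

from carotscan.phylo import DistanceMatrix
from carotscan.seqio import TaxonEntry, TaxonomyTable


def random_tree(
    n_tips: int,
    rng: np.random.Generator,
    min_len: float = 0.5,
    max_len: float = 2.0,
    rooted: bool = True,
) -> dendropy.Tree:
    """A random Yule-shaped tree with uniform branch lengths."""
    root = dendropy.Node()
    leaves = [root]
    while len(leaves) < n_tips:
        i = int(rng.integers(len(leaves)))
        nd = leaves[i]
        kids = [dendropy.Node(), dendropy.Node()]
        for k in kids:
            nd.add_child(k)
        leaves[i : i + 1] = kids
    tns = dendropy.TaxonNamespace()
    for i, leaf in enumerate(leaves):
        leaf.taxon = tns.new_taxon(f"T{i + 1:03d}")
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = rooted
    for node in tree.preorder_node_iter():
        node.support = None
        if node.parent_node is not None:
            node.edge.length = float(rng.uniform(min_len, max_len))
    return tree


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length distances, via dendropy (independent oracle)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = tuple(t.label for t in taxa)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, d)


def splits_of(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial unrooted splits, each normalised away from the min tip."""
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(all_tips)
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(below) <= 1 or len(all_tips - below) <= 1:
            continue
        out.add((all_tips - below) if ref in below else below)
    return out


def brute_force_min_max_depth(tree: dendropy.Tree) -> float:
    """Minimum achievable maximum root-to-tip depth over all edge positions.

    For each edge (u, v) of length w, the tail-side tips are at distance
    d_u(tip) from u and the head-side tips at d_v(tip) from v; rooting x
    from u gives max depth max(Mu + x, Mv + w - x), minimised in closed
    form at the clamped balance point.
    """
    # adjacency with lengths
    adj: dict = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adj.setdefault(node, []).append((child, w))
            adj.setdefault(child, []).append((node, w))

    def depths_from(start, blocked):
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v is blocked or v in dist:
                    continue
                dist[v] = dist[u] + w
                stack.append(v)
        leaf_depths = [d for n, d in dist.items() if n.is_leaf()]
        return max(leaf_depths) if leaf_depths else 0.0

    best = np.inf
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        u, v, w = node.parent_node, node, node.edge.length or 0.0
        mu = depths_from(u, blocked=v)
        mv = depths_from(v, blocked=u)
        x = min(max((mv - mu + w) / 2.0, 0.0), w)
        best = min(best, max(mu + x, mv + w - x))
    return float(best)


def max_root_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length of a rooted tree."""
    best = 0.0
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        best = max(best, d)
    return best


def random_taxonomy(
    tips: list[str],
    rng: np.random.Generator,
    n_taxa: int = 3,
    na_fraction: float = 0.1,
    rank: str = "genus",
) -> TaxonomyTable:
    """Assign each tip a random label at one rank (some NA)."""
    entries = {}
    for t in tips:
        if rng.random() < na_fraction:
            label = "NA"
        else:
            label = f"tax{int(rng.integers(n_taxa)) + 1}"
        entries[t] = TaxonEntry(cell_domain="eukaryote", lineage=(label,))
    return TaxonomyTable((rank,), entries)


def caterpillar(
    labels: list[str], pendant: float = 1.0, internal: float = 1.0
) -> dendropy.Tree:
    """A caterpillar (ladder) tree over ``labels``, first label deepest."""
    tns = dendropy.TaxonNamespace()
    nodes = []
    for lb in labels:
        nd = dendropy.Node()
        nd.taxon = tns.new_taxon(lb)
        nodes.append(nd)
    current = nodes[0]
    for nxt in nodes[1:]:
        parent = dendropy.Node()
        parent.add_child(current)
        current.edge.length = pendant if current.is_leaf() else internal
        parent.add_child(nxt)
        nxt.edge.length = pendant
        current = parent
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = current
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        node.support = None
    return tree
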