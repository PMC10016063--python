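"""Distance-based tree inference: pairwise distances, neighbor joining,
midpoint rooting, and nonparametric bootstrap support.

This is a deliberately small, exactly-testable core: neighbor joining is
consistent on additive matrices (it reconstructs the generating tree's
topology and branch lengths exactly), which gives every downstream stage an
oracle.  Supports are Felsenstein column-resampling bootstrap proportions in
[0, 1]; they share the *role* of SH-aLRT/UFBoot percentages in the original
workflow but are not numerically comparable to them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import dendropy
import numpy as np

from .seqio import GAP, Alignment

logger = logging.getLogger(__name__)

#: p-distance cap used before the Poisson transform so saturated pairs stay finite
POISSON_P_CAP = 0.999

_GAP_CODE = ord(GAP)


@dataclass
class DistanceMatrix:
    """A symmetric, hollow, non-negative labelled distance matrix."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix entries must be finite")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


@dataclass
class BootstrapParams:
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _encode(alignment: Alignment) -> np.ndarray:
    return alignment.to_matrix()


def _distances_from_matrix(
    M: np.ndarray, labels: tuple[str, ...], model: str
) -> DistanceMatrix:
    n = M.shape[0]
    d = np.zeros((n, n))
    nongap = M != _GAP_CODE
    for i, j in combinations(range(n), 2):
        ok = nongap[i] & nongap[j]
        comp = int(ok.sum())
        if comp == 0:
            raise ValueError(
                f"sequences {labels[i]!r} and {labels[j]!r} share no "
                "gap-free columns; distance undefined"
            )
        p = float(((M[i] != M[j]) & ok).sum()) / comp
        if model == "p":
            dij = p
        elif model == "poisson":
            dij = -np.log1p(-min(p, POISSON_P_CAP))
        else:
            raise ValueError(f"unknown distance model {model!r}")
        d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels, d)


def pairwise_distance(alignment: Alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances under pairwise deletion of gapped columns.

    ``p``: proportion of mismatching columns among columns gap-free in both
    sequences.  ``poisson``: -ln(1 - p), with p capped at ``POISSON_P_CAP``.
    """
    return _distances_from_matrix(
        _encode(alignment), tuple(alignment.ids()), model
    )


# ---------------------------------------------------------------------------
# Neighbor joining


def _new_leaf(label: str, tns: dendropy.TaxonNamespace) -> dendropy.Node:
    nd = dendropy.Node()
    nd.taxon = tns.get_taxon(label) or tns.new_taxon(label)
    nd.support = None
    return nd


def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    Deterministic: input labels are canonically sorted before agglomeration,
    and ties in the Q criterion are broken by the lexicographically smallest
    (representative-label) pair.  Negative branch-length estimates are
    clamped to zero (the clamped deficit is logged at DEBUG level).
    """
    n = len(D)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")

    order = sorted(range(n), key=lambda i: D.labels[i])
    labels = [D.labels[i] for i in order]
    d = D.values[np.ix_(order, order)].astype(float).copy()

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = [_new_leaf(lb, tns) for lb in labels]
    reps: list[str] = list(labels)  # representative = min tip label in cluster
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("clamping negative NJ branch length %g to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        best_key = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                pair = tuple(sorted((reps[active[a]], reps[active[b]])))
                key = (q, pair)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = clamp(0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))))
        parent = dendropy.Node()
        parent.support = None
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        # distances from the new cluster to the rest
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # resolve the final three clusters with the three-point formulas
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    center = dendropy.Node()
    center.support = None
    for k, lk in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        center.add_child(nodes[k])
        nodes[k].edge.length = clamp(lk)

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Midpoint rooting


def _adjacency(tree: dendropy.Tree) -> dict:
    adj: dict = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            w = child.edge.length or 0.0
            adj.setdefault(node, []).append((child, w))
            adj.setdefault(child, []).append((node, w))
    return adj


def _paths_from(start, adj):
    """Distance and predecessor maps from ``start`` over the tree graph."""
    dist = {start: 0.0}
    pred = {start: None}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                pred[v] = u
                stack.append(v)
    return dist, pred


def midpoint_root(tree: dendropy.Tree, _atol: float = 1e-12) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest tip-to-tip path.

    Ties between equally longest paths are broken by the lexicographically
    smallest (tip, tip) label pair.  If the midpoint falls on a node, the
    tree is rooted at that node.  The input tree is not modified.
    """
    tree = tree.clone(depth=1)
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    if len(leaves) < 2:
        raise ValueError("midpoint rooting needs at least 2 tips")
    adj = _adjacency(tree)
    if all(w == 0.0 for nbrs in adj.values() for _, w in nbrs):
        raise ValueError("midpoint undefined: all branch lengths are zero")

    best = None  # (-length, labelA, labelB, leafA, leafB, pred-map)
    for la in leaves:
        dist, pred = _paths_from(la, adj)
        for lb in leaves:
            if lb is la or lb.taxon.label < la.taxon.label:
                continue
            key = (-dist[lb], la.taxon.label, lb.taxon.label)
            if best is None or key < best[0]:
                best = (key, la, lb, pred, dist[lb])
    _, la, lb, pred, total = best

    # node path from lb back to la
    path = [lb]
    while path[-1] is not la:
        path.append(pred[path[-1]])
    path.reverse()  # la ... lb

    half = total / 2.0
    cum = 0.0
    for u, v in zip(path, path[1:]):
        w = dict((nb, wt) for nb, wt in adj[u])[v]
        if cum + w >= half - _atol:
            into_edge = half - cum  # distance from u along edge (u, v)
            if abs(into_edge) <= _atol:
                return _root_at_node(tree, u)
            if abs(into_edge - w) <= _atol:
                return _root_at_node(tree, v)
            return _root_on_edge(tree, u, v, into_edge)
        cum += w
    raise AssertionError("midpoint not located on the path")  # pragma: no cover


def _find_edge(u: dendropy.Node, v: dendropy.Node):
    """The dendropy edge between adjacent nodes u, v; returns (edge, head_is_v)."""
    if v.parent_node is u:
        return v.edge, True
    if u.parent_node is v:
        return u.edge, False
    raise ValueError("nodes are not adjacent")


def _root_at_node(tree: dendropy.Tree, node: dendropy.Node) -> dendropy.Tree:
    if node.parent_node is not None:
        tree.reroot_at_node(node, update_bipartitions=False)
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def _root_on_edge(
    tree: dendropy.Tree, u: dendropy.Node, v: dendropy.Node, dist_from_u: float
) -> dendropy.Tree:
    edge, head_is_v = _find_edge(u, v)
    # dendropy: length2 is assigned to the edge's head (child) side
    if head_is_v:
        length1, length2 = dist_from_u, (edge.length or 0.0) - dist_from_u
    else:
        length1, length2 = (edge.length or 0.0) - dist_from_u, dist_from_u
    tree.reroot_at_edge(
        edge, length1=length1, length2=length2, update_bipartitions=False
    )
    tree.seed_node.edge.length = None
    if not hasattr(tree.seed_node, "support"):
        tree.seed_node.support = None
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Bootstrap


def tree_splits(tree: dendropy.Tree) -> dict:
    """Map each internal, non-root node to its unrooted split.

    A split is the frozenset of tip labels on the node's side of its edge,
    normalised to the side *not* containing the lexicographically smallest
    tip of the whole tree.
    """
    all_tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    ref = min(all_tips)
    splits = {}
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(below) <= 1 or len(all_tips - below) <= 1:
            continue  # trivial split
        splits[node] = (all_tips - below) if ref in below else below
    return splits


def bootstrap_support(
    alignment: Alignment,
    model: str = "p",
    params: BootstrapParams | None = None,
    tree: dendropy.Tree | None = None,
) -> tuple[dendropy.Tree, dict]:
    """Attach column-resampling bootstrap supports to a tree's internal edges.

    If ``tree`` is None, the reference tree is the NJ tree of the full
    alignment.  Each replicate resamples columns with replacement, rebuilds
    an NJ tree, and the support of an internal edge is the fraction of valid
    replicates whose tree contains the same unrooted split.  Replicates in
    which some pair loses all comparable columns are dropped and the
    denominator adjusted (reported in the returned summary).
    """
    params = params or BootstrapParams()
    labels = tuple(alignment.ids())
    M = _encode(alignment)
    if tree is None:
        tree = nj_tree(pairwise_distance(alignment, model))
    splits = tree_splits(tree)
    counts = {node: 0 for node in splits}
    target_splits = set(splits.values())

    rng = np.random.default_rng(params.seed)
    n_cols = alignment.n_cols
    dropped = 0
    for _ in range(params.n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        try:
            D = _distances_from_matrix(M[:, cols], labels, model)
        except ValueError:
            dropped += 1
            continue
        rep_splits = set(tree_splits(nj_tree(D)).values()) & target_splits
        for node, split in splits.items():
            if split in rep_splits:
                counts[node] += 1
    valid = params.n_replicates - dropped
    if valid == 0:
        raise ValueError("all bootstrap replicates were dropped")
    for node, c in counts.items():
        node.support = c / valid
    report = {
        "n_replicates": params.n_replicates,
        "dropped_replicates": dropped,
        "valid_replicates": valid,
    }
    return tree, report
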