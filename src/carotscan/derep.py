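"""Tree-guided taxonomic dereplication.

Redundant same-taxon sequences are collapsed on an (intermediate) phylogeny:
whenever two tips that are sisters on the tree carry the same label at the
chosen taxonomic rank, the lower-scoring tip is dropped, until no such pair
remains.  "Sisters" means two leaf children of the same internal node (at
the unrooted seed trifurcation the node may have a third, internal child).
The pipeline variant rebuilds the tree between rounds, mirroring the
two-pass intermediate-tree workflow this formalises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import dendropy

from .phylo import midpoint_root, nj_tree, pairwise_distance
from .seqio import Alignment, SequenceRecord, TaxonomyTable

logger = logging.getLogger(__name__)

MISSING_LABEL = "NA"


@dataclass
class DerepParams:
    rank: str
    scores: Mapping[str, float]
    rounds: int = 2
    single_pass: bool = False


def find_matching_cherries(
    tree: dendropy.Tree, taxonomy: TaxonomyTable, rank: str
) -> list[tuple[str, str]]:
    """All sister tip pairs whose labels at ``rank`` match and are not NA.

    Pairs are returned as (smaller id, larger id), sorted by the smaller id
    then the larger.
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in taxonomy:
            raise KeyError(f"tip {leaf.taxon.label!r} missing from taxonomy")
    pairs: list[tuple[str, str]] = []
    for node in tree.preorder_internal_node_iter():
        leaf_children = sorted(
            (c for c in node.child_nodes() if c.is_leaf()),
            key=lambda c: c.taxon.label,
        )
        for i in range(len(leaf_children)):
            for j in range(i + 1, len(leaf_children)):
                a, b = leaf_children[i].taxon.label, leaf_children[j].taxon.label
                la, lb = taxonomy.label(a, rank), taxonomy.label(b, rank)
                if la == lb and la != MISSING_LABEL:
                    pairs.append((a, b))
    return sorted(pairs)


def _drop_tip(tree: dendropy.Tree, label: str) -> None:
    """Remove one tip; suppress the resulting degree-2 node by summing lengths."""
    leaf = next(
        l for l in tree.leaf_node_iter() if l.taxon.label == label
    )
    parent = leaf.parent_node
    parent.remove_child(leaf)
    if len(parent.child_nodes()) == 1:
        child = parent.child_nodes()[0]
        grand = parent.parent_node
        if grand is None:
            # parent was the root; the remaining child becomes the new root
            parent.remove_child(child)
            child.edge.length = None
            tree.seed_node = child
        else:
            extra = parent.edge.length or 0.0
            grand.remove_child(parent)
            parent.remove_child(child)
            grand.add_child(child)
            if child.edge.length is not None or extra:
                child.edge.length = (child.edge.length or 0.0) + extra


def dereplicate_tree(
    tree: dendropy.Tree,
    taxonomy: TaxonomyTable,
    params: DerepParams,
) -> tuple[dendropy.Tree, list[str], list[str]]:
    """Collapse same-rank sister pairs until none remain (or one pass).

    At each step the first cherry in sorted order is resolved: the
    lower-scoring tip is dropped (ties drop the lexicographically larger
    id).  Returns (pruned tree, retained tip labels, dropped tip labels).
    The input tree is not modified.
    """
    tree = tree.clone(depth=1)
    for t in (l.taxon.label for l in tree.leaf_node_iter()):
        if t not in params.scores:
            raise KeyError(f"tip {t!r} has no bit score")
    dropped: list[str] = []

    def resolve(a: str, b: str) -> None:
        sa, sb = params.scores[a], params.scores[b]
        if sa > sb:
            victim = b
        elif sb > sa:
            victim = a
        else:
            victim = max(a, b)
        _drop_tip(tree, victim)
        dropped.append(victim)

    if params.single_pass:
        gone: set[str] = set()
        for a, b in find_matching_cherries(tree, taxonomy, params.rank):
            if a in gone or b in gone:
                continue
            resolve(a, b)
            gone.add(dropped[-1])
    else:
        while True:
            cherries = find_matching_cherries(tree, taxonomy, params.rank)
            if not cherries:
                break
            resolve(*cherries[0])

    retained = sorted(l.taxon.label for l in tree.leaf_node_iter())
    return tree, retained, dropped


def default_tree_builder(alignment: Alignment) -> dendropy.Tree:
    """Midpoint-rooted NJ tree on Poisson distances.

    Rooting matters: on an unrooted tree, redundant tips straddling the
    point where an outgroup clade attaches never become sisters, so the
    collapse can stall; on a rooted tree every pure same-taxon clade
    contains a cherry until a single representative remains.  Falls back to
    the unrooted tree when the midpoint is undefined (all-zero distances).
    """
    tree = nj_tree(pairwise_distance(alignment, model="poisson"))
    try:
        return midpoint_root(tree)
    except ValueError:
        return tree


@dataclass
class DerepRound:
    tree: dendropy.Tree
    retained: list[str]
    dropped: list[str]


def derep_pipeline(
    records: Sequence[SequenceRecord],
    taxonomy: TaxonomyTable,
    params: DerepParams,
    tree_builder: Callable[[Alignment], dendropy.Tree] | None = None,
) -> tuple[list[SequenceRecord], list[DerepRound]]:
    """Iterate (build tree, dereplicate, subset records) for ``params.rounds``.

    Rounds with fewer than 3 surviving records are skipped with a warning
    (a tree cannot be built).  Returns the retained records and a per-round
    trace.
    """
    tree_builder = tree_builder or default_tree_builder
    current = list(records)
    rounds: list[DerepRound] = []
    for rnd in range(params.rounds):
        if len(current) < 3:
            logger.warning(
                "dereplication round %d skipped: only %d records remain",
                rnd + 1, len(current),
            )
            break
        tree = tree_builder(Alignment(current))
        pruned, retained, dropped = dereplicate_tree(tree, taxonomy, params)
        rounds.append(DerepRound(tree=pruned, retained=retained, dropped=dropped))
        retained_set = set(retained)
        current = [r for r in current if r.id in retained_set]
    return current, rounds
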