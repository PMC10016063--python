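"""Detection of taxonomically disjunct clades — the tree-scan formalisation
of spotting a horizontally transferred gene cluster.

A candidate horizontal-transfer signature is a well-supported clade whose
tips are all eukaryotic yet span several distinct higher taxa (supergroups),
sitting inside a tree context dominated by prokaryotes: unrelated eukaryote
lineages clustering together inside a prokaryotic gene radiation are far
more parsimoniously explained by transfer than by vertical descent.  The
"nested in foreign context" aspect is reported as a fraction rather than
thresholded, since nesting is a matter of degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import dendropy

from .seqio import TaxonomyTable

FOREIGN_CELL_DOMAINS = {"prokaryote", "virus"}


@dataclass
class CladeReport:
    tips: frozenset[str]
    support: float | None
    n_groups: int
    parent_context_foreign_fraction: float
    depth: int

    def __post_init__(self) -> None:
        if not self.tips:
            raise ValueError("a clade report needs a non-empty tip set")


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def clade_support(
    tree: dendropy.Tree, tip_set: Iterable[str]
) -> tuple[bool, float | None]:
    """Is ``tip_set`` monophyletic, and with what support?

    Returns (True, support) when some node's tip descendants equal the set
    exactly; the root and single tips carry support 1.0 by convention.
    Non-monophyletic sets return (False, None).
    """
    tip_set = frozenset(tip_set)
    all_tips = _leafset(tree.seed_node)
    unknown = tip_set - all_tips
    if unknown:
        raise KeyError(f"tips not in tree: {sorted(unknown)}")
    if not tip_set:
        raise ValueError("empty tip set")
    if len(tip_set) == 1:
        return True, 1.0
    for node in tree.preorder_node_iter():
        if _leafset(node) == tip_set:
            if node.parent_node is None:
                return True, 1.0
            return True, getattr(node, "support", None)
    return False, None


def _node_support(node: dendropy.Node) -> float | None:
    if node.parent_node is None:
        return 1.0  # root convention
    return getattr(node, "support", None)


def scan_disjunct_clades(
    tree: dendropy.Tree,
    taxonomy: TaxonomyTable,
    grouping_rank: str,
    min_groups: int = 3,
    min_support: float = 0.0,
) -> list[CladeReport]:
    """Report maximal all-eukaryote clades spanning many groups.

    A node qualifies when (a) every tip below it is eukaryotic, (b) its tips
    carry at least ``min_groups`` distinct non-NA labels at
    ``grouping_rank``, and (c) its support is >= ``min_support`` (a missing
    support passes only when min_support is 0).  Only maximal qualifying
    clades are reported (none nested inside another report).  Each report
    carries the fraction of prokaryote/viral tips among the parent clade's
    *other* descendants, quantifying how foreign the surrounding context is.
    Sorted by support (descending, missing last), then by n_groups.
    """
    for t in _leafset(tree.seed_node):
        if t not in taxonomy:
            raise KeyError(f"tip {t!r} missing from taxonomy")
        taxonomy.label(t, grouping_rank)  # raises on unknown rank

    reports: list[CladeReport] = []

    def qualifies(node: dendropy.Node) -> CladeReport | None:
        tips = _leafset(node)
        if any(taxonomy.cell_domain(t) != "eukaryote" for t in tips):
            return None
        groups = {
            taxonomy.label(t, grouping_rank) for t in tips
        } - {"NA"}
        if len(groups) < min_groups:
            return None
        support = _node_support(node)
        if support is None:
            if min_support > 0:
                return None
        elif support < min_support:
            return None
        parent = node.parent_node
        if parent is None:
            foreign_fraction = 0.0
        else:
            others = _leafset(parent) - tips
            if others:
                foreign = sum(
                    1 for t in others
                    if taxonomy.cell_domain(t) in FOREIGN_CELL_DOMAINS
                )
                foreign_fraction = foreign / len(others)
            else:
                foreign_fraction = 0.0
        depth = 0
        p = node
        while p.parent_node is not None:
            p = p.parent_node
            depth += 1
        return CladeReport(
            tips=tips,
            support=support,
            n_groups=len(groups),
            parent_context_foreign_fraction=foreign_fraction,
            depth=depth,
        )

    def walk(node: dendropy.Node) -> None:
        report = qualifies(node)
        if report is not None:
            reports.append(report)
            return  # maximality: do not descend into a reported clade
        for child in node.child_nodes():
            walk(child)

    walk(tree.seed_node)
    reports.sort(
        key=lambda r: (
            r.support is None,
            -(r.support if r.support is not None else 0.0),
            -r.n_groups,
            sorted(r.tips),
        )
    )
    return reports
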