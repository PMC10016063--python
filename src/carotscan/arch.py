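"""Domain-architecture resolution and fusion-pattern classification.

A protein's architecture is the N-to-C order of its non-overlapping domain
hits, e.g. ``CrtI+CrtB+CrtYc/d`` for the trifunctional carotenoid-synthesis
fusion.  Overlapping hits are resolved greedily by bit score; the surviving
ordered domain tuple is looked up in a registry of named fusion patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .seqio import DomainHit

#: named multidomain patterns of the carotenoid/retinal pathway proteins
DEFAULT_REGISTRY: dict[tuple[str, ...], str] = {
    ("CrtI", "CrtB", "CrtYc/d"): "trifunctional_CrtIBY",
    ("CrtI", "CrtB", "CrtYc/d", "Blh"): "quadrifunctional_CrtIBY_Blh",
    ("CrtB", "CrtYc/d"): "bifunctional_CrtB_CrtYcd",
    ("CrtI", "CrtYc/d"): "bifunctional_CrtI_CrtYcd",
}


@dataclass
class OverlapParams:
    #: maximum tolerated envelope overlap, as a fraction of the shorter envelope
    max_overlap_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.max_overlap_fraction < 1):
            raise ValueError("max_overlap_fraction must be in [0, 1)")


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1)


def _overlap_fraction(a: DomainHit, b: DomainHit) -> float:
    return _overlap(a, b) / min(a.env_length, b.env_length)


def resolve_hits(
    hits: Sequence[DomainHit], params: OverlapParams | None = None
) -> list[DomainHit]:
    """Greedy score-first overlap resolution for one protein's hits.

    Hits are considered in descending bit-score order (ties: smaller
    env_start first); a hit is kept iff it overlaps every already-kept hit
    by at most ``max_overlap_fraction`` of the shorter envelope.  The result
    is sorted by env_start.
    """
    params = params or OverlapParams()
    if not hits:
        return []
    ids = {h.seq_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"resolve_hits expects hits for one protein, got {sorted(ids)}")
    kept: list[DomainHit] = []
    for h in sorted(hits, key=lambda h: (-h.bit_score, h.env_start, h.domain)):
        if all(_overlap_fraction(h, k) <= params.max_overlap_fraction for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: (h.env_start, h.env_end))


def architecture_string(
    resolved_hits: Sequence[DomainHit], params: OverlapParams | None = None
) -> str:
    """Join domain names with '+' in ascending env_start order.

    Expects already-resolved hits; raises if any pair overlaps beyond the
    tolerated fraction.  An empty list yields ``"none"``.
    """
    params = params or OverlapParams()
    if not resolved_hits:
        return "none"
    ordered = sorted(resolved_hits, key=lambda h: (h.env_start, h.env_end))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if _overlap_fraction(a, b) > params.max_overlap_fraction:
                raise ValueError(
                    f"hits {a.domain} ({a.env_start}-{a.env_end}) and "
                    f"{b.domain} ({b.env_start}-{b.env_end}) overlap beyond "
                    "the tolerated fraction; resolve_hits first"
                )
    return "+".join(h.domain for h in ordered)


def classify(
    architecture: str,
    registry: Mapping[tuple[str, ...], str] | None = None,
) -> str:
    """Look an architecture string up in the fusion-pattern registry.

    Single domains map to ``single_domain_<name>``; unknown multidomain
    tuples map to ``"other"``.
    """
    registry = DEFAULT_REGISTRY if registry is None else registry
    if architecture == "none":
        return "other"
    domains = tuple(architecture.split("+"))
    if domains in registry:
        return registry[domains]
    if len(domains) == 1:
        return f"single_domain_{domains[0]}"
    return "other"


def classify_protein(
    hits: Sequence[DomainHit],
    registry: Mapping[tuple[str, ...], str] | None = None,
    params: OverlapParams | None = None,
) -> tuple[str, str]:
    """Convenience: resolve -> architecture string -> label for one protein."""
    resolved = resolve_hits(hits, params)
    arch = architecture_string(resolved, params)
    return arch, classify(arch, registry)
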