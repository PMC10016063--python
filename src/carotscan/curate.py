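"""Pre-tree cleanup of a homolog family.

Three independent steps, applied in pipeline order:

1. ``merge_split_hits`` — collapse split/incomplete duplicate records that
   share a parent protein back into the full-length parent sequence.
2. ``length_filter`` — drop sequences whose length deviates from the family
   median by more than a multiple (default 1.0) of the sample standard
   deviation of the lengths.
3. ``trim_columns`` — drop alignment columns in which at least a threshold
   fraction (default 0.90 or 0.99) of sequences carry a gap; a column is
   retained iff its gap fraction is strictly below the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import GAP, Alignment, DomainHit, SequenceRecord


@dataclass
class FilterParams:
    sd_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")


@dataclass
class TrimParams:
    gap_threshold: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.gap_threshold <= 1):
            raise ValueError("gap_threshold must be in (0, 1]")


@dataclass
class LengthFilterReport:
    median: float
    sd: float
    lower: float
    upper: float
    n_kept: int
    n_removed: int


def length_filter(
    records: Sequence[SequenceRecord],
    params: FilterParams | None = None,
    bounds: tuple[float, float] | None = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord], LengthFilterReport]:
    """Remove records whose (ungapped) length is an outlier for the family.

    A record is removed iff |len - median| > sd_multiplier * sd, with sd the
    sample (n-1) standard deviation; the keep interval is closed (a record
    sitting exactly on a bound is kept).  Note the rule is *not* idempotent
    under recomputation: removing outliers shrinks the sd, so a rerun may
    remove more.  Pass ``bounds`` (from a previous report) to re-apply a
    frozen interval instead.
    """
    params = params or FilterParams()
    if len(records) < 2:
        raise ValueError(
            "length filter needs >= 2 records (standard deviation undefined); "
            "pass the family through unchanged instead"
        )
    lengths = np.array([len(r.ungapped) for r in records], dtype=float)
    median = float(np.median(lengths))
    sd = float(np.std(lengths, ddof=1))
    if bounds is None:
        lower = median - params.sd_multiplier * sd
        upper = median + params.sd_multiplier * sd
    else:
        lower, upper = bounds
    kept, removed = [], []
    for r, ln in zip(records, lengths):
        (kept if lower <= ln <= upper else removed).append(r)
    report = LengthFilterReport(
        median=median, sd=sd, lower=lower, upper=upper,
        n_kept=len(kept), n_removed=len(removed),
    )
    return kept, removed, report


@dataclass
class MergeReport:
    n_groups_merged: int
    merged_parent_ids: list[str]


def merge_split_hits(
    records: Sequence[SequenceRecord],
    hits: Sequence[DomainHit],
    full_sequences: Mapping[str, SequenceRecord],
) -> tuple[list[SequenceRecord], MergeReport]:
    """Resolve split/incomplete duplicate records into full parent sequences.

    Hit records that share a (parent_id, domain) pair in groups of >= 2 are
    replaced by a single record carrying the full parent sequence (looked up
    in ``full_sequences`` by parent_id) with the group's maximum bit score
    retained on the emitted record id; all other records pass through
    unchanged, in input order.
    """
    by_id = {h.seq_id: h for h in hits}
    groups: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        if h.parent_id:
            groups.setdefault((h.parent_id, h.domain), []).append(h)
    split_groups = {k: v for k, v in groups.items() if len(v) >= 2}
    fragment_ids = {h.seq_id for g in split_groups.values() for h in g}

    resolved: list[SequenceRecord] = []
    emitted_parents: set[str] = set()
    merged_parent_ids: list[str] = []
    for r in records:
        if r.id not in fragment_ids:
            resolved.append(r)
            continue
        hit = by_id[r.id]
        parent = hit.parent_id
        if parent in emitted_parents:
            continue
        if parent not in full_sequences:
            raise KeyError(
                f"parent sequence {parent!r} referenced by {r.id!r} "
                "is missing from full_sequences"
            )
        full = full_sequences[parent]
        resolved.append(
            SequenceRecord(
                id=parent,
                residues=full.residues,
                description=full.description,
            )
        )
        emitted_parents.add(parent)
        merged_parent_ids.append(parent)
    report = MergeReport(
        n_groups_merged=len(merged_parent_ids), merged_parent_ids=merged_parent_ids
    )
    return resolved, report


def merged_scores(
    hits: Sequence[DomainHit], scores: Mapping[str, float]
) -> dict[str, float]:
    """Per-id scores after merging: a merged parent gets its fragments' maximum."""
    out = dict(scores)
    groups: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        if h.parent_id:
            groups.setdefault((h.parent_id, h.domain), []).append(h)
    for (parent, _domain), g in groups.items():
        if len(g) >= 2:
            out[parent] = max(
                max(scores.get(h.seq_id, h.bit_score) for h in g),
                out.get(parent, float("-inf")),
            )
    return out


def trim_columns(
    alignment: Alignment, params: TrimParams | None = None
) -> tuple[Alignment, list[int]]:
    """Drop high-gap columns; returns the trimmed alignment and the kept
    original column numbers (1-based, ascending).

    A column is kept iff gap_count / n_records < gap_threshold (strict).
    """
    params = params or TrimParams()
    M = alignment.to_matrix()
    gap_frac = (M == ord(GAP)).mean(axis=0)
    keep = gap_frac < params.gap_threshold
    if not keep.any():
        raise ValueError(
            f"trimming at gap threshold {params.gap_threshold} removed every "
            "column; an empty alignment is invalid"
        )
    kept_indices = [int(i) + 1 for i in np.flatnonzero(keep)]
    records = [
        SequenceRecord(
            id=r.id,
            residues="".join(r.residues[i - 1] for i in kept_indices),
            description=r.description,
        )
        for r in alignment
    ]
    return Alignment(records), kept_indices
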