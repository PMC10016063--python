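"""End-to-end convenience wrappers: family curation and the full
simulate -> curate -> tree -> scan recovery experiment.

These compose the stage modules in their canonical order (merge split
fragments, length-filter, align-as-identity, trim, NJ, midpoint root,
bootstrap, disjunct-clade scan) and are what the command-line entry points
and the recovery experiments call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy

from . import curate, hgtscan, phylo, simulate
from .seqio import Alignment, DomainHit, SequenceRecord, TaxonomyTable


@dataclass
class CuratedFamily:
    records: list[SequenceRecord]
    scores: dict[str, float]
    removed_ids: list[str]


def curate_family(
    records: Sequence[SequenceRecord],
    hits: Sequence[DomainHit],
    full_sequences: Mapping[str, SequenceRecord],
    scores: Mapping[str, float],
    filter_params: curate.FilterParams | None = None,
) -> CuratedFamily:
    """Merge split fragments, then drop length outliers."""
    merged, _ = curate.merge_split_hits(records, hits, full_sequences)
    merged_scores = curate.merged_scores(hits, scores)
    kept, removed, _ = curate.length_filter(merged, filter_params)
    return CuratedFamily(
        records=kept,
        scores={r.id: merged_scores[r.id] for r in kept},
        removed_ids=[r.id for r in removed],
    )


def infer_supported_tree(
    alignment: Alignment,
    model: str = "poisson",
    n_bootstrap: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree, midpoint rooted, with bootstrap supports on internal edges."""
    tree = phylo.nj_tree(phylo.pairwise_distance(alignment, model))
    rooted = phylo.midpoint_root(tree)
    annotated, _report = phylo.bootstrap_support(
        alignment, model, phylo.BootstrapParams(n_replicates=n_bootstrap, seed=seed),
        tree=rooted,
    )
    return annotated


@dataclass
class RecoveryResult:
    recovered: bool
    reports: list[hgtscan.CladeReport]
    recipient_ids: frozenset[str]
    n_recipient_groups: int


def hgt_recovery_trial(
    seed: int,
    config: simulate.SimConfig | None = None,
    family: str = "CrtI",
    n_bootstrap: int = 100,
    min_groups: int = 3,
    min_support: float = 0.8,
) -> RecoveryResult:
    """One full parameter-recovery run on a fresh synthetic dataset.

    Simulates a dataset, curates the chosen domain family, infers a
    midpoint-rooted NJ tree with bootstrap supports, scans for disjunct
    eukaryote clades, and checks that some reported clade's tips are
    exactly the transferred recipients.
    """
    if config is None:
        config = simulate.SimConfig(seed=seed)
    else:
        config = simulate.SimConfig(
            **{**config.__dict__, "seed": seed}
        )
    ds = simulate.build_dataset(config)
    full_sequences = {r.id: r for r in ds.records}
    fam_hits = [h for h in ds.hits if h.domain == family]
    curated = curate_family(
        ds.family_records[family], fam_hits, full_sequences, ds.scores
    )
    tree = infer_supported_tree(
        Alignment(curated.records), n_bootstrap=n_bootstrap, seed=seed
    )
    reports = hgtscan.scan_disjunct_clades(
        tree, ds.taxonomy, grouping_rank="group",
        min_groups=min_groups, min_support=min_support,
    )
    surviving = {r.id for r in curated.records}
    recipients = frozenset(ds.truth.recipient_ids) & surviving
    recovered = any(rep.tips == recipients for rep in reports)
    groups = {
        ds.taxonomy.label(t, "group") for t in recipients
    }
    return RecoveryResult(
        recovered=recovered,
        reports=reports,
        recipient_ids=recipients,
        n_recipient_groups=len(groups),
    )
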