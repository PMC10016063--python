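"""Synthetic datasets with the structure the curation/phylogenetics pipeline
assumes, plus ground truth.

The generator emulates, at desk scale, a comparative protein database in
which a cassette of carotenoid-synthesis domains evolves vertically in a
prokaryotic radiation and was horizontally transferred into several
taxonomically disjoint eukaryote lineages, where it occurs fused into one
multidomain protein.  Sequence evolution is a Poisson substitution process
on a Yule species tree with exponential branch lengths and no indels, so
each domain family's true alignment is the site-wise identity.  Because the
sampled prokaryote nearest the transfer is a relative of the true donor
rather than the donor itself, the transferred copies may carry extra
divergence from the sampled donor tip (``donor_divergence_scale``).

Length outliers (truncated/extended copies) and split fragments (duplicate
pairs sharing a parent protein) are injected so the curation stage has real
work to do; all injections are recorded in the truth bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .seqio import (
    AMINO_ACIDS,
    Alignment,
    DomainHit,
    SequenceRecord,
    TaxonEntry,
    TaxonomyTable,
    write_fasta,
    write_hits,
    write_newick,
    write_scores,
    write_taxonomy,
)

_AA = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)
_N_AA = len(AMINO_ACIDS)

TAXONOMY_RANKS = ("group", "species")


def domain_slug(domain: str) -> str:
    """Filesystem/id-safe token for a domain name (``CrtYc/d`` -> ``CrtYcd``)."""
    return domain.replace("/", "")


@dataclass(frozen=True)
class HgtEvent:
    """One horizontal transfer of a domain cassette.

    ``recipients`` is either an explicit tuple of species ids or None, in
    which case one recipient is drawn per eukaryote group (other than the
    donor's).  ``post_transfer_scale`` is the extra time (in branch-length
    units) each recipient copy evolves after the transfer;
    ``donor_divergence_scale`` is the time separating the transferred copy
    from the sampled donor tip.
    """

    donor_group: str
    cassette: tuple[str, ...] = ("CrtI", "CrtB", "CrtYc/d")
    recipients: tuple[str, ...] | None = None
    post_transfer_scale: float = 0.1
    donor_divergence_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.post_transfer_scale < 0 or self.donor_divergence_scale < 0:
            raise ValueError("transfer scales must be >= 0")
        if not self.cassette:
            raise ValueError("cassette must list at least one domain")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the reference scenario: 40 species in six groups
    (three prokaryotic, carrying the three-domain cassette vertically as
    single-domain proteins; three eukaryotic supergroups), one transfer of
    the full cassette into one recipient per eukaryote group, fused into a
    trifunctional protein in each recipient.
    """

    n_species: int = 40
    group_spec: tuple[tuple[str, str, int], ...] = (
        ("Actinobacteria", "prokaryote", 7),
        ("Bacteroidetes", "prokaryote", 7),
        ("Gammaproteobacteria", "prokaryote", 6),
        ("Stramenopila", "eukaryote", 7),
        ("Alveolata", "eukaryote", 7),
        ("Obazoa", "eukaryote", 6),
    )
    birth_rate: float = 1.0
    branch_length_mean: float = 0.1
    subst_rate: float = 0.2
    domain_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"CrtI": 500, "CrtB": 300, "CrtYc/d": 120}
    )
    hgt_events: tuple[HgtEvent, ...] = (HgtEvent(donor_group="Actinobacteria"),)
    fusion_linker: str = "GS"
    outlier_fraction: float = 0.05
    fragment_fraction: float = 0.05
    disjoint_recipients: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        total = sum(n for _, _, n in self.group_spec)
        if total != self.n_species:
            raise ValueError(
                f"group sizes sum to {total}, expected n_species={self.n_species}"
            )
        if self.birth_rate <= 0 or self.branch_length_mean <= 0:
            raise ValueError("birth_rate and branch_length_mean must be positive")
        if self.subst_rate < 0:
            raise ValueError("subst_rate must be >= 0")
        for dom, ln in self.domain_lengths.items():
            if ln < 30:
                raise ValueError(f"domain {dom!r}: length {ln} < 30")
        for frac_name in ("outlier_fraction", "fragment_fraction"):
            v = getattr(self, frac_name)
            if not (0 <= v < 1):
                raise ValueError(f"{frac_name} must be in [0, 1)")
        for ev in self.hgt_events:
            if ev.donor_group not in {g for g, _, _ in self.group_spec}:
                raise ValueError(f"unknown donor group {ev.donor_group!r}")
            for dom in ev.cassette:
                if dom not in self.domain_lengths:
                    raise ValueError(f"cassette domain {dom!r} has no length")


@dataclass
class TruthBundle:
    """Ground truth emitted alongside a synthetic dataset."""

    species_tree: dendropy.Tree
    true_taxonomy: TaxonomyTable
    true_alignments: dict[str, Alignment]
    recipient_ids: frozenset[str]          # fused-protein sequence ids
    recipient_species: frozenset[str]
    donor_tip: str | None
    donor_clade: frozenset[str]            # donor group's sequence ids (per family)
    true_architecture: dict[str, tuple[str, ...]]
    outlier_ids: frozenset[str]
    fragment_parent_ids: frozenset[str]


@dataclass
class Dataset:
    records: list[SequenceRecord]          # full-length protein database
    family_records: dict[str, list[SequenceRecord]]  # per-domain analysis sets
    hits: list[DomainHit]
    scores: dict[str, float]
    taxonomy: TaxonomyTable
    truth: TruthBundle


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Species tree


def _yule_topology(n: int, rng: np.random.Generator):
    """Grow a rooted topology by repeatedly splitting a uniform random tip."""
    root = dendropy.Node()
    leaves = [root]
    while len(leaves) < n:
        i = int(rng.integers(len(leaves)))
        nd = leaves[i]
        children = [dendropy.Node(), dendropy.Node()]
        for c in children:
            nd.add_child(c)
        leaves[i : i + 1] = children
    return root, leaves


def simulate_species_tree(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dendropy.Tree, TaxonomyTable]:
    """A Yule species tree whose tips form contiguous monophyletic groups.

    A group-level backbone is grown first, then each backbone tip is
    replaced by a within-group Yule subtree; every branch length is an
    independent exponential draw with mean ``branch_length_mean``.  The
    taxonomy maps each species id to (group, species) plus its
    prokaryote/eukaryote flag.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    backbone_root, backbone_leaves = _yule_topology(len(config.group_spec), rng)

    tns = dendropy.TaxonNamespace()
    entries: dict[str, TaxonEntry] = {}
    for leaf, (group, cell_domain, g_n) in zip(backbone_leaves, config.group_spec):
        if g_n == 1:
            group_leaves = [leaf]
        else:
            sub_root, group_leaves = _yule_topology(g_n, rng)
            for child in list(sub_root.child_nodes()):
                sub_root.remove_child(child)
                leaf.add_child(child)
        for i, gl in enumerate(group_leaves):
            name = f"{group}_{i + 1:02d}"
            gl.taxon = tns.new_taxon(name)
            entries[name] = TaxonEntry(
                cell_domain=cell_domain, lineage=(group, name)
            )

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = backbone_root
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.exponential(config.branch_length_mean))
        node.support = None
    return tree, TaxonomyTable(TAXONOMY_RANKS, entries)


# ---------------------------------------------------------------------------
# Sequence evolution


def _random_root_sequence(length: int, rng: np.random.Generator) -> str:
    return bytes(_AA[rng.integers(0, _N_AA, size=length)]).decode("ascii")


def _encode_aa(seq: str) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int64)
    for i, c in enumerate(AMINO_ACIDS):
        lut[ord(c)] = i
    idx = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (idx < 0).any():
        bad = int(np.flatnonzero(idx < 0)[0])
        raise ValueError(f"non-amino-acid character {seq[bad]!r} at position {bad + 1}")
    return idx


def _decode_aa(idx: np.ndarray) -> str:
    return bytes(_AA[idx]).decode("ascii")


def _mutate(idx: np.ndarray, rate: float, t: float, rng: np.random.Generator) -> np.ndarray:
    """Each site mutates with p = 1 - exp(-rate*t) to a uniform other residue."""
    p = -math.expm1(-rate * t)
    out = idx.copy()
    mask = rng.random(idx.shape[0]) < p
    k = int(mask.sum())
    if k:
        out[mask] = (out[mask] + rng.integers(1, _N_AA, size=k)) % _N_AA
    return out


def evolve_domain(
    tree: dendropy.Tree, root_sequence: str, subst_rate: float, seed
) -> dict[str, str]:
    """Evolve a gap-free root sequence down a tree; returns tip -> residues.

    Along each branch of length t, each site independently mutates with
    probability 1 - exp(-subst_rate * t) to a uniformly chosen different
    residue.  No indels: the site-wise identity is the true alignment.
    """
    if subst_rate < 0:
        raise ValueError("subst_rate must be >= 0")
    if "-" in root_sequence:
        raise ValueError("root sequence must be gap-free")
    rng = _as_rng(seed)
    root_idx = _encode_aa(root_sequence)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_idx}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            current = root_idx
        else:
            parent = seqs[id(node.parent_node)]
            current = _mutate(parent, subst_rate, node.edge.length or 0.0, rng)
            seqs[id(node)] = current
        if node.is_leaf():
            out[node.taxon.label] = _decode_aa(current)
    return out


def apply_hgt(
    tip_sequences: Mapping[str, Mapping[str, str]],
    donor_tip: str,
    recipients: Sequence[str],
    cassette: Sequence[str],
    subst_rate: float,
    post_transfer_scale: float,
    seed,
    donor_divergence_scale: float = 0.0,
) -> tuple[dict[str, dict[str, str]], frozenset[str]]:
    """Copy the donor tip's cassette into each recipient, with divergence.

    ``tip_sequences`` maps domain -> {carrier tip -> residues} and must not
    already list the recipients.  Per domain, a single transferred ancestor
    copy is drawn at ``donor_divergence_scale`` time units from the donor
    tip; each recipient's copy then evolves independently for
    ``post_transfer_scale`` units.  With both scales zero, recipient copies
    equal the donor's exactly.
    """
    rng = _as_rng(seed)
    updated = {dom: dict(tips) for dom, tips in tip_sequences.items()}
    for dom in cassette:
        if dom not in updated or donor_tip not in updated[dom]:
            raise ValueError(f"donor {donor_tip!r} lacks cassette domain {dom!r}")
        for r in recipients:
            if r in updated[dom]:
                raise ValueError(
                    f"recipient {r!r} already carries cassette domain {dom!r}"
                )
    for dom in cassette:
        donor_idx = _encode_aa(updated[dom][donor_tip])
        ancestor = _mutate(donor_idx, subst_rate, donor_divergence_scale, rng)
        for r in recipients:
            updated[dom][r] = _decode_aa(
                _mutate(ancestor, subst_rate, post_transfer_scale, rng)
            )
    return updated, frozenset(recipients)


# ---------------------------------------------------------------------------
# Fusion proteins


def _divergence(seq: str, reference: str | None) -> float:
    if reference is None:
        return 0.0
    if len(seq) != len(reference):
        raise ValueError("divergence needs equal-length sequences")
    return sum(a != b for a, b in zip(seq, reference)) / len(seq)


def _bit_score(seq: str, reference: str | None) -> float:
    return len(seq) * (1.0 - _divergence(seq, reference))


def _e_value(bit_score: float) -> float:
    return 10.0 ** (-bit_score / 10.0)


def fuse_domains(
    domain_sequences: Mapping[str, str],
    order: Sequence[str],
    linker: str,
    seq_id: str = "fusion",
    root_sequences: Mapping[str, str] | None = None,
    description: str = "",
) -> tuple[SequenceRecord, list[DomainHit]]:
    """Concatenate domains N->C with a linker; emit exact-envelope hits.

    The synthetic bit score of each constituent domain is
    ``length * (1 - divergence from the domain's root sequence)`` (root
    sequences optional; without them the divergence is taken as 0).
    """
    if not order:
        raise ValueError("fusion order must list at least one domain")
    for dom in order:
        if dom not in domain_sequences:
            raise KeyError(f"domain {dom!r} missing from domain_sequences")
    parts: list[str] = []
    hits: list[DomainHit] = []
    pos = 0
    for i, dom in enumerate(order):
        if i > 0:
            parts.append(linker)
            pos += len(linker)
        seq = domain_sequences[dom]
        score = _bit_score(seq, root_sequences.get(dom) if root_sequences else None)
        hits.append(
            DomainHit(
                seq_id=seq_id,
                domain=dom,
                env_start=pos + 1,
                env_end=pos + len(seq),
                bit_score=score,
                e_value=_e_value(score),
            )
        )
        parts.append(seq)
        pos += len(seq)
    record = SequenceRecord(id=seq_id, residues="".join(parts), description=description)
    return record, hits


# ---------------------------------------------------------------------------
# Dataset assembly


def _pick_recipients(
    config: SimConfig, event: HgtEvent, taxonomy: TaxonomyTable,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    if event.recipients is not None:
        recips = tuple(event.recipients)
    else:
        recips = []
        for group, cell_domain, _n in config.group_spec:
            if cell_domain != "eukaryote" or group == event.donor_group:
                continue
            members = sorted(
                sid for sid in taxonomy.ids()
                if taxonomy.label(sid, "group") == group
            )
            recips.append(members[int(rng.integers(len(members)))])
        recips = tuple(recips)
    if config.disjoint_recipients:
        groups = [taxonomy.label(r, "group") for r in recips]
        if len(set(groups)) != len(groups) or event.donor_group in groups:
            raise ValueError(
                "disjoint_recipients requires recipients in pairwise distinct "
                "groups, all different from the donor group"
            )
    return recips


def build_dataset(config: SimConfig, out_dir: str | Path | None = None) -> Dataset:
    """Generate one complete synthetic dataset (and optionally write it).

    Deterministic under ``config.seed`` (a single RNG stream drives every
    draw): identical configs give byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    species_tree, species_tax = simulate_species_tree(config, rng)

    root_seqs = {
        dom: _random_root_sequence(ln, rng)
        for dom, ln in config.domain_lengths.items()
    }
    evolved = {
        dom: evolve_domain(species_tree, root_seqs[dom], config.subst_rate, rng)
        for dom in config.domain_lengths
    }

    prok_species = sorted(
        sid for sid in species_tax.ids()
        if species_tax.cell_domain(sid) == "prokaryote"
    )
    # vertical carriers: the prokaryote radiation
    carriers: dict[str, dict[str, str]] = {
        dom: {sp: evolved[dom][sp] for sp in prok_species}
        for dom in config.domain_lengths
    }

    donor_tip: str | None = None
    recipient_species: list[str] = []
    recipient_cassettes: dict[str, tuple[str, ...]] = {}
    for event in config.hgt_events:
        donor_members = sorted(
            sid for sid in species_tax.ids()
            if species_tax.label(sid, "group") == event.donor_group
        )
        donor_tip = donor_members[int(rng.integers(len(donor_members)))]
        recips = _pick_recipients(config, event, species_tax, rng)
        carriers, _ = apply_hgt(
            carriers,
            donor_tip,
            recips,
            event.cassette,
            config.subst_rate,
            event.post_transfer_scale,
            rng,
            donor_divergence_scale=event.donor_divergence_scale,
        )
        recipient_species.extend(recips)
        for r in recips:
            recipient_cassettes[r] = tuple(event.cassette)

    # --- assemble protein records, hits, scores, architectures
    records: list[SequenceRecord] = []
    hits: list[DomainHit] = []
    scores: dict[str, float] = {}
    architecture: dict[str, tuple[str, ...]] = {}
    entries: dict[str, TaxonEntry] = {}
    family_members: dict[str, list[SequenceRecord]] = {
        dom: [] for dom in config.domain_lengths
    }

    def add_taxon(seq_id: str, species: str) -> None:
        e = species_tax.entries[species]
        entries[seq_id] = TaxonEntry(cell_domain=e.cell_domain, lineage=e.lineage)

    for sp in prok_species:
        for dom in config.domain_lengths:
            sid = f"{sp}__{domain_slug(dom)}"
            seq = carriers[dom][sp]
            score = _bit_score(seq, root_seqs[dom])
            records.append(SequenceRecord(id=sid, residues=seq))
            hits.append(
                DomainHit(sid, dom, 1, len(seq), score, _e_value(score))
            )
            scores[sid] = score
            architecture[sid] = (dom,)
            add_taxon(sid, sp)
            family_members[dom].append(records[-1])

    recipient_ids: list[str] = []
    for sp in sorted(recipient_species):
        cassette = recipient_cassettes[sp]
        sid = f"{sp}__fusion"
        record, fusion_hits = fuse_domains(
            {dom: carriers[dom][sp] for dom in cassette},
            order=cassette,
            linker=config.fusion_linker,
            seq_id=sid,
            root_sequences=root_seqs,
        )
        records.append(record)
        hits.extend(fusion_hits)
        scores[sid] = max(h.bit_score for h in fusion_hits)
        architecture[sid] = cassette
        add_taxon(sid, sp)
        recipient_ids.append(sid)
        for h in fusion_hits:
            family_members[h.domain].append(
                SequenceRecord(
                    id=sid,
                    residues=record.residues[h.env_start - 1 : h.env_end],
                )
            )

    # true alignments: per-family site-wise identity, before injections
    true_alignments = {
        dom: Alignment([SequenceRecord(id=r.id, residues=r.residues)
                        for r in members])
        for dom, members in family_members.items()
        if len(members) >= 2
    }

    # --- inject length outliers and split fragments (prokaryote singles only,
    # so the transfer signal itself is never corrupted)
    outlier_ids: list[str] = []
    fragment_parents: list[str] = []
    hit_by_id = {h.seq_id: h for h in hits}
    for dom in config.domain_lengths:
        members = family_members[dom]
        eligible = sorted(
            r.id for r in members if architecture.get(r.id) == (dom,)
        )
        n_out = round(config.outlier_fraction * len(members))
        n_frag = round(config.fragment_fraction * len(members))
        chosen_out = [
            eligible[i]
            for i in sorted(rng.choice(len(eligible), size=min(n_out, len(eligible)),
                                       replace=False))
        ] if eligible and n_out else []
        remaining = [e for e in eligible if e not in chosen_out]
        chosen_frag = [
            remaining[i]
            for i in sorted(rng.choice(len(remaining),
                                       size=min(n_frag, len(remaining)),
                                       replace=False))
        ] if remaining and n_frag else []

        by_id = {r.id: i for i, r in enumerate(members)}
        for sid in chosen_out:
            r = members[by_id[sid]]
            L = len(r.residues)
            if rng.integers(2):  # extend
                tail = _random_root_sequence(round(0.8 * L), rng)
                new_seq = r.residues + tail
            else:  # truncate
                new_seq = r.residues[: round(0.4 * L)]
            mutated = SequenceRecord(id=r.id, residues=new_seq)
            members[by_id[sid]] = mutated
            # the database copy of a single-domain protein is the same molecule
            records[[rec.id for rec in records].index(sid)] = mutated
            outlier_ids.append(sid)

        for sid in chosen_frag:
            r = members[by_id[sid]]
            L = len(r.residues)
            cut = max(30, round(0.55 * L))
            parent_hit = hit_by_id[sid]
            frags = [
                (f"{sid}__frag1", r.residues[:cut], 1, cut),
                (f"{sid}__frag2", r.residues[L - cut :], L - cut + 1, L),
            ]
            members[by_id[sid] : by_id[sid] + 1] = []
            hits.remove(parent_hit)
            for fid, fseq, s, e in frags:
                frec = SequenceRecord(id=fid, residues=fseq)
                members.append(frec)
                fscore = _bit_score(fseq, root_seqs[dom][s - 1 : e])
                hits.append(
                    DomainHit(fid, dom, 1, len(fseq), fscore, _e_value(fscore),
                              parent_id=sid)
                )
                scores[fid] = fscore
                entries[fid] = entries[sid]
            fragment_parents.append(sid)

    taxonomy = TaxonomyTable(TAXONOMY_RANKS, entries)
    truth = TruthBundle(
        species_tree=species_tree,
        true_taxonomy=taxonomy,
        true_alignments=true_alignments,
        recipient_ids=frozenset(recipient_ids),
        recipient_species=frozenset(recipient_species),
        donor_tip=donor_tip,
        donor_clade=frozenset(
            sid for sid in scores
            if sid in entries
            and donor_tip is not None
            and entries[sid].lineage[0]
            == species_tax.entries[donor_tip].lineage[0]
        ),
        true_architecture=architecture,
        outlier_ids=frozenset(outlier_ids),
        fragment_parent_ids=frozenset(fragment_parents),
    )
    dataset = Dataset(
        records=records,
        family_records=family_members,
        hits=hits,
        scores=scores,
        taxonomy=taxonomy,
        truth=truth,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(ds: Dataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.records, out_dir / "proteins.fasta")
    write_taxonomy(ds.taxonomy, out_dir / "taxonomy.tsv")
    write_hits(ds.hits, out_dir / "hits.tsv")
    write_scores(ds.scores, out_dir / "scores.tsv")
    fam_dir = out_dir / "families"
    fam_dir.mkdir(exist_ok=True)
    for dom, members in ds.family_records.items():
        write_fasta(members, fam_dir / f"{domain_slug(dom)}.fasta")
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    write_newick(ds.truth.species_tree, truth_dir / "species_tree.nwk")
    aln_dir = truth_dir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for dom, aln in ds.truth.true_alignments.items():
        write_fasta(aln.records, aln_dir / f"{domain_slug(dom)}.fasta")
    with open(truth_dir / "architectures.tsv", "w") as fh:
        fh.write("seq_id\tarchitecture\n")
        for sid in sorted(ds.truth.true_architecture):
            fh.write(f"{sid}\t{'+'.join(ds.truth.true_architecture[sid])}\n")
    (truth_dir / "recipients.txt").write_text(
        "".join(f"{sid}\n" for sid in sorted(ds.truth.recipient_ids))
    )
    (truth_dir / "outliers.txt").write_text(
        "".join(f"{sid}\n" for sid in sorted(ds.truth.outlier_ids))
    )
    (truth_dir / "fragments.txt").write_text(
        "".join(f"{sid}\n" for sid in sorted(ds.truth.fragment_parent_ids))
    )
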