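"""The synthetic-data generator: tree shape, substitution process, HGT,
fusion arithmetic, and dataset assembly."""

import filecmp
import math

import numpy as np
import pytest

from carotscan.seqio import read_newick, write_newick
from carotscan.simulate import (
    HgtEvent,
    SimConfig,
    apply_hgt,
    build_dataset,
    evolve_domain,
    fuse_domains,
    simulate_species_tree,
)


def _tiny_config(**kw):
    defaults = dict(
        n_species=4,
        group_spec=(("Ga", "prokaryote", 2), ("Gb", "eukaryote", 2)),
        hgt_events=(),
        outlier_fraction=0.0,
        fragment_fraction=0.0,
        domain_lengths={"CrtB": 60},
        seed=1,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


# ---------------------------------------------------------------- species tree

def test_species_tree_shape_and_groups():
    tree, tax = simulate_species_tree(_tiny_config())
    tips = [l.taxon.label for l in tree.leaf_node_iter()]
    assert len(tips) == 4
    assert sum(1 for _ in tree.preorder_internal_node_iter()) == 3
    for g in ("Ga", "Gb"):
        members = [t for t in tips if tax.label(t, "group") == g]
        assert len(members) == 2
    # groups are monophyletic
    for node in tree.preorder_internal_node_iter():
        below = {tax.label(l.taxon.label, "group") for l in node.leaf_iter()}
        if len(below) == 1:
            continue
    assert tax.cell_domain("Ga_01") == "prokaryote"
    assert tax.cell_domain("Gb_01") == "eukaryote"


def test_species_tree_deterministic_under_seed():
    t1, _ = simulate_species_tree(_tiny_config(seed=7))
    t2, _ = simulate_species_tree(_tiny_config(seed=7))
    assert write_newick(t1) == write_newick(t2)


def test_group_sizes_must_sum_to_n_species():
    with pytest.raises(ValueError, match="sum"):
        _tiny_config(n_species=5)


def test_branch_length_mean_recovered():
    lengths = []
    for seed in (1, 2, 3):
        cfg = SimConfig(
            n_species=2000,
            group_spec=(("G", "prokaryote", 2000),),
            hgt_events=(),
            branch_length_mean=2.0,
            domain_lengths={"CrtB": 60},
            seed=seed,
        )
        tree, _ = simulate_species_tree(cfg)
        lengths.extend(
            n.edge.length for n in tree.preorder_node_iter() if n.parent_node
        )
    lengths = np.array(lengths)
    se = 2.0 / math.sqrt(len(lengths))  # exponential: sd == mean
    assert abs(lengths.mean() - 2.0) < 3 * se


# -------------------------------------------------------------------- evolver

def test_zero_rate_copies_root_everywhere(rng):
    tree, _ = simulate_species_tree(_tiny_config())
    tips = evolve_domain(tree, "MKVLW" * 10, subst_rate=0.0, seed=rng)
    assert set(tips.values()) == {"MKVLW" * 10}


def test_single_branch_substitution_fraction_matches_closed_form():
    tree = read_newick("(A:1.0,B:0.0);")
    root = "ACDEFGHIKLMNPQRSTVWY" * 500  # 10,000 sites
    tips = evolve_domain(tree, root, subst_rate=0.3, seed=11)
    assert tips["B"] == root  # zero-length branch
    p_obs = sum(a != b for a, b in zip(tips["A"], root)) / len(root)
    p_exp = 1 - math.exp(-0.3)
    se = math.sqrt(p_exp * (1 - p_exp) / len(root))
    assert abs(p_obs - p_exp) < 3 * se


def test_sibling_tips_mutate_independently():
    # excess identity beyond chance: both siblings mutate a site AND agree
    # with probability p^2 / 19; check over 50 seeds
    tree = read_newick("(A:1.0,B:1.0);")
    root = "A" * 1000
    p = 1 - math.exp(-0.2)
    hits = total = 0
    for seed in range(50):
        tips = evolve_domain(tree, root, subst_rate=0.2, seed=seed)
        for a, b in zip(tips["A"], tips["B"]):
            if a != "A" and b != "A":
                total += 1
                hits += a == b
    assert total > 500
    assert abs(hits / total - 1 / 19) < 3 * math.sqrt((1 / 19) * (18 / 19) / total)


def test_negative_rate_rejected(rng):
    tree, _ = simulate_species_tree(_tiny_config())
    with pytest.raises(ValueError):
        evolve_domain(tree, "MKV", subst_rate=-0.1, seed=rng)


# ------------------------------------------------------------------------ HGT

def test_hgt_with_zero_scales_copies_donor_exactly():
    seqs = {"CrtB": {"d": "MKVLW" * 12, "p2": "AAAAA" * 12}}
    out, recips = apply_hgt(
        seqs, "d", ["r1", "r2"], ["CrtB"], subst_rate=0.2,
        post_transfer_scale=0.0, seed=5,
    )
    assert recips == {"r1", "r2"}
    assert out["CrtB"]["r1"] == out["CrtB"]["r2"] == seqs["CrtB"]["d"]
    assert seqs["CrtB"].keys() == {"d", "p2"}  # input untouched


def test_hgt_no_recipients_is_identity():
    seqs = {"CrtB": {"d": "MKVLW" * 12}}
    out, recips = apply_hgt(seqs, "d", [], ["CrtB"], 0.2, 0.1, seed=5)
    assert out == seqs and recips == frozenset()


def test_hgt_rejects_recipient_that_already_carries():
    seqs = {"CrtB": {"d": "MKV", "r1": "MKV"}}
    with pytest.raises(ValueError, match="already carries"):
        apply_hgt(seqs, "d", ["r1"], ["CrtB"], 0.2, 0.1, seed=5)


def test_hgt_donor_divergence_separates_recipients_from_donor():
    seqs = {"CrtB": {"d": "MKVLWACDEF" * 50}}
    out, _ = apply_hgt(
        seqs, "d", ["r1", "r2"], ["CrtB"], subst_rate=0.2,
        post_transfer_scale=0.1, seed=5, donor_divergence_scale=0.5,
    )
    def diff(a, b):
        return sum(x != y for x, y in zip(a, b)) / len(a)
    d_rr = diff(out["CrtB"]["r1"], out["CrtB"]["r2"])
    d_rd = diff(out["CrtB"]["r1"], seqs["CrtB"]["d"])
    assert d_rr < d_rd  # recipients mutually closer than either is to donor


# --------------------------------------------------------------------- fusion

def test_fuse_domain_arithmetic():
    doms = {"CrtI": "I" * 500, "CrtB": "C" * 300, "CrtYc/d": "Y" * 120}
    rec, hits = fuse_domains(doms, ["CrtI", "CrtB", "CrtYc/d"], linker="GS")
    assert len(rec) == 924
    assert [(h.env_start, h.env_end) for h in hits] == [
        (1, 500), (503, 802), (805, 924)
    ]


def test_fuse_single_domain_and_zero_divergence_score():
    rec, (hit,) = fuse_domains(
        {"CrtB": "C" * 300}, ["CrtB"], linker="GS",
        root_sequences={"CrtB": "C" * 300},
    )
    assert rec.residues == "C" * 300
    assert (hit.env_start, hit.env_end) == (1, 300)
    assert hit.bit_score == 300.0


def test_fuse_empty_order_rejected():
    with pytest.raises(ValueError):
        fuse_domains({"CrtB": "C" * 60}, [], linker="GS")


# -------------------------------------------------------------------- dataset

def test_dataset_identical_seeds_are_byte_identical(tmp_path):
    cfg = SimConfig(seed=3)
    build_dataset(cfg, out_dir=tmp_path / "a")
    build_dataset(SimConfig(seed=3), out_dir=tmp_path / "b")
    cmp = filecmp.dircmp(tmp_path / "a", tmp_path / "b")
    def assert_same(c):
        assert not c.diff_files and not c.left_only and not c.right_only
        for sub in c.subdirs.values():
            assert_same(sub)
    assert_same(cmp)


def test_dataset_conservation_across_tables():
    ds = build_dataset(SimConfig(seed=2))
    family_ids = {r.id for members in ds.family_records.values() for r in members}
    for sid in family_ids:
        assert sid in ds.taxonomy
        assert sid in ds.scores
    for sid, archs in ds.truth.true_architecture.items():
        assert archs  # non-empty tuple
    # each emitted protein has exactly one architecture entry
    for rec in ds.records:
        assert rec.id in ds.truth.true_architecture


def test_outlier_count_follows_round_rule():
    cfg = SimConfig(
        n_species=100,
        group_spec=(("G", "prokaryote", 100),),
        hgt_events=(),
        domain_lengths={"CrtB": 60},
        outlier_fraction=0.1,
        fragment_fraction=0.0,
        seed=4,
    )
    ds = build_dataset(cfg)
    assert len(ds.truth.outlier_ids) == 10
    lengths = [len(r) for members in ds.family_records.values() for r in members]
    assert sum(1 for L in lengths if L != 60) == 10


def test_zero_fractions_leave_families_clean():
    ds = build_dataset(SimConfig(seed=5, outlier_fraction=0.0, fragment_fraction=0.0))
    assert not ds.truth.outlier_ids and not ds.truth.fragment_parent_ids
    for dom, members in ds.family_records.items():
        L = {len(r) for r in members}
        assert len(L) == 1  # no indels, no injections: equal lengths
    assert not any(h.parent_id for h in ds.hits)


def test_recipients_are_disjoint_eukaryotes():
    ds = build_dataset(SimConfig(seed=6))
    groups = [ds.taxonomy.label(r, "group") for r in ds.truth.recipient_ids]
    assert len(set(groups)) == len(groups) == 3
    for r in ds.truth.recipient_ids:
        assert ds.taxonomy.cell_domain(r) == "eukaryote"
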