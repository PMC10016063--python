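"""Core data types and readers/writers for FASTA, Newick, and the pipeline's TSV tables.

All tables are tab-separated UTF-8 with a header row.  FASTA ids are the
first whitespace-delimited token of the header; the remainder is kept as the
record description.  Newick internal-node labels that parse as numbers are
interpreted as branch supports; values above 1 are assumed to be percentages
and are divided by 100 so the whole pipeline works on a single [0, 1] scale.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: residues legal in a sequence: the 20 amino acids, ambiguity 'X', gap '-'
ALPHABET = frozenset(AMINO_ACIDS) | {"X", GAP}

CELL_DOMAINS = ("prokaryote", "eukaryote", "virus")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence (aligned or not)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}: must be a non-empty token")
        bad = [(i, c) for i, c in enumerate(self.residues) if c not in ALPHABET]
        if bad:
            i, c = bad[0]
            raise ValueError(
                f"sequence {self.id!r}: illegal character {c!r} at position {i + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


class Alignment:
    """An equal-length collection of >=2 sequence records."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if len(records) < 2:
            raise ValueError("an alignment needs at least two records")
        n_cols = len(records[0].residues)
        for r in records:
            if len(r.residues) != n_cols:
                raise ValueError(
                    f"record {r.id!r} has length {len(r.residues)}, expected {n_cols}"
                )
        _check_unique_ids(records)
        self.records: list[SequenceRecord] = records
        self.n_cols: int = n_cols

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def to_matrix(self) -> np.ndarray:
        """Residues as an (n_records, n_cols) array of single-byte codes."""
        return np.frombuffer(
            "".join(r.residues for r in self.records).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.records), self.n_cols)


@dataclass(frozen=True)
class DomainHit:
    """One domain match on one protein; envelope coordinates are 1-based inclusive."""

    seq_id: str
    domain: str
    env_start: int
    env_end: int
    bit_score: float
    e_value: float
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"hit on {self.seq_id!r}: invalid envelope "
                f"({self.env_start}, {self.env_end})"
            )
        if not math.isfinite(self.bit_score):
            raise ValueError(f"hit on {self.seq_id!r}: bit score must be finite")
        if self.e_value < 0:
            raise ValueError(f"hit on {self.seq_id!r}: e-value must be non-negative")

    @property
    def env_length(self) -> int:
        return self.env_end - self.env_start + 1


@dataclass(frozen=True)
class TaxonEntry:
    cell_domain: str
    lineage: tuple[str, ...]


class TaxonomyTable:
    """sequence id -> ordered ranked lineage plus prokaryote/eukaryote/virus flag.

    Missing labels are encoded as the explicit string ``"NA"``.
    """

    def __init__(self, ranks: Sequence[str], entries: Mapping[str, TaxonEntry]):
        self.ranks: tuple[str, ...] = tuple(ranks)
        for sid, e in entries.items():
            if e.cell_domain not in CELL_DOMAINS:
                raise ValueError(f"{sid!r}: unknown cell domain {e.cell_domain!r}")
            if len(e.lineage) != len(self.ranks):
                raise ValueError(
                    f"{sid!r}: lineage has {len(e.lineage)} labels, "
                    f"expected {len(self.ranks)}"
                )
        self.entries: dict[str, TaxonEntry] = dict(entries)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return list(self.entries)

    def label(self, seq_id: str, rank: str) -> str:
        if rank not in self.ranks:
            raise KeyError(f"unknown rank {rank!r}; known ranks: {list(self.ranks)}")
        if seq_id not in self.entries:
            raise KeyError(f"sequence {seq_id!r} missing from taxonomy")
        return self.entries[seq_id].lineage[self.ranks.index(rank)]

    def cell_domain(self, seq_id: str) -> str:
        if seq_id not in self.entries:
            raise KeyError(f"sequence {seq_id!r} missing from taxonomy")
        return self.entries[seq_id].cell_domain

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"seq_id": sid, "cell_domain": e.cell_domain,
             **dict(zip(self.ranks, e.lineage))}
            for sid, e in self.entries.items()
        ]
        return pd.DataFrame(rows, columns=["seq_id", "cell_domain", *self.ranks])


@dataclass
class Spectrum:
    """An absorbance spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and absorbance must be equal-length 1-D arrays")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance values must be finite")

    def value_at(self, wavelength: float, tolerance: float = 0.25) -> float:
        """Absorbance at the sampled wavelength nearest to ``wavelength``."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[i] - wavelength) > tolerance:
            raise ValueError(
                f"no sampled wavelength within {tolerance} nm of {wavelength} nm "
                f"(range {self.wavelengths[0]}-{self.wavelengths[-1]} nm)"
            )
        return float(self.absorbance[i])


def _check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records.

    The id is the first whitespace-delimited header token; the rest of the
    header becomes the description.
    """
    records: list[SequenceRecord] = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                description=rec.description[len(rec.id):].strip(),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    _check_unique_ids(records)
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, wrap_width: int = 60
) -> None:
    records = list(records)
    _check_unique_ids(records)
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            header = f">{r.id} {r.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.residues), wrap_width):
                fh.write(r.residues[i : i + wrap_width] + "\n")


def records_to_biopython(records: Iterable[SequenceRecord]) -> list[_BioSeqRecord]:
    return [
        _BioSeqRecord(_BioSeq(r.residues), id=r.id, description=r.description)
        for r in records
    ]


# ---------------------------------------------------------------------------
# Newick


def read_newick(text_or_path: str | Path) -> dendropy.Tree:
    """Parse a Newick string (or file path) into a tree.

    Numeric internal-node labels are interpreted as branch supports and
    stored on ``node.support`` on the [0, 1] scale (values > 1 are treated
    as percentages).
    """
    if isinstance(text_or_path, Path) or (
        isinstance(text_or_path, str)
        and "(" not in text_or_path
        and Path(text_or_path).exists()
    ):
        text = Path(text_or_path).read_text()
    else:
        text = str(text_or_path)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"malformed Newick: {exc}") from exc
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise ValueError("malformed Newick: unlabeled tip")
            continue
        if node.label is not None:
            try:
                val = float(node.label)
            except ValueError:
                continue
            node.support = val / 100.0 if val > 1.0 else val
    _check_branch_lengths(tree)
    return tree


def _check_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")


def format_support(value: float) -> str:
    """Render a support value with >= 4 significant digits, minimally."""
    s = f"{value:.6g}"
    return s


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialise a tree to Newick; supports become internal-node labels."""
    for node in tree.preorder_internal_node_iter():
        support = getattr(node, "support", None)
        if support is not None:
            node.label = format_support(support)
    text = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def tree_tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Tables

_HIT_COLUMNS = ["seq_id", "domain", "env_start", "env_end", "bit_score", "e_value"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")


def read_table(path: str | Path, kind: str):
    """Read one of the pipeline's typed TSV tables.

    kind: ``taxonomy`` -> TaxonomyTable; ``hits`` -> list[DomainHit];
    ``scores`` -> dict[str, float]; ``spectrum`` -> Spectrum.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if kind == "taxonomy":
        _require_columns(df, ["seq_id", "cell_domain"], path)
        ranks = [c for c in df.columns if c not in ("seq_id", "cell_domain")]
        if not ranks:
            raise ValueError(f"{path}: taxonomy table has no rank columns")
        if df["seq_id"].duplicated().any():
            dup = df.loc[df["seq_id"].duplicated(), "seq_id"].iloc[0]
            raise ValueError(f"{path}: duplicate seq_id {dup!r}")
        entries = {
            row["seq_id"]: TaxonEntry(
                cell_domain=row["cell_domain"],
                lineage=tuple(row[r] if row[r] else "NA" for r in ranks),
            )
            for _, row in df.iterrows()
        }
        return TaxonomyTable(ranks, entries)
    if kind == "hits":
        _require_columns(df, _HIT_COLUMNS, path)
        hits = []
        for i, row in df.iterrows():
            try:
                hits.append(
                    DomainHit(
                        seq_id=row["seq_id"],
                        domain=row["domain"],
                        env_start=int(row["env_start"]),
                        env_end=int(row["env_end"]),
                        bit_score=float(row["bit_score"]),
                        e_value=float(row["e_value"]),
                        parent_id=(row.get("parent_id") or None)
                        if "parent_id" in df.columns
                        else None,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
        return hits
    if kind == "scores":
        _require_columns(df, ["seq_id", "bit_score"], path)
        return {row["seq_id"]: float(row["bit_score"]) for _, row in df.iterrows()}
    if kind == "spectrum":
        _require_columns(df, ["wavelength", "absorbance"], path)
        return Spectrum(
            wavelengths=df["wavelength"].astype(float).to_numpy(),
            absorbance=df["absorbance"].astype(float).to_numpy(),
        )
    raise ValueError(f"unknown table kind {kind!r}")


def write_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    hits = list(hits)
    with_parent = any(h.parent_id for h in hits)
    rows = []
    for h in hits:
        row = {
            "seq_id": h.seq_id,
            "domain": h.domain,
            "env_start": h.env_start,
            "env_end": h.env_end,
            "bit_score": f"{h.bit_score:.4f}",
            "e_value": f"{h.e_value:.3g}",
        }
        if with_parent:
            row["parent_id"] = h.parent_id or ""
        rows.append(row)
    cols = _HIT_COLUMNS + (["parent_id"] if with_parent else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    taxonomy.to_frame().to_csv(path, sep="\t", index=False)


def write_scores(scores: Mapping[str, float], path: str | Path) -> None:
    df = pd.DataFrame(
        {"seq_id": list(scores), "bit_score": [f"{v:.4f}" for v in scores.values()]}
    )
    df.to_csv(path, sep="\t", index=False)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    df = pd.DataFrame(
        {"wavelength": spectrum.wavelengths, "absorbance": spectrum.absorbance}
    )
    df.to_csv(path, sep="\t", index=False)
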