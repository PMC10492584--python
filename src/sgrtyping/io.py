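"""Domain types and readers/writers for the formats the pipeline touches.

Sequences are plain DNA strings over ``{A, C, G, T, N}``; alignments carry
``-`` gaps.  All coordinates handed around internally are 0-based half-open;
conversion to 1-based display positions happens only in report formatting.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP = "-"
DNA_ALPHABET = frozenset("ACGTN")
WRAP = 70  # fixed line wrap on write, for deterministic diffs

#: the six morphology traits carried in accession metadata
TRAIT_NAMES = (
    "testa_color",
    "testa_marbling",
    "violet_testa_spotting",
    "axil_pigmentation",
    "pod_spotting",
    "leaflet_serration",
)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One accession's amplicon sequence.

    Parameters
    ----------
    id : str
        Accession identifier (unique within a panel).
    seq : str
        DNA over ``{A,C,G,T,N}``, uppercase, no gaps.
    source : str
        Free-text provenance (file name, simulation tag, ...).
    """

    id: str
    seq: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        if not self.seq:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal characters {sorted(bad)} "
                "(only A,C,G,T,N allowed; ambiguity codes must be mapped to N "
                "and gaps are not permitted in unaligned input)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Alignment:
    """A gapped multiple alignment: equal-length rows over ``{A,C,G,T,N,-}``."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ParseError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ParseError("duplicate ids in alignment")
        if self.rows:
            L = len(self.rows[0])
            ragged = [i for i, r in zip(self.ids, self.rows) if len(r) != L]
            if ragged:
                raise ParseError(f"ragged alignment rows for ids: {ragged}")
        for i, r in zip(self.ids, self.rows):
            bad = set(r) - DNA_ALPHABET - {GAP}
            if bad:
                raise ParseError(f"alignment row {i!r}: illegal characters {sorted(bad)}")

    @property
    def length(self) -> int:
        """Number of columns."""
        return len(self.rows[0]) if self.rows else 0

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def ungapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


@dataclass
class AccessionMeta:
    """Passport + morphology metadata for one accession."""

    id: str
    synonyms: list[str] = field(default_factory=list)
    latitude: float | None = None
    longitude: float | None = None
    traits: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ParseError(f"accession {self.id!r}: latitude {self.latitude} out of range")
        for t in TRAIT_NAMES:
            self.traits.setdefault(t, "unknown")


#: default mapping from on-disk TSV column names to AccessionMeta fields
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "id": "id",
    "synonyms": "synonyms",
    "latitude": "latitude",
    "longitude": "longitude",
    **{t: t for t in TRAIT_NAMES},
}


def ungapped_length(row: str) -> int:
    """Count of non-gap characters in a (possibly gapped) sequence string."""
    return len(row) - row.count(GAP)


# ---------------------------------------------------------------------------
# FASTA

def _iter_fasta(path: str | Path):
    for rec in SeqIO.parse(str(path), "fasta"):
        yield rec.id, str(rec.seq).upper()


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read unaligned FASTA; sequences are uppercased and validated.

    Gap characters in unaligned input are a contract violation (use
    :func:`read_alignment` for aligned FASTA).
    """
    path = Path(path)
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for rid, seq in _iter_fasta(path):
        if rid in seen:
            raise ParseError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        if GAP in seq:
            raise ParseError(f"{path}: record {rid!r} contains gap characters in unaligned input")
        if not seq:
            raise ParseError(f"{path}: record {rid!r} has an empty sequence")
        out.append(SequenceRecord(id=rid, seq=seq, source=str(path)))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    _write_wrapped(bio, path)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA (``-`` gaps); all rows must be equal length."""
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    for rid, seq in _iter_fasta(path):
        ids.append(rid)
        rows.append(seq)
    if not rows:
        raise ParseError(f"{path}: empty alignment")
    L = len(rows[0])
    ragged = [i for i, r in zip(ids, rows) if len(r) != L]
    if ragged:
        raise ParseError(f"{path}: ragged rows for ids {ragged}")
    return Alignment(ids=ids, rows=rows)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(r), id=i, description="") for i, r in zip(aln.ids, aln.rows)]
    _write_wrapped(bio, path)


def _write_wrapped(bio_records, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in bio_records:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for k in range(0, len(s), WRAP):
                fh.write(s[k : k + WRAP] + "\n")


# ---------------------------------------------------------------------------
# Metadata TSV

def read_metadata(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[AccessionMeta]:
    """Read an accession metadata TSV.

    ``column_map`` maps AccessionMeta field / trait names to on-disk column
    names (the supplementary-table schema varies between repositories).
    Missing coordinates become ``None`` and missing traits ``"unknown"``.
    Duplicate primary ids are an error.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if cmap["id"] not in df.columns:
        raise ParseError(f"{path}: missing id column {cmap['id']!r}")
    out: list[AccessionMeta] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        rid = row[cmap["id"]].strip()
        if not rid:
            raise ParseError(f"{path}: row with empty id")
        if rid in seen:
            raise ParseError(f"{path}: duplicate accession id {rid!r}")
        seen.add(rid)
        syn_col = cmap["synonyms"]
        syns = []
        if syn_col in df.columns and row[syn_col].strip():
            syns = [s.strip() for s in row[syn_col].split(",") if s.strip()]
        lat = _parse_coord(row, df.columns, cmap["latitude"])
        lon = _parse_coord(row, df.columns, cmap["longitude"])
        traits = {}
        for t in TRAIT_NAMES:
            col = cmap[t]
            val = row[col].strip() if col in df.columns else ""
            traits[t] = val if val else "unknown"
        out.append(AccessionMeta(id=rid, synonyms=syns, latitude=lat, longitude=lon, traits=traits))
    return out


def _parse_coord(row, columns, col: str) -> float | None:
    if col not in columns:
        return None
    raw = row[col].strip()
    if not raw or raw.lower() in {"na", "nan", "unknown", "?"}:
        return None
    try:
        return float(raw)
    except ValueError as e:
        raise ParseError(f"bad coordinate value {raw!r} in column {col!r}") from e


# ---------------------------------------------------------------------------
# Trees

def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a newick tree; leaf labels must be unique."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except Exception as e:
        raise ParseError(f"{path}: malformed newick tree: {e}") from e
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ParseError(f"{path}: duplicate leaf labels in tree")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tree_from_string(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ParseError("duplicate leaf labels in tree")
    return tree
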