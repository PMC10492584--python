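"""Allele identification, naming, SNP-only collapse, and diversity summaries.

Two accessions share an allele iff their amplicon sequences are identical
strings.  Alleles are named ``<length><letter>`` (536a, 536b, ...), with
letters assigned by first occurrence after sorting accession ids
lexicographically — the discovery order of the original survey is not
recoverable, so names are internally consistent only.

Alleles that differ only by substitutions (their optimal global alignment
contains no gaps) collapse into a common *indel class*; the relation is
closed transitively so class counts describe a partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner

from .io import AccessionMeta, SequenceRecord, TRAIT_NAMES


@dataclass
class AlleleTable:
    allele_of: dict[str, str]
    members: dict[str, list[str]]
    indel_class_of: dict[str, str] = field(default_factory=dict)
    #: allele pairs distinguishable only at N positions
    ambiguous_distinct: list[tuple[str, str]] = field(default_factory=list)
    _seq_of_allele: dict[str, str] = field(default_factory=dict)

    @property
    def n_alleles(self) -> int:
        return len(self.members)

    def display_name(self, allele: str) -> str:
        """Drop the letter when a length has a single allele."""
        length = "".join(c for c in allele if c.isdigit())
        same_len = [a for a in self.members if a.rstrip("abcdefghijklmnopqrstuvwxyz") == length]
        return length if len(same_len) == 1 else allele


def _letters(k: int) -> str:
    """a, b, ..., z, aa, ab, ... for arbitrarily many same-length alleles."""
    out = ""
    k += 1
    while k:
        k, r = divmod(k - 1, 26)
        out = chr(ord("a") + r) + out
    return out


def call_alleles(records: Sequence[SequenceRecord]) -> AlleleTable:
    """Partition accessions into alleles by exact sequence identity.

    Names are ``<ungapped length><letter>``; letter order follows first
    occurrence over lexicographically sorted accession ids, so the result is
    independent of input order.  Sequences containing N are compared with N
    matching nothing: same-length alleles that differ only at N positions
    are distinct but flagged ``ambiguous_distinct``.
    """
    by_seq: dict[str, list[str]] = {}
    for r in sorted(records, key=lambda r: r.id):
        by_seq.setdefault(r.seq, []).append(r.id)
    length_counter: dict[int, int] = {}
    allele_of: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    seq_of: dict[str, str] = {}
    # name in order of first (sorted-id) occurrence
    for seq, ids in sorted(by_seq.items(), key=lambda kv: kv[1][0]):
        L = len(seq)
        k = length_counter.get(L, 0)
        length_counter[L] = k + 1
        name = f"{L}{_letters(k)}"
        members[name] = ids
        seq_of[name] = seq
        for i in ids:
            allele_of[i] = name
    ambiguous = []
    names = sorted(members)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = seq_of[a], seq_of[b]
            if len(sa) == len(sb) and all(
                x == y or x == "N" or y == "N" for x, y in zip(sa, sb)
            ):
                ambiguous.append((a, b))
    return AlleleTable(
        allele_of=allele_of, members=members, ambiguous_distinct=ambiguous, _seq_of_allele=seq_of
    )


def _gapfree_aligner() -> PairwiseAligner:
    # match +1, mismatch 0, gap open -4, gap extend -1; N matches nothing
    from Bio.Align import substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "global"
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for c in "ACGT":
        mat[c, c] = 1.0
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    return aligner


def _snp_only_pair(sa: str, sb: str, aligner: PairwiseAligner) -> bool:
    """True iff an optimal global alignment of the two alleles is gap-free.

    Different lengths force gaps.  For equal lengths, a gap-free alignment
    is optimal exactly when the direct (ungapped) score reaches the optimum.
    """
    if len(sa) != len(sb):
        return False
    direct = sum(1 for x, y in zip(sa, sb) if x == y and x != "N")
    return aligner.score(sa, sb) <= direct


def collapse_snp_only(table: AlleleTable, records: Sequence[SequenceRecord] | None = None) -> AlleleTable:
    """Group alleles inter-convertible by substitutions alone.

    Fills ``indel_class_of``: alleles whose pairwise optimal global
    alignment contains no gaps share a class, closed transitively
    (union-find).  Never merges alleles of different length.
    """
    seq_of = dict(table._seq_of_allele)
    if not seq_of and records is not None:
        for r in records:
            seq_of[table.allele_of[r.id]] = r.seq
    names = sorted(table.members)
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    aligner = _gapfree_aligner()
    by_len: dict[int, list[str]] = {}
    for n in names:
        by_len.setdefault(len(seq_of[n]), []).append(n)
    for group in by_len.values():
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if find(a) != find(b) and _snp_only_pair(seq_of[a], seq_of[b], aligner):
                    parent[find(b)] = find(a)
    roots: dict[str, str] = {}
    indel_class_of: dict[str, str] = {}
    for n in names:
        r = find(n)
        if r not in roots:
            roots[r] = f"ic{len(roots) + 1}"
        indel_class_of[n] = roots[r]
    table.indel_class_of = indel_class_of
    return table


@dataclass
class SynonymCheck:
    id_a: str
    id_b: str
    same_allele: bool
    trait_mismatches: int
    probable_mislabel: bool


def verify_synonyms(
    table: AlleleTable,
    meta: Mapping[str, AccessionMeta],
    pairs: Sequence[tuple[str, str]],
) -> list[SynonymCheck]:
    """Check putatively synonymous accession pairs.

    Same sequence with a slightly different morphology score is the expected
    outcome; different sequences flag a probable mislabeling of one of the
    two accessions.  Traits scored ``unknown`` on either side are ignored.
    """
    out = []
    for a, b in pairs:
        for x in (a, b):
            if x not in table.allele_of:
                raise KeyError(f"accession {x!r} missing from allele table")
            if x not in meta:
                raise KeyError(f"accession {x!r} missing from metadata")
        same = table.allele_of[a] == table.allele_of[b]
        mism = sum(
            1
            for t in TRAIT_NAMES
            if meta[a].traits[t] != "unknown"
            and meta[b].traits[t] != "unknown"
            and meta[a].traits[t] != meta[b].traits[t]
        )
        out.append(SynonymCheck(a, b, same, mism, probable_mislabel=not same))
    return out


@dataclass
class DiversitySummary:
    n_accessions: int
    n_alleles: int
    pct_unique: float
    n_indel_classes: int
    per_group: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n_accessions": self.n_accessions,
            "n_alleles": self.n_alleles,
            "pct_unique": self.pct_unique,
            "n_indel_classes": self.n_indel_classes,
            "per_group": self.per_group.to_dict(orient="records"),
        }


def diversity_summary(
    table: AlleleTable,
    records: Sequence[SequenceRecord],
    groups: Mapping[str, str] | None = None,
) -> DiversitySummary:
    """Overall and per-group allele / indel-class / length statistics.

    ``pct_unique`` is 100 * alleles / accessions, the headline diversity
    figure for a fingerprinting locus.
    """
    groups = groups or {}
    if not table.indel_class_of:
        collapse_snp_only(table, records)
    seq_of = {r.id: r.seq for r in records}
    ids = sorted(table.allele_of)
    labels = sorted({groups.get(i, "unassigned") for i in ids})
    rows = []
    for label in ["all"] + labels:
        sel = ids if label == "all" else [i for i in ids if groups.get(i, "unassigned") == label]
        if not sel:
            continue
        alleles = {table.allele_of[i] for i in sel}
        classes = {table.indel_class_of[a] for a in alleles}
        mean_len = sum(len(seq_of[i]) for i in sel) / len(sel)
        rows.append(
            {
                "group": label,
                "n": len(sel),
                "n_alleles": len(alleles),
                "n_indel_classes": len(classes),
                "pct_unique": round(100.0 * len(alleles) / len(sel), 1),
                "mean_length": round(mean_len, 1),
            }
        )
    per_group = pd.DataFrame(rows)
    n = len(ids)
    n_alleles = table.n_alleles
    return DiversitySummary(
        n_accessions=n,
        n_alleles=n_alleles,
        pct_unique=round(100.0 * n_alleles / n, 1) if n else 0.0,
        n_indel_classes=len(set(table.indel_class_of.values())),
        per_group=per_group,
    )


def table_to_dataframe(table: AlleleTable) -> pd.DataFrame:
    rows = [
        {
            "id": i,
            "allele": a,
            "indel_class": table.indel_class_of.get(a, ""),
        }
        for i, a in sorted(table.allele_of.items())
    ]
    return pd.DataFrame(rows)
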