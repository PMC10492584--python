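"""Repeat-aware alignment of amplicons, mimicking a curator's priorities.

Instead of aligning nucleotides directly, sequences are first tokenized into
their major repeat units (via :mod:`sgrtyping.annotate`).  Units are aligned
as symbols by dynamic programming whose substitution score is the
global-alignment identity between unit sequences; whole omitted units cost a
flat gap penalty.  Two curation priorities are encoded:

* *tandem preservation* — a run of highly similar adjacent units is assumed
  to be a recent head-to-tail duplication and is kept contiguous: inserted
  copies are re-packed against their template instead of being scattered;
* *homology over length* — candidate alignments are ranked by base match
  fraction first and total alignment length second.

The unit-level alignment is then projected to nucleotides: matched units are
aligned base-by-base, omitted units become whole-unit gap blocks, and the
conserved end blocks are aligned as anchored prefix/suffix blocks.  The
module does not claim column-level agreement with any hand alignment; it
claims the stated priorities as testable properties.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import PairwiseAligner

from .annotate import RepeatDecomposition
from .io import Alignment, SequenceRecord

DEFAULT_THRESHOLD = 0.90   # within-tandem similarity cutoff
DEFAULT_UNIT_GAP = 0.45    # flat per-unit gap penalty at token level


@dataclass(frozen=True)
class UnitToken:
    owner: str
    index: int
    span: tuple[int, int]
    sequence: str
    has_ga_rich: bool = False
    has_extension: bool = False
    has_gtaagt: bool = False


@dataclass
class UnitAlignment:
    """Token-level alignment: one row of (token | None) per sequence."""

    ids: list[str]
    rows: list[list[UnitToken | None]]

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class AlignmentScore:
    match_fraction: float
    total_length: int

    @property
    def homology_rank(self) -> tuple[float, int]:
        """Sort key: higher match fraction first, shorter alignment second."""
        return (-self.match_fraction, self.total_length)

    def __lt__(self, other: "AlignmentScore") -> bool:
        return self.homology_rank < other.homology_rank


def tokenize(record: SequenceRecord, decomposition: RepeatDecomposition) -> list[UnitToken]:
    return [
        UnitToken(
            owner=record.id,
            index=i,
            span=(u.start, u.end),
            sequence=record.seq[u.start : u.end],
            has_ga_rich=u.has_ga_rich,
            has_extension=u.has_extension,
            has_gtaagt=u.has_gtaagt,
        )
        for i, u in enumerate(decomposition.units)
    ]


def _nt_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -2.0
    a.extend_gap_score = -2.0
    return a


@functools.lru_cache(maxsize=200_000)
def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    aligner = _nt_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length if aln.length else 0.0


def unit_similarity(u: UnitToken | str, v: UnitToken | str) -> float:
    """Global-alignment identity of two unit sequences, in [0, 1]."""
    sa = u.sequence if isinstance(u, UnitToken) else u
    sb = v.sequence if isinstance(v, UnitToken) else v
    return _identity(sa, sb)


# ---------------------------------------------------------------------------
# token-level alignment

def _token_dp(n: int, m: int, sub, gap: float) -> list[tuple[int | None, int | None]]:
    """Needleman-Wunsch over two token strings given a substitution score
    function; returns (i, j) column pairs with None marking gaps.

    Traceback prefers the diagonal on ties, then the j-gap move, so a
    duplicated unit lands as an insertion immediately after its template.
    """
    if n == 0:
        return [(None, j) for j in range(m)]
    if m == 0:
        return [(i, None) for i in range(n)]
    S = np.empty((n + 1, m + 1))
    S[0, :] = -gap * np.arange(m + 1)
    S[:, 0] = -gap * np.arange(n + 1)
    scores = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            scores[i, j] = sub(i, j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            S[i, j] = max(S[i - 1, j - 1] + scores[i - 1, j - 1], S[i - 1, j] - gap, S[i, j - 1] - gap)
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and S[i, j] == S[i - 1, j - 1] + scores[i - 1, j - 1]:
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and S[i, j] == S[i - 1, j] - gap:
            cols.append((i - 1, None))
            i -= 1
        else:
            cols.append((None, j - 1))
            j -= 1
    cols.reverse()
    return cols


def _sub_score(sim: float, threshold: float, gap: float) -> float:
    """Homology-thresholded substitution score.

    Within-set similarity (>= threshold) scores at face value.  Between-set
    similarity scores marginally better than the two gap columns the
    substitution replaces (``0.1 * sim - 2 * gap``): an isolated pair of
    dissimilar units still aligns as one substitution column, but a stack
    of merely scaffold-similar (paralogous) units can never outbid a true
    homologous match placed elsewhere."""
    return sim if sim >= threshold else 0.1 * sim - 2.0 * gap


def _pairwise_token_align(
    a: Sequence[UnitToken],
    b: Sequence[UnitToken],
    gap: float,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[tuple[int | None, int | None]]:
    return _token_dp(
        len(a), len(b),
        lambda i, j: _sub_score(unit_similarity(a[i], b[j]), threshold, gap),
        gap,
    )


def _runs(n: int, sim, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of adjacent items with pairwise similarity >= threshold."""
    runs = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sim(j, j + 1) >= threshold:
            j += 1
        if j > i:
            runs.append((i, j + 1))
        i = j + 1
    return runs


def _repack_tandems(
    cols: list[tuple[int | None, int | None]],
    n_a: int,
    sim_a,
    threshold: float,
) -> list[tuple[int | None, int | None]]:
    """Keep tandem blocks whole: within a run of >=threshold-similar adjacent
    units on the ``a`` side, matched partners on the other side are packed to
    the leftmost columns of the run, so surplus copies form one contiguous
    insertion adjacent to their template.  Packing happens only within
    consecutive column segments, so tokens outside the run can never be
    leap-frogged.  (All units within a run are mutually similar, so the
    re-assignment does not degrade homology.)"""
    cols = list(cols)
    for lo, hi in _runs(n_a, sim_a, threshold):
        idx = [k for k, (i, _) in enumerate(cols) if i is not None and lo <= i < hi]
        seg: list[int] = []
        for k in idx + [None]:
            if seg and (k is None or k != seg[-1] + 1):
                partners = [cols[q][1] for q in seg if cols[q][1] is not None]
                packed = partners + [None] * (len(seg) - len(partners))
                for q, j in zip(seg, packed):
                    cols[q] = (cols[q][0], j)
                seg = []
            if k is not None:
                seg.append(k)
    return cols


def align_unit_strings(
    token_lists: Sequence[Sequence[UnitToken]],
    threshold: float = DEFAULT_THRESHOLD,
    gap: float = DEFAULT_UNIT_GAP,
    ids: Sequence[str] | None = None,
) -> UnitAlignment:
    """Align sequences at the repeat-unit level.

    Progressive profile alignment: sequences join in order of descending
    token count (the richest repeat structure anchors the profile); each
    joins by dynamic programming against the current profile, where a
    token-vs-column score is the mean :func:`unit_similarity` over the
    column's present tokens and an omitted unit costs a flat ``gap``
    penalty.  After each join a tandem re-pack pass keeps runs of
    >=``threshold``-similar adjacent units contiguous on both sides.
    """
    if ids is None:
        ids = [tl[0].owner if tl else f"seq{k}" for k, tl in enumerate(token_lists)]
    ids = list(ids)
    lists = [list(tl) for tl in token_lists]
    if not lists:
        return UnitAlignment(ids=[], rows=[])
    order = sorted(range(len(lists)), key=lambda k: (-len(lists[k]), ids[k]))
    placed = [order[0]]
    columns: list[list[UnitToken | None]] = [[t] for t in lists[order[0]]]
    for k in order[1:]:
        s = lists[k]

        def col_tokens(j: int) -> list[UnitToken]:
            return [t for t in columns[j] if t is not None]

        def sub(i: int, j: int) -> float:
            toks = col_tokens(j)
            if not toks:
                return 0.0
            mean = sum(unit_similarity(s[i], t) for t in toks) / len(toks)
            # infinitesimal occupancy bonus: when two columns tie (identical
            # tandem copies), every joiner picks the same, better-populated
            # column, keeping pairwise projections consistent
            return _sub_score(mean, threshold, gap) + 1e-6 * len(toks)

        cols = _token_dp(len(s), len(columns), sub, gap)
        # re-pack runs in the joining sequence ...
        cols = _repack_tandems(
            cols, len(s), lambda x, y: unit_similarity(s[x], s[y]), threshold
        )
        # ... and runs of similar adjacent profile columns; a column pair only
        # counts as tandem when every cross-column token pair is similar,
        # so heterogeneous columns never get re-packed
        def col_sim(x: int, y: int) -> float:
            tx, ty = col_tokens(x), col_tokens(y)
            if not tx or not ty:
                return 0.0
            return min(unit_similarity(u, v) for u in tx for v in ty)

        flipped = _repack_tandems(
            [(j, i) for i, j in cols], len(columns), col_sim, threshold
        )
        cols = [(i, j) for j, i in flipped]
        new_columns: list[list[UnitToken | None]] = []
        for i, j in cols:
            if j is None:
                new_columns.append([None] * len(placed) + [s[i]])
            elif i is None:
                new_columns.append(columns[j] + [None])
            else:
                new_columns.append(columns[j] + [s[i]])
        columns = _compact_columns(new_columns, threshold)
        placed.append(k)
    # rows in caller order
    rows_by_k = {k: [col[slot] for col in columns] for slot, k in enumerate(placed)}
    return UnitAlignment(ids=ids, rows=[rows_by_k[k] for k in range(len(lists))])


def _compact_columns(
    columns: list[list[UnitToken | None]], threshold: float
) -> list[list[UnitToken | None]]:
    """Merge adjacent columns with disjoint row support whose tokens are all
    mutually >= threshold similar.  Such column pairs arise when identical
    tandem copies of different sequences were placed side by side instead of
    stacked; merging cannot violate row order (each row occupies at most one
    of the two columns) and strictly shortens the alignment."""
    merged = True
    while merged:
        merged = False
        out: list[list[UnitToken | None]] = []
        i = 0
        while i < len(columns):
            if i + 1 < len(columns):
                x, y = columns[i], columns[i + 1]
                disjoint = all(a is None or b is None for a, b in zip(x, y))
                tx = [t for t in x if t is not None]
                ty = [t for t in y if t is not None]
                if disjoint and tx and ty and all(
                    unit_similarity(u, v) >= threshold for u in tx for v in ty
                ):
                    out.append([a if a is not None else b for a, b in zip(x, y)])
                    i += 2
                    merged = True
                    continue
            out.append(columns[i])
            i += 1
        columns = out
    return columns


# ---------------------------------------------------------------------------
# nucleotide projection

def _profile_align(strings: list[str]) -> list[str]:
    """Progressive profile Needleman-Wunsch over a small set of strings."""
    order = sorted(range(len(strings)), key=lambda k: (-len(strings[k]), k))
    profile: list[str] = [strings[order[0]]]
    for k in order[1:]:
        profile = _string_to_profile(strings[k], profile)
    out = [None] * len(strings)
    for slot, k in enumerate(order):
        out[k] = profile[slot]
    return out


def _string_to_profile(s: str, profile: list[str]) -> list[str]:
    MATCH, MISMATCH, GAP = 1.0, -1.0, -2.0
    m = len(profile[0]) if profile else 0
    n = len(s)

    def colscore(ci: int, ch: str) -> float:
        sc = cnt = 0
        for row in profile:
            c = row[ci]
            if c == "-":
                continue
            cnt += 1
            sc += MATCH if c == ch else MISMATCH
        return sc / cnt if cnt else 0.0

    S = np.empty((n + 1, m + 1))
    S[0, :] = GAP * np.arange(m + 1)
    S[:, 0] = GAP * np.arange(n + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            S[i, j] = max(
                S[i - 1, j - 1] + colscore(j - 1, s[i - 1]),
                S[i - 1, j] + GAP,
                S[i, j - 1] + GAP,
            )
    # traceback
    new_s: list[str] = []
    new_profile: list[list[str]] = [[] for _ in profile]
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and S[i, j] == S[i - 1, j - 1] + colscore(j - 1, s[i - 1]):
            new_s.append(s[i - 1])
            for r, nr in zip(profile, new_profile):
                nr.append(r[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and S[i, j] == S[i - 1, j] + GAP:
            new_s.append(s[i - 1])
            for nr in new_profile:
                nr.append("-")
            i -= 1
        else:
            new_s.append("-")
            for r, nr in zip(profile, new_profile):
                nr.append(r[j - 1])
            j -= 1
    rows = ["".join(reversed(r)) for r in new_profile]
    rows.append("".join(reversed(new_s)))
    return rows


def project_to_nucleotides(
    unit_alignment: UnitAlignment,
    records: Sequence[SequenceRecord],
    decompositions: dict[str, RepeatDecomposition],
) -> Alignment:
    """Expand the token alignment to a nucleotide alignment.

    Prefix and suffix blocks (the conserved ends) are aligned across all
    sequences; each token column becomes a block where present units are
    aligned base-by-base and absent sequences get a whole-unit gap run.
    Ungapping any row reproduces its input sequence exactly.
    """
    rec_of = {r.id: r for r in records}
    ids = unit_alignment.ids
    blocks: list[list[str]] = []

    def block_for(strings_of: dict[str, str]) -> list[str]:
        present = [i for i in ids if i in strings_of and strings_of[i]]
        if not present:
            return [""] * len(ids)
        aligned = _profile_align([strings_of[i] for i in present])
        width = len(aligned[0]) if aligned else 0
        out = []
        ai = {i: a for i, a in zip(present, aligned)}
        for i in ids:
            out.append(ai.get(i, "-" * width))
        return out

    prefixes = {
        i: rec_of[i].seq[decompositions[i].prefix_span[0] : decompositions[i].prefix_span[1]]
        for i in ids
    }
    blocks.append(block_for(prefixes))
    for col in range(unit_alignment.length):
        col_strings = {}
        for i, row in zip(ids, unit_alignment.rows):
            tok = row[col]
            if tok is not None:
                col_strings[i] = tok.sequence
        blocks.append(block_for(col_strings))
    suffixes = {
        i: rec_of[i].seq[decompositions[i].suffix_span[0] : decompositions[i].suffix_span[1]]
        for i in ids
    }
    blocks.append(block_for(suffixes))
    rows = ["".join(b[k] for b in blocks) for k in range(len(ids))]
    aln = Alignment(ids=list(ids), rows=rows)
    for i in ids:  # lossless contract
        if aln.ungapped(i) != rec_of[i].seq:
            raise AssertionError(f"projection lost sequence content for {i}")
    return aln


def align_panel(
    records: Sequence[SequenceRecord],
    decompositions: dict[str, RepeatDecomposition],
    threshold: float = DEFAULT_THRESHOLD,
    gap: float = DEFAULT_UNIT_GAP,
) -> Alignment:
    """Tokenize, align at unit level, and project to nucleotides."""
    token_lists = [tokenize(r, decompositions[r.id]) for r in records]
    ua = align_unit_strings(token_lists, threshold=threshold, gap=gap, ids=[r.id for r in records])
    return project_to_nucleotides(ua, records, decompositions)


def score_alignment(alignment: Alignment) -> AlignmentScore:
    """Homology-priority score: base match fraction over all row pairs.

    A column contributes to a pair when both rows are non-gap; it matches
    when the bases are equal (N matches nothing).
    """
    if alignment.nrows < 2:
        raise ValueError("scoring needs at least two rows")
    pairs = matches = 0
    rows = alignment.rows
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            for x, y in zip(rows[i], rows[j]):
                if x != "-" and y != "-":
                    pairs += 1
                    if x == y and x != "N":
                        matches += 1
    frac = matches / pairs if pairs else 0.0
    return AlignmentScore(match_fraction=frac, total_length=alignment.length)
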