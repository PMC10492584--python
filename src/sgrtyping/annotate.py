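"""Fuzzy motif scanning and repeat-unit decomposition of intron amplicons.

The hypervariable interior of the amplicon is built from imperfect
head-to-tail "major repeat" units, each carrying a purine-rich (GA-rich)
segment.  A handful of short motifs recur across units and are the raw
material for classification:

* ``GA-rich``      — ``AGAAGAGGAGGAGAGA`` (approximate), one or two per unit
* ``GA-rich extension`` — ``CAAGAGGATAAA``, diagnostic of group A
* ``GTAAGT motif`` — ``GTAAGTCTAAT``; at most one per group-A sequence,
  many per group-B sequence
* ``line start``   — ``CTCTTCTAAT``, the common unit-start motif
* ``unit end``     — ``CTTGTTTGTGTCTGGT`` near the end of many units

Two 5'-end features complete the picture: the poly-T run and the ``CTTTT``
sequence, whose presence/deletion separates several subgroups.  All motif
matching is Hamming-distance (no indels inside a motif window); ``N``
matches nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import pandas as pd

from .io import SequenceRecord

# canonical motifs
GA_RICH = "AGAAGAGGAGGAGAGA"
EXTENSION = "CAAGAGGATAAA"
GTAAGT = "GTAAGTCTAAT"
LINE_START = "CTCTTCTAAT"
UNIT_END = "CTTGTTTGTGTCTGGT"

HINDIII = "AAGCTT"
DRAI = "TTTAAA"

# flanks of the canonical CTTTT context; the "deleted" state is the two
# flanks adjacent with the C+T-run between them gone
CTTTT_LEFT = "GCACGATG"
CTTTT_RIGHT = "CAGTGAGC"


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int
    length: int
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class AnnotatorParams:
    """Mismatch budgets and windows for the motif scan.

    The budgets admit the "slight variants" of each motif seen across
    accessions; they are deliberately loose for the long degenerate motifs
    (GA-rich, unit end) and tight for the short diagnostic ones.
    """

    max_mismatch_ga_rich: int = 3
    max_mismatch_extension: int = 2
    max_mismatch_gtaagt: int = 2
    max_mismatch_line_start: int = 2
    max_mismatch_unit_end: int = 4
    #: GA-rich windows must additionally be >= this fraction G+A
    ga_content_min: float = 0.75
    #: poly-T run is sought in this many leading nucleotides
    polyt_window: int = 80
    #: CTTTT context is sought in this window of sequence coordinates
    ctttt_window: tuple[int, int] = (30, 100)
    ctttt_left: str = CTTTT_LEFT
    ctttt_right: str = CTTTT_RIGHT
    #: conserved-end spans used by the decomposition
    suffix_len: int = 130
    prefix_fallback: int = 80


@dataclass
class UnitSpan:
    start: int
    end: int
    has_ga_rich: bool = False
    has_extension: bool = False
    has_gtaagt: bool = False
    degenerate: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatDecomposition:
    """Ordered major-repeat-unit spans for one sequence.

    ``units`` partition the interior ``[prefix_span.end, suffix_span.start)``.
    """

    id: str
    units: list[UnitSpan]
    prefix_span: tuple[int, int]
    suffix_span: tuple[int, int]

    @property
    def n_units(self) -> int:
        return len(self.units)


@dataclass
class AnnotationProfile:
    """Per-sequence motif/repeat/restriction feature vector."""

    id: str
    seq_length: int
    ga_rich_hits: list[MotifHit] = field(default_factory=list)
    extension_hits: list[MotifHit] = field(default_factory=list)
    gtaagt_hits: list[MotifHit] = field(default_factory=list)
    line_start_hits: list[MotifHit] = field(default_factory=list)
    unit_end_hits: list[MotifHit] = field(default_factory=list)
    polyT_len: int = 0
    ctttt_state: str = "absent"  # present | deleted | absent
    ctttt_span: tuple[int, int] | None = None
    dra1_sites: list[int] = field(default_factory=list)
    hindiii_sites: list[int] = field(default_factory=list)

    @property
    def ga_rich_count(self) -> int:
        return len(self.ga_rich_hits)

    @property
    def extension_count(self) -> int:
        return len(self.extension_hits)

    @property
    def gtaagt_count(self) -> int:
        return len(self.gtaagt_hits)


def hamming(a: str, b: str) -> int:
    """Hamming distance; ``N`` never matches anything (including ``N``)."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def find_motifs(
    seq: str,
    motif: str,
    max_mismatch: int,
    motif_name: str | None = None,
    min_ga_content: float | None = None,
) -> list[MotifHit]:
    """All approximate (Hamming) occurrences of ``motif`` in ``seq``.

    Every window at distance <= ``max_mismatch`` is found; overlapping hits
    are then merged keeping the lower-mismatch hit (ties: leftmost).  When
    ``min_ga_content`` is given, windows whose G+A fraction falls below it
    are discarded before merging (used to keep the GA-rich scan out of
    unrelated purine runs).
    """
    if len(motif) < 4:
        raise ValueError("motif length must be >= 4")
    if max_mismatch >= len(motif) / 2:
        raise ValueError("max_mismatch must be < motif length / 2")
    name = motif_name or motif
    m = len(motif)
    raw: list[MotifHit] = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        d = hamming(window, motif)
        if d <= max_mismatch:
            if min_ga_content is not None:
                ga = sum(1 for c in window if c in "GA") / m
                if ga < min_ga_content:
                    continue
            raw.append(MotifHit(name, i, m, d))
    # resolve overlaps: prefer fewer mismatches, then leftmost
    raw.sort(key=lambda h: (h.mismatches, h.start))
    kept: list[MotifHit] = []
    for h in raw:
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def restriction_sites(seq: str, recognition: str) -> list[int]:
    """0-based start positions of exact matches of a recognition sequence."""
    if not set(recognition) <= set("ACGT"):
        raise ValueError("recognition sequence must be over A,C,G,T")
    out: list[int] = []
    i = seq.find(recognition)
    while i != -1:
        out.append(i)
        i = seq.find(recognition, i + 1)
    return out


def _longest_t_run(s: str) -> int:
    best = run = 0
    for c in s:
        run = run + 1 if c == "T" else 0
        best = max(best, run)
    return best


def _ctttt_scan(seq: str, params: AnnotatorParams) -> tuple[str, tuple[int, int] | None]:
    """Classify the CTTTT feature as present / deleted / absent.

    ``present``: a C followed by >= 4 T's inside the search window.
    ``deleted``: the two canonical context flanks adjacent (<=1 mismatch
    each) without the T-run between them.
    """
    lo, hi = params.ctttt_window
    window = seq[lo : min(hi, len(seq))]
    for i in range(len(window) - 4):
        if window[i] == "C" and window[i + 1 : i + 5] == "TTTT":
            j = i + 5
            while j < len(window) and window[j] == "T":
                j += 1
            return "present", (lo + i, lo + j)
    left, right = params.ctttt_left, params.ctttt_right
    la, ra = len(left), len(right)
    for i in range(max(0, lo - 10), min(hi, len(seq) - la - ra) + 1):
        if (
            hamming(seq[i : i + la], left) <= 1
            and hamming(seq[i + la : i + la + ra], right) <= 1
        ):
            return "deleted", (i + la, i + la)
    return "absent", None


def annotate(record: SequenceRecord, params: AnnotatorParams | None = None) -> AnnotationProfile:
    """Compute the full feature vector for one amplicon sequence.

    Pure function of (sequence, params): the scan has no state and no
    randomness, so identical inputs always yield identical profiles.
    """
    params = params or AnnotatorParams()
    seq = record.seq
    ctttt_state, ctttt_span = _ctttt_scan(seq, params)
    return AnnotationProfile(
        id=record.id,
        seq_length=len(seq),
        ga_rich_hits=find_motifs(
            seq, GA_RICH, params.max_mismatch_ga_rich, "ga_rich",
            min_ga_content=params.ga_content_min,
        ),
        extension_hits=find_motifs(seq, EXTENSION, params.max_mismatch_extension, "extension"),
        gtaagt_hits=find_motifs(seq, GTAAGT, params.max_mismatch_gtaagt, "gtaagt"),
        line_start_hits=find_motifs(seq, LINE_START, params.max_mismatch_line_start, "line_start"),
        unit_end_hits=find_motifs(seq, UNIT_END, params.max_mismatch_unit_end, "unit_end"),
        polyT_len=_longest_t_run(seq[: params.polyt_window]),
        ctttt_state=ctttt_state,
        ctttt_span=ctttt_span,
        dra1_sites=restriction_sites(seq, DRAI),
        hindiii_sites=restriction_sites(seq, HINDIII),
    )


MAX_UNITS = 25


def decompose_units(
    record: SequenceRecord,
    profile: AnnotationProfile,
    params: AnnotatorParams | None = None,
) -> RepeatDecomposition:
    """Cut the amplicon interior into major-repeat-unit spans.

    The 5' prefix runs through the CTTTT context (fallback: the first 80 nt)
    and the 3' suffix is the final conserved block.  The interior is cut at
    each unit-start anchor — line-start or GTAAGT motif hit — with GA-rich
    hits supplying a fallback anchor where no start motif precedes them.
    With no anchors at all the interior is one degenerate unit.
    """
    params = params or AnnotatorParams()
    seq = record.seq
    n = len(seq)
    if profile.ctttt_span is not None:
        # through the right flank of the CTTTT context
        prefix_end = profile.ctttt_span[1] + len(params.ctttt_right)
    else:
        prefix_end = min(params.prefix_fallback, n)
    suffix_start = max(prefix_end, n - params.suffix_len)
    prefix_end = min(prefix_end, suffix_start)

    def interior(hits: Iterable[MotifHit]) -> list[MotifHit]:
        return [h for h in hits if prefix_end <= h.start < suffix_start]

    anchors = sorted(
        {h.start for h in interior(profile.line_start_hits)}
        | {h.start for h in interior(profile.gtaagt_hits)}
    )
    # GA-rich hits with no start-motif anchor in the 100 nt before them
    for h in interior(profile.ga_rich_hits):
        if not any(h.start - 100 <= a <= h.start for a in anchors):
            anchors.append(h.start)
    anchors = sorted(set(anchors))
    # drop anchors closer than a plausible minimal unit
    pruned: list[int] = []
    for a in anchors:
        if not pruned or a - pruned[-1] >= 30:
            pruned.append(a)
    anchors = pruned

    degenerate = not anchors
    if degenerate:
        cuts = [prefix_end, suffix_start]
    else:
        cuts = sorted(set([prefix_end] + anchors + [suffix_start]))
        # a sub-unit-length leading remnant before the first anchor (flank
        # leftovers, pads) joins the first unit rather than forming its own
        if len(cuts) > 2 and cuts[1] - cuts[0] < 55:
            cuts.pop(1)
    units = [UnitSpan(a, b, degenerate=degenerate) for a, b in zip(cuts, cuts[1:]) if b > a]
    if not units:
        units = [UnitSpan(prefix_end, suffix_start, degenerate=True)]
    while len(units) > MAX_UNITS:  # merge the smallest adjacent pair
        k = min(range(len(units) - 1), key=lambda i: units[i].length + units[i + 1].length)
        units[k] = UnitSpan(units[k].start, units[k + 1].end)
        del units[k + 1]
    for u in units:
        u.has_ga_rich = any(u.start <= h.start < u.end for h in profile.ga_rich_hits)
        u.has_extension = any(u.start <= h.start < u.end for h in profile.extension_hits)
        u.has_gtaagt = any(u.start <= h.start < u.end for h in profile.gtaagt_hits)
    return RepeatDecomposition(
        id=record.id,
        units=units,
        prefix_span=(0, prefix_end),
        suffix_span=(suffix_start, n),
    )


# ---------------------------------------------------------------------------
# exports

def profiles_to_dataframe(profiles: Sequence[AnnotationProfile]) -> pd.DataFrame:
    """One row per accession: counts and 5'-end features, for TSV export."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "id": p.id,
                "seq_length": p.seq_length,
                "ga_rich_count": p.ga_rich_count,
                "extension_count": p.extension_count,
                "gtaagt_count": p.gtaagt_count,
                "line_start_count": len(p.line_start_hits),
                "unit_end_count": len(p.unit_end_hits),
                "polyT_len": p.polyT_len,
                "ctttt_state": p.ctttt_state,
                "dra1_sites": ",".join(map(str, p.dra1_sites)),
                "hindiii_sites": ",".join(map(str, p.hindiii_sites)),
            }
        )
    return pd.DataFrame(rows)


def profile_to_dict(profile: AnnotationProfile) -> dict:
    return asdict(profile)


def format_decomposition(record: SequenceRecord, decomp: RepeatDecomposition) -> str:
    """Formatted text emphasising the major repeat structure: the sequence
    is broken so that each line carries one full or partial repeat unit."""
    seq = record.seq
    lines = [f"# {record.id}  ({len(seq)} nt, {decomp.n_units} units)"]
    p0, p1 = decomp.prefix_span
    lines.append(f"prefix  {p0 + 1:>5}  {seq[p0:p1]}")
    for k, u in enumerate(decomp.units, start=1):
        flags = "".join(
            c for c, f in (("G", u.has_ga_rich), ("E", u.has_extension), ("T", u.has_gtaagt)) if f
        )
        tag = "unit*" if u.degenerate else "unit"
        lines.append(f"{tag:<6}{u.start + 1:>6}  {seq[u.start:u.end]}  [{flags}]")
    s0, s1 = decomp.suffix_span
    lines.append(f"suffix  {s0 + 1:>5}  {seq[s0:s1]}")
    return "\n".join(lines) + "\n"
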