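"""Group and subgroup assignment from annotation profiles.

Group A and group B amplicons are separated by a cluster of co-occurring
features rather than any single necessary one, so group assignment is a
weighted vote: the GA-rich extension (present in every group-A sequence,
absent from every group-B sequence) carries double weight, GTAAGT-motif
multiplicity, GA-rich repeat count, and the DraI / HindIII diagnostic sites
carry unit weight.  A sequence whose scores nearly tie — the signature of a
hybrid-derived allele — is called ``atypical`` rather than forced into a
group.

Subgroups are decided by ordered rule chains over indel-structure features
(CTTTT state, poly-T length, diagnostic insert probes, restriction sites).
Diagnostics that the survey located by alignment coordinates are
re-expressed here as sequence-space probe subsequences with fuzzy matching,
because the classifier sees unaligned input; the shipped probes match the
synthetic archetypes and real panels supply their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .annotate import AnnotationProfile, RepeatDecomposition, find_motifs
from .io import AccessionMeta

GROUPS = ("A", "B", "atypical", "unassigned")
SUBGROUPS = ("A-1-a", "A-1-b", "A-2", "A-3", "A-4-a", "A-4-b", "B-5", "B-6", "B-7", "B-8", "none")


@dataclass(frozen=True)
class ClassifierRule:
    name: str
    side: str  # "A" or "B"
    predicate: Callable[[AnnotationProfile], bool]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("rule weight must be > 0")


@dataclass
class Classification:
    id: str
    group: str = "unassigned"
    subgroup: str = "none"
    score_A: float = 0.0
    score_B: float = 0.0
    evidence: list[str] = field(default_factory=list)


@dataclass
class ProbeLibrary:
    """Diagnostic subsequences for subgroup rules (fuzzy-matched)."""

    insert_a4a: str = ""  # the 65-nt subgroup A-4-a insert
    insert_a4b: str = ""  # the 39-nt subgroup A-4-b insert
    fragment_b6: str = ""  # the 43-nt subgroup B-6 tandem fragment

    @classmethod
    def synthetic(cls) -> "ProbeLibrary":
        from .simulate import FRAG43, INSERT39, INSERT65

        return cls(insert_a4a=INSERT65, insert_a4b=INSERT39, fragment_b6=FRAG43)


@dataclass
class ClassifierParams:
    margin: float = 0.2
    extension_weight: float = 2.0
    #: tolerance around the 1-based position-95 HindIII diagnostic
    hindiii_offset: int = 94
    hindiii_tol: int = 3
    probes: ProbeLibrary = field(default_factory=ProbeLibrary.synthetic)


def _dra1_in_3prime_quarter(p: AnnotationProfile) -> bool:
    return any(s >= 0.75 * p.seq_length for s in p.dra1_sites)


def _hindiii_near_95(p: AnnotationProfile, params: ClassifierParams) -> bool:
    return any(abs(s - params.hindiii_offset) <= params.hindiii_tol for s in p.hindiii_sites)


def _rules(params: ClassifierParams) -> list[ClassifierRule]:
    w_ext = params.extension_weight
    return [
        ClassifierRule("A:extension_present", "A", lambda p: p.extension_count >= 1, w_ext),
        ClassifierRule("A:gtaagt_at_most_one", "A", lambda p: p.gtaagt_count <= 1),
        ClassifierRule("A:ga_rich_6_to_13", "A", lambda p: 6 <= p.ga_rich_count <= 13),
        ClassifierRule("A:no_dra1_3prime", "A", lambda p: not _dra1_in_3prime_quarter(p)),
        ClassifierRule("A:no_hindiii", "A", lambda p: not p.hindiii_sites),
        ClassifierRule("B:extension_absent", "B", lambda p: p.extension_count == 0, w_ext),
        ClassifierRule("B:gtaagt_multiple", "B", lambda p: p.gtaagt_count >= 3),
        ClassifierRule("B:ga_rich_13_plus", "B", lambda p: p.ga_rich_count >= 13),
        ClassifierRule("B:dra1_3prime", "B", _dra1_in_3prime_quarter),
        ClassifierRule("B:hindiii_near_95", "B", lambda p: _hindiii_near_95(p, params)),
    ]


def classify_group(profile: AnnotationProfile, params: ClassifierParams | None = None) -> Classification:
    """Weighted vote over the A-side and B-side diagnostic rules.

    ``atypical`` when the relative margin ``|sA - sB| / (sA + sB)`` falls
    below the configured threshold (default 0.2) — the hallmark of a
    sequence mixing group-A and group-B features.
    """
    params = params or ClassifierParams()
    c = Classification(id=profile.id)
    for rule in _rules(params):
        if rule.predicate(profile):
            c.evidence.append(rule.name)
            if rule.side == "A":
                c.score_A += rule.weight
            else:
                c.score_B += rule.weight
    total = c.score_A + c.score_B
    if total == 0:
        c.group = "unassigned"
    elif abs(c.score_A - c.score_B) / total < params.margin:
        c.group = "atypical"
    else:
        c.group = "A" if c.score_A > c.score_B else "B"
    return c


def _probe_hits(seq: str, probe: str, frac_mismatch: float = 0.12) -> int:
    if not probe:
        return 0
    budget = min(int(len(probe) * frac_mismatch), len(probe) // 2 - 1)
    return len(find_motifs(seq, probe, max(budget, 1)))


def classify_subgroup(
    profile: AnnotationProfile,
    decomposition: RepeatDecomposition | None,
    classification: Classification,
    seq: str,
    params: ClassifierParams | None = None,
) -> Classification:
    """Fill the subgroup by the ordered rule chain for the assigned group.

    A-side order: A-3 (CTTTT lost, one GTAAGT) — A-4-a/A-4-b (CTTTT kept,
    split by insert probes) — A-1-a (few GA repeats, short) — A-1-b (7-9 GA
    repeats) — A-2 (fallback).  B-side order: B-7 (CTTTT deleted) — B-6
    (HindIII + tandem fragment) — B-5 (long poly-T, few GA repeats) — B-8
    (the collection of sequences fitting no other rule).
    """
    params = params or ClassifierParams()
    p = profile
    c = classification
    if c.group == "A":
        if p.ctttt_state != "present" and p.gtaagt_count == 1:
            c.subgroup = "A-3"
        elif p.ctttt_state == "present" and p.gtaagt_count >= 1:
            a = _probe_hits(seq, params.probes.insert_a4a)
            b = _probe_hits(seq, params.probes.insert_a4b)
            c.subgroup = "A-4-a" if a >= max(b, 1) else ("A-4-b" if b >= 1 else "none")
        elif p.ga_rich_count <= 6 and p.seq_length <= 560:
            c.subgroup = "A-1-a"
        elif 7 <= p.ga_rich_count <= 9:
            c.subgroup = "A-1-b"
        else:
            c.subgroup = "A-2"
    elif c.group == "B":
        full = _probe_hits(seq, params.probes.fragment_b6)
        partial = (
            _probe_hits(seq, params.probes.fragment_b6[: len(params.probes.fragment_b6) // 2])
            if params.probes.fragment_b6
            else 0
        )
        if p.ctttt_state == "deleted":
            c.subgroup = "B-7"
        elif p.hindiii_sites and full >= 2 and partial > full:
            c.subgroup = "B-6"
        elif p.polyT_len > 10 and p.ga_rich_count < 13:
            c.subgroup = "B-5"
        else:
            c.subgroup = "B-8"
    else:
        c.subgroup = "none"
    return c


def classify_panel(
    profiles: Sequence[AnnotationProfile],
    seqs: Mapping[str, str],
    decompositions: Mapping[str, RepeatDecomposition] | None = None,
    params: ClassifierParams | None = None,
) -> list[Classification]:
    params = params or ClassifierParams()
    out = []
    for p in profiles:
        c = classify_group(p, params)
        dec = decompositions.get(p.id) if decompositions else None
        out.append(classify_subgroup(p, dec, c, seqs[p.id], params))
    return out


def classifications_to_dataframe(classifications: Sequence[Classification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "group": c.group,
                "subgroup": c.subgroup,
                "score_A": c.score_A,
                "score_B": c.score_B,
                "evidence": ";".join(c.evidence),
            }
            for c in classifications
        ]
    )


def geo_partition_summary(
    classifications: Sequence[Classification],
    meta: Mapping[str, AccessionMeta],
    latitude_cut: float = 35.5,
) -> dict:
    """Tally groups north and south of a latitude cut.

    Accessions without coordinates are listed separately, not tallied.
    """
    if not -90.0 <= latitude_cut <= 90.0:
        raise ValueError("latitude_cut must be in [-90, 90]")
    counts = {
        "north": {g: 0 for g in GROUPS},
        "south": {g: 0 for g in GROUPS},
    }
    missing: list[str] = []
    for c in classifications:
        m = meta.get(c.id)
        if m is None or m.latitude is None:
            missing.append(c.id)
            continue
        side = "north" if m.latitude >= latitude_cut else "south"
        counts[side][c.group] += 1
    return {"latitude_cut": latitude_cut, "counts": counts, "missing_coordinates": sorted(missing)}
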