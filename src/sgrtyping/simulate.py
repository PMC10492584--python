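"""Synthetic amplicon panels with known group labels and generating tree.

The generator emulates the architecture of the hypervariable intron: a
conserved 5' block (~80 nt, carrying the poly-T run and the CTTTT context)
and a conserved 3' block (~130 nt) flank an interior of 5-20 imperfect
head-to-tail major repeat units (60-100 nt), each holding one or two GA-rich
segments.  Group-A archetypes carry a GA-rich extension and at most one
GTAAGT motif; group-B archetypes carry no extension, many GTAAGT motifs,
more GA-rich repeats, and the diagnostic restriction sites.  Subgroup
archetypes add the indel features the classifier keys on (CTTTT deletion,
long poly-T, characteristic inserts).

Mutation along a tree combines nucleotide substitutions, slippage in short
tandem repeats, and duplication/deletion of whole repeat units; branch
lengths are expected substitutions per site and the indel processes scale
with the same lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import dendropy
import numpy as np

from .annotate import (
    CTTTT_LEFT,
    CTTTT_RIGHT,
    EXTENSION,
    GA_RICH,
    GTAAGT,
    HINDIII,
    DRAI,
    LINE_START,
    UNIT_END,
    AnnotatorParams,
    annotate,
    decompose_units,
    restriction_sites,
)
from .io import SequenceRecord, tree_from_string

# fixed conserved-end constants: any sequences of the right size work, the
# analysis depends only on their conservation across the panel
_FIX_A = "GCTAGCATCGGACTCATGCCAGTCAGCATC"          # 30 nt lead-in
_FIX_C = "ATGGCATGCCTAGCTGACGGTCATG"               # 25 nt after CTTTT context
CONSERVED3 = (
    "CATCGGACTAGCATGCAGTCGATCGGCATA"
    "GCTACGGATCAGCATCGCTAGGCATCGACT"
    "AGCATCGCAGATCGGCTACGATCAGCGATC"
    "GGCTAGCATCGCAGTCGATCAGGCTACGAT"
    "CAGCATCGAC"
)  # 130 nt

# diagnostic insert probes carried by the synthetic archetypes; real data
# needs user-supplied probes because these features are accession-specific
INSERT65 = (
    "CGATCAGGCTTACGGATCAGCGTACGGCTA"
    "GCATCAGCGGATCACGGCTAGCATCGACGT"
    "CATGC"
)  # 65 nt, subgroup A-4-a
INSERT39 = "GCTACGATCAGGCATCGCTAGCGATCACGGCTAGCATCG"  # 39 nt, subgroup A-4-b
FRAG43 = "CGGATCAGCTACGGCATCGATCAGGCTAGCGATCACGCTAGCA"  # 43 nt, subgroup B-6

_DRA_OFFSET_IN_SUFFIX = 20  # DraI planted this far into the 3' block
HINDIII_OFFSET = 94  # 0-based start: 1-based position 95 of the amplicon
# neutral pad opening the interior when HindIII is planted, so the spliced
# site lands between the conserved 5' block and the first unit-start motif
_HINDIII_PAD = "GCATCGACTGCAGCATCGGA"


@dataclass
class ArchetypeSpec:
    """Blueprint of one group/subgroup amplicon architecture."""

    group: str  # "A" or "B"
    n_units: int = 8
    unit_length: int = 62
    ga_rich_count: int = 8
    has_extension: bool = True
    gtaagt_count: int = 0
    include_hindiii: bool = False
    include_dra1: bool = False
    conserved5: str = ""  # assembled from the constants when empty
    conserved3: str = CONSERVED3
    polyT_len: int = 8
    ctttt_present: bool = True
    #: per-unit degeneracy: substitutions applied inside each GA-rich segment
    ga_degeneracy: int = 1
    #: optional diagnostic insert planted between interior units
    insert_seq: str | None = None
    subgroup: str = "none"

    def validate(self) -> None:
        if self.group not in ("A", "B"):
            raise ValueError(f"group must be A or B, got {self.group!r}")
        if not 60 <= self.unit_length <= 100:
            raise ValueError("unit_length must be in [60, 100]")
        if not 7 <= self.polyT_len <= 11:
            raise ValueError("polyT_len must be in [7, 11]")
        if not self.n_units <= self.ga_rich_count <= 2 * self.n_units:
            raise ValueError("ga_rich_count must be in [n_units, 2*n_units]")
        if self.group == "A":
            if not self.has_extension:
                raise ValueError("group A requires a GA-rich extension")
            if self.gtaagt_count > 1:
                raise ValueError("group A allows at most one GTAAGT motif")
            if not 6 <= self.ga_rich_count <= 13:
                raise ValueError("group A GA-rich count must be in [6, 13]")
        else:
            if self.has_extension:
                raise ValueError("group B excludes the GA-rich extension")
            if self.gtaagt_count < 5:
                raise ValueError("group B requires >= 5 GTAAGT motifs")
            # the 13-18 range holds for group B except the long-poly-T
            # (B-5-like) architecture, which runs lower
            if not 13 <= self.ga_rich_count <= 18 and not self.polyT_len > 10:
                raise ValueError("group B GA-rich count must be in [13, 18]")


@dataclass
class MutationModel:
    """Rates per unit branch length (expected substitutions per site)."""

    snp_rate: float = 1.0
    slippage_rate: float = 5.0
    unit_dup_rate: float = 1.0
    unit_del_rate: float = 0.5
    block_dup_rate: float = 0.2
    #: geometric continuation probability for multi-period slippage steps
    slippage_geom_p: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("snp_rate", "slippage_rate", "unit_dup_rate", "unit_del_rate", "block_dup_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MutationEvent:
    node: str
    kind: str  # snp | slippage | unit_dup | unit_del | block_dup
    pos: int
    length: int
    detail: str = ""


@dataclass
class SimulatedPanel:
    records: list[SequenceRecord]
    truth_group: dict[str, str]
    truth_allele: dict[str, str]
    tree: dendropy.Tree
    truth_subgroup: dict[str, str] = field(default_factory=dict)
    events: list[MutationEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# archetype construction

_FORBIDDEN = (HINDIII, DRAI)


def _conserved5(spec: ArchetypeSpec) -> str:
    if spec.conserved5:
        return spec.conserved5
    core = "CTTTTTT" if spec.ctttt_present else ""
    return (
        _FIX_A
        + "T" * spec.polyT_len
        + "CA"
        + CTTTT_LEFT
        + core
        + CTTTT_RIGHT
        + _FIX_C
    )


def _random_filler(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    bases = np.array(list("ACGT"))
    probs = np.array([0.20, 0.30, 0.20, 0.30])  # pyrimidine-leaning
    return "".join(rng.choice(bases, size=n, p=probs))


def _degenerate_ga(rng: np.random.Generator, k: int) -> str:
    """GA-rich segment with k purine-preserving substitutions (erosion)."""
    seg = list(GA_RICH)
    for pos in rng.choice(len(seg), size=min(k, len(seg)), replace=False):
        seg[pos] = "A" if seg[pos] == "G" else "G"
    return "".join(seg)


def _build_unit(
    rng: np.random.Generator,
    length: int,
    start_motif: str,
    n_ga: int,
    with_extension: bool,
    degeneracy: int,
) -> str:
    parts = [start_motif]
    core = [_degenerate_ga(rng, degeneracy) for _ in range(n_ga)]
    if with_extension:
        core[-1] = core[-1] + EXTENSION
    fixed = len(start_motif) + sum(len(c) for c in core) + len(UNIT_END)
    n_slots = n_ga + 1
    n_fill = max(length - fixed, 4 * n_slots)
    extra = n_fill - 4 * n_slots  # every filler slot gets >= 4 nt spacing
    cut_points = sorted(rng.integers(0, extra + 1, size=n_slots - 1))
    fills = [4 + c - p for p, c in zip([0] + list(cut_points), list(cut_points) + [extra])]
    # interleave: start | fill | GA | fill | [GA | fill] | unit-end
    for ga, f in zip(core, fills[:-1]):
        parts.append(_random_filler(rng, f))
        parts.append(ga)
    parts.append(_random_filler(rng, fills[-1]))
    parts.append(UNIT_END)
    return "".join(parts)


def build_archetype(spec: ArchetypeSpec, seed: int) -> SequenceRecord:
    """Assemble a root amplicon for one architecture; deterministic in seed.

    The assembled sequence is verified against the motif annotator (GA-rich,
    extension and GTAAGT counts, CTTTT state, poly-T length, restriction
    sites) and re-drawn on the rare filler collision.
    """
    spec.validate()
    params = AnnotatorParams()
    for attempt in range(60):
        rng = np.random.default_rng((seed, attempt))
        seq = _assemble(spec, rng)
        if _verify(spec, seq, params):
            return SequenceRecord(
                id=f"archetype_{spec.group}_{spec.subgroup}",
                seq=seq,
                source=f"synthetic archetype (seed={seed})",
            )
    raise RuntimeError(f"could not assemble a clean archetype for {spec}")


def _assemble(spec: ArchetypeSpec, rng: np.random.Generator) -> str:
    # distribute GA segments: every unit gets one, extras double up in the
    # earliest units; the extension rides on the last unit (group A)
    doubles = spec.ga_rich_count - spec.n_units
    units = []
    for i in range(spec.n_units):
        start = GTAAGT if i < spec.gtaagt_count else LINE_START
        n_ga = 2 if i < doubles else 1
        with_ext = spec.has_extension and i == spec.n_units - 1
        units.append(
            _build_unit(rng, spec.unit_length, start, n_ga, with_ext, spec.ga_degeneracy)
        )
    if spec.insert_seq:
        k = spec.n_units // 2
        units.insert(k, spec.insert_seq)
    if spec.include_hindiii:
        units.insert(0, _HINDIII_PAD)
    suffix = spec.conserved3
    if spec.include_dra1:
        o = _DRA_OFFSET_IN_SUFFIX
        suffix = suffix[:o] + DRAI + suffix[o + len(DRAI) :]
    seq = _conserved5(spec) + "".join(units) + suffix
    if spec.include_hindiii:
        seq = seq[:HINDIII_OFFSET] + HINDIII + seq[HINDIII_OFFSET + len(HINDIII) :]
    return seq


def _verify(spec: ArchetypeSpec, seq: str, params: AnnotatorParams) -> bool:
    prof = annotate(SequenceRecord(id="x", seq=seq), params)
    if prof.ga_rich_count != spec.ga_rich_count:
        return False
    if prof.extension_count != (1 if spec.has_extension else 0):
        return False
    if prof.gtaagt_count != spec.gtaagt_count:
        return False
    if prof.polyT_len != spec.polyT_len:
        return False
    want_state = "present" if spec.ctttt_present else "deleted"
    if prof.ctttt_state != want_state:
        return False
    hind = restriction_sites(seq, HINDIII)
    if spec.include_hindiii and hind != [HINDIII_OFFSET]:
        return False
    if not spec.include_hindiii and hind:
        return False
    dra = restriction_sites(seq, DRAI)
    want_dra = [len(seq) - len(spec.conserved3) + _DRA_OFFSET_IN_SUFFIX] if spec.include_dra1 else []
    if dra != want_dra:
        return False
    # unit-start anchors must be exactly the designed ones, so the repeat
    # decomposition recovers the designed unit count
    if len(prof.line_start_hits) != spec.n_units - spec.gtaagt_count:
        return False
    rec = SequenceRecord(id="x", seq=seq)
    if decompose_units(rec, prof, params).n_units != spec.n_units:
        return False
    return True


# ---------------------------------------------------------------------------
# mutation processes

LENGTH_MIN, LENGTH_MAX = 500, 1400


def find_ssrs(seq: str, max_period: int = 6, min_len: int = 8) -> list[tuple[int, int, int]]:
    """Maximal short tandem repeats (period <= max_period, length >= min_len).

    Returns non-overlapping (start, end, period) runs, longest-first greedy.
    """
    runs: list[tuple[int, int, int]] = []
    n = len(seq)
    for p in range(1, max_period + 1):
        i = 0
        while i + p < n:
            j = i + p
            while j < n and seq[j] == seq[j - p]:
                j += 1
            runlen = j - i
            if runlen >= max(min_len, 2 * p):
                runs.append((i, j, p))
                i = j - p + 1
            else:
                i += 1
    runs.sort(key=lambda r: (-(r[1] - r[0]), r[0]))
    kept: list[tuple[int, int, int]] = []
    for r in runs:
        if all(r[1] <= k[0] or r[0] >= k[1] for k in kept):
            kept.append(r)
    kept.sort()
    return kept


def _interior_units(seq: str, params: AnnotatorParams) -> list[tuple[int, int]]:
    rec = SequenceRecord(id="node", seq=seq)
    prof = annotate(rec, params)
    dec = decompose_units(rec, prof, params)
    return [(u.start, u.end) for u in dec.units]


def _mutate_branch(
    seq: str,
    brlen: float,
    rng: np.random.Generator,
    model: MutationModel,
    node: str,
    log: list[MutationEvent],
    params: AnnotatorParams,
) -> str:
    # ---- whole-unit duplication / deletion / block duplication; the first
    # unit carries the irregular lead-in between the conserved 5' block and
    # the first start motif, so only proper units (index >= 1) are candidates
    def candidates(units):
        return units[1:] if len(units) > 1 else units

    units = _interior_units(seq, params)
    n_dup = rng.poisson(model.unit_dup_rate * len(units) * brlen)
    n_del = rng.poisson(model.unit_del_rate * len(units) * brlen)
    n_blk = rng.poisson(model.block_dup_rate * len(units) * brlen)
    for _ in range(n_dup):
        cand = candidates(_interior_units(seq, params))
        s, e = cand[rng.integers(len(cand))]
        if len(seq) + (e - s) > LENGTH_MAX:
            continue
        seq = seq[:e] + seq[s:e] + seq[e:]  # head-to-tail copy after template
        log.append(MutationEvent(node, "unit_dup", e, e - s, seq[s:e]))
    for _ in range(n_del):
        units = _interior_units(seq, params)
        if len(units) <= 1:
            continue
        s, e = units[1:][rng.integers(len(units) - 1)]
        if len(seq) - (e - s) < LENGTH_MIN:
            continue
        log.append(MutationEvent(node, "unit_del", s, e - s, seq[s:e]))
        seq = seq[:s] + seq[e:]
    for _ in range(n_blk):
        units = _interior_units(seq, params)
        if len(units) < 3:
            continue
        i = 1 + int(rng.integers(len(units) - 2))
        w = int(rng.integers(2, min(3, len(units) - i) + 1))
        s, e = units[i][0], units[i + w - 1][1]
        if len(seq) + (e - s) > LENGTH_MAX:
            continue
        seq = seq[:e] + seq[s:e] + seq[e:]
        log.append(MutationEvent(node, "block_dup", e, e - s, f"{w} units"))

    # ---- SSR slippage (period <= 6, run length >= 8)
    for s, e, p in find_ssrs(seq):
        k_events = rng.poisson(model.slippage_rate * brlen)
        for _ in range(k_events):
            steps = 1
            while rng.random() < model.slippage_geom_p:
                steps += 1
            expand = rng.random() < 0.5
            for _ in range(steps):
                if expand:
                    if len(seq) + p > LENGTH_MAX:
                        break
                    seq = seq[:e] + seq[e - p : e] + seq[e:]
                    e += p
                    log.append(MutationEvent(node, "slippage", e - p, p, "+"))
                else:
                    if e - s - p < p or len(seq) - p < LENGTH_MIN:
                        break
                    seq = seq[: e - p] + seq[e:]
                    e -= p
                    log.append(MutationEvent(node, "slippage", e, p, "-"))

    # ---- SNPs
    n_snp = rng.poisson(model.snp_rate * len(seq) * brlen)
    for _ in range(n_snp):
        pos = int(rng.integers(len(seq)))
        old = seq[pos]
        choices = [b for b in "ACGT" if b != old]
        new = choices[rng.integers(3)]
        seq = seq[:pos] + new + seq[pos + 1 :]
        log.append(MutationEvent(node, "snp", pos, 1, f"{old}>{new}"))
    return seq


def evolve_on_tree(
    tree: dendropy.Tree,
    root_record: SequenceRecord,
    model: MutationModel,
    group: str = "A",
    subgroup: str = "none",
    rng: np.random.Generator | None = None,
) -> SimulatedPanel:
    """Evolve the root amplicon independently along each branch, pre-order.

    Every edge must carry a branch length (expected substitutions per site).
    Leaves become the panel records; identical leaf sequences share a truth
    allele class.
    """
    model.validate()
    if rng is None:
        rng = np.random.default_rng(model.seed)
    params = AnnotatorParams()
    log: list[MutationEvent] = []
    seqs: dict[int, str] = {}
    records: list[SequenceRecord] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = root_record.seq
        else:
            if node.edge.length is None:
                raise ValueError("tree has edges without branch lengths")
            label = node.taxon.label if node.taxon else f"internal_{id(node)}"
            seqs[id(node)] = _mutate_branch(
                seqs[id(node.parent_node)], node.edge.length, rng, model, label, log, params
            )
        if node.is_leaf():
            records.append(
                SequenceRecord(id=node.taxon.label, seq=seqs[id(node)], source="simulated")
            )
    truth_allele = _allele_classes(records)
    return SimulatedPanel(
        records=records,
        truth_group={r.id: group for r in records},
        truth_allele=truth_allele,
        tree=tree,
        truth_subgroup={r.id: subgroup for r in records},
        events=log,
    )


def _allele_classes(records: Sequence[SequenceRecord]) -> dict[str, str]:
    classes: dict[str, str] = {}
    out: dict[str, str] = {}
    for r in sorted(records, key=lambda r: r.id):
        if r.seq not in classes:
            classes[r.seq] = f"c{len(classes) + 1}"
        out[r.id] = classes[r.seq]
    return out


# ---------------------------------------------------------------------------
# panel generation

#: default subgroup architectures (see module docstring); proportions echo
#: the relative subgroup sizes seen in germplasm panels of this species
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "A-1-a": ArchetypeSpec(
        group="A", subgroup="A-1-a", n_units=5, unit_length=60, ga_rich_count=6,
        gtaagt_count=0, ctttt_present=False,
    ),
    "A-1-b": ArchetypeSpec(
        group="A", subgroup="A-1-b", n_units=8, unit_length=60, ga_rich_count=8,
        gtaagt_count=0, ctttt_present=False,
    ),
    "A-2": ArchetypeSpec(
        group="A", subgroup="A-2", n_units=11, unit_length=60, ga_rich_count=11,
        gtaagt_count=0, ctttt_present=False,
    ),
    "A-3": ArchetypeSpec(
        group="A", subgroup="A-3", n_units=8, unit_length=65, ga_rich_count=8,
        gtaagt_count=1, ctttt_present=False,
    ),
    "A-4-a": ArchetypeSpec(
        group="A", subgroup="A-4-a", n_units=9, unit_length=62, ga_rich_count=9,
        gtaagt_count=1, ctttt_present=True, insert_seq=INSERT65,
    ),
    "A-4-b": ArchetypeSpec(
        group="A", subgroup="A-4-b", n_units=9, unit_length=62, ga_rich_count=9,
        gtaagt_count=1, ctttt_present=True, insert_seq=INSERT39,
    ),
    "B-5": ArchetypeSpec(
        group="B", subgroup="B-5", n_units=9, unit_length=65, ga_rich_count=11,
        gtaagt_count=9, has_extension=False, polyT_len=11, ctttt_present=True,
        include_dra1=True,
    ),
    "B-6": ArchetypeSpec(
        group="B", subgroup="B-6", n_units=10, unit_length=62, ga_rich_count=13,
        gtaagt_count=10, has_extension=False, ctttt_present=True,
        include_hindiii=True, include_dra1=True,
        insert_seq=FRAG43 + FRAG43 + FRAG43[:21],
    ),
    "B-7": ArchetypeSpec(
        group="B", subgroup="B-7", n_units=11, unit_length=62, ga_rich_count=14,
        gtaagt_count=11, has_extension=False, ctttt_present=False,
        include_hindiii=True, include_dra1=True,
    ),
    "B-8": ArchetypeSpec(
        group="B", subgroup="B-8", n_units=12, unit_length=62, ga_rich_count=15,
        gtaagt_count=12, has_extension=False, ctttt_present=True,
        include_hindiii=True, include_dra1=True,
    ),
}

SUBGROUP_PROPORTIONS_A = {"A-1-a": 0.25, "A-1-b": 0.25, "A-2": 0.15, "A-3": 0.15, "A-4-a": 0.12, "A-4-b": 0.08}
SUBGROUP_PROPORTIONS_B = {"B-5": 0.07, "B-6": 0.13, "B-7": 0.40, "B-8": 0.40}


@dataclass
class PanelConfig:
    n_A: int = 15
    n_B: int = 15
    model: MutationModel = field(default_factory=MutationModel)
    seed: int = 0
    #: mean branch length within subgroup subtrees (subs/site)
    mean_branch: float = 0.004
    #: stem branch from the root to each group clade
    stem: float = 0.008
    subgroup_proportions_A: dict[str, float] = field(
        default_factory=lambda: dict(SUBGROUP_PROPORTIONS_A)
    )
    subgroup_proportions_B: dict[str, float] = field(
        default_factory=lambda: dict(SUBGROUP_PROPORTIONS_B)
    )


def _allocate(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n leaves to subgroups."""
    if n == 0:
        return {}
    items = sorted(proportions.items())
    raw = [(name, n * p) for name, p in items]
    counts = {name: int(math.floor(x)) for name, x in raw}
    rem = n - sum(counts.values())
    frac_order = sorted(raw, key=lambda t: (-(t[1] - math.floor(t[1])), t[0]))
    for name, _ in frac_order[:rem]:
        counts[name] += 1
    return {k: v for k, v in counts.items() if v > 0}


def _random_subtree(leaves: list[str], rng: np.random.Generator, mean_branch: float) -> str:
    if len(leaves) == 1:
        return f"{leaves[0]}:{rng.exponential(mean_branch):.6f}"
    k = int(rng.integers(1, len(leaves)))
    left = _random_subtree(leaves[:k], rng, mean_branch)
    right = _random_subtree(leaves[k:], rng, mean_branch)
    return f"({left},{right}):{rng.exponential(mean_branch):.6f}"


def generate_panel(config: PanelConfig) -> SimulatedPanel:
    """One group-A and one group-B clade joined at the root.

    Subgroup clades evolve from their own archetypes, so truth subgroup
    labels are exact; between-subgroup divergence enters through the
    archetype differences rather than simulated stem mutations.
    """
    if config.n_A + config.n_B < 3:
        raise ValueError("panel needs at least 3 leaves (n_A + n_B >= 3)")
    rng = np.random.default_rng(config.seed)
    records: list[SequenceRecord] = []
    truth_group: dict[str, str] = {}
    truth_subgroup: dict[str, str] = {}
    events: list[MutationEvent] = []
    group_newicks: list[str] = []
    for grp, n, props in (
        ("A", config.n_A, config.subgroup_proportions_A),
        ("B", config.n_B, config.subgroup_proportions_B),
    ):
        if n == 0:
            continue
        alloc = _allocate(n, props)
        sub_newicks: list[str] = []
        idx = 1
        for sub, k in sorted(alloc.items()):
            leaves = [f"{grp}{idx + j:03d}" for j in range(k)]
            idx += k
            newick = _random_subtree(leaves, rng, config.mean_branch)
            sub_tree = tree_from_string(f"({newick});")
            arche_seed = int(rng.integers(2**31 - 1))
            root = build_archetype(ARCHETYPES[sub], arche_seed)
            sub_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
            panel = evolve_on_tree(sub_tree, root, config.model, grp, sub, rng=sub_rng)
            records.extend(panel.records)
            events.extend(panel.events)
            for r in panel.records:
                truth_group[r.id] = grp
                truth_subgroup[r.id] = sub
            sub_newicks.append(newick)
        if len(sub_newicks) == 1:
            group_newicks.append(f"({sub_newicks[0]}):{config.stem:.6f}")
        else:
            group_newicks.append(f"({','.join(sub_newicks)}):{config.stem:.6f}")
    tree = tree_from_string(f"({','.join(group_newicks)});")
    return SimulatedPanel(
        records=records,
        truth_group=truth_group,
        truth_allele=_allele_classes(records),
        tree=tree,
        truth_subgroup=truth_subgroup,
        events=events,
    )
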