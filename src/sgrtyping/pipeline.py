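"""End-to-end orchestration: simulate/load → annotate → alleles → classify →
align → parsimony → geo summary, with a manifest for reproducibility.

The configuration is a flat, fully-defaulted key space that round-trips
through YAML; unknown keys are errors so a typo cannot silently fall back
to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .alleles import call_alleles, collapse_snp_only, diversity_summary, table_to_dataframe
from .annotate import AnnotatorParams, annotate, decompose_units, format_decomposition, profiles_to_dataframe
from .align import align_panel, score_alignment
from .classify import ClassifierParams, classifications_to_dataframe, classify_panel, geo_partition_summary
from .io import (
    Alignment,
    read_alignment,
    read_fasta,
    read_metadata,
    read_tree,
    write_alignment,
    write_fasta,
    write_tree,
)
from .parsimony import best_tree_small, bipartition_group_counts, parsimony_report
from .simulate import MutationModel, PanelConfig, SimulatedPanel, generate_panel

log = logging.getLogger("sgrtyping")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; every tunable has a default."""

    # inputs: either a FASTA path or a simulated panel
    fasta: str | None = None
    metadata: str | None = None
    tree: str | None = None
    alignment: str | None = None  # pre-computed external alignment (FASTA)
    # simulation (used when fasta is None)
    n_A: int = 15
    n_B: int = 15
    # analysis knobs
    classifier_margin: float = 0.2
    unit_threshold: float = 0.90
    unit_gap: float = 0.45
    gap_mode: str = "missing"
    latitude_cut: float = 35.5
    max_taxa_exact: int = 9
    seed: int = 0
    outdir: str = "sgr_out"

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())


def write_panel(panel: SimulatedPanel, outdir: str | Path) -> None:
    """FASTA + truth TSV + generating newick for a simulated panel."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(panel.records, outdir / "panel.fasta")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("id\tgroup\tsubgroup\tallele_class\n")
        for r in sorted(panel.records, key=lambda r: r.id):
            fh.write(
                f"{r.id}\t{panel.truth_group[r.id]}\t{panel.truth_subgroup.get(r.id, 'none')}"
                f"\t{panel.truth_allele[r.id]}\n"
            )
    write_tree(panel.tree, outdir / "tree.nwk")


def run(config: PipelineConfig) -> dict:
    """Execute all stages; writes the report bundle to ``config.outdir``.

    Outputs: allele table TSV, annotation TSV, classification TSV, aligned
    FASTA, parsimony report JSON, geo summary JSON, run manifest JSON.
    """
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": str(outdir)}
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as e:
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
            timings[name] = round(time.time() - t0, 3)
            log.info("stage %s done in %.2fs", name, timings[name])
            return result

        return deco

    @stage("input")
    def _input():
        if config.fasta:
            path = Path(config.fasta)
            if not path.exists():
                raise FileNotFoundError(f"input FASTA not found: {path}")
            return read_fasta(path), None
        panel = generate_panel(
            PanelConfig(n_A=config.n_A, n_B=config.n_B, seed=config.seed,
                        model=MutationModel(seed=config.seed))
        )
        write_panel(panel, outdir / "simulated")
        return panel.records, panel

    records, panel = _input
    bundle["n_records"] = len(records)

    @stage("annotate")
    def _annotate():
        params = AnnotatorParams()
        profiles = [annotate(r, params) for r in records]
        decs = {r.id: decompose_units(r, p, params) for r, p in zip(records, profiles)}
        profiles_to_dataframe(profiles).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        with open(outdir / "repeat_structure.txt", "w") as fh:
            for r in records:
                fh.write(format_decomposition(r, decs[r.id]) + "\n")
        return profiles, decs

    profiles, decs = _annotate

    @stage("alleles")
    def _alleles():
        table = collapse_snp_only(call_alleles(records), records)
        table_to_dataframe(table).to_csv(outdir / "alleles.tsv", sep="\t", index=False)
        return table

    table = _alleles

    @stage("classify")
    def _classify():
        params = ClassifierParams(margin=config.classifier_margin)
        cls = classify_panel(profiles, {r.id: r.seq for r in records}, decs, params)
        classifications_to_dataframe(cls).to_csv(outdir / "classification.tsv", sep="\t", index=False)
        return cls

    classifications = _classify

    # per-group diversity uses simulation truth when available, otherwise
    # the classifier's own group calls
    groups = panel.truth_group if panel else {c.id: c.group for c in classifications}
    summary = diversity_summary(table, records, groups)
    with open(outdir / "diversity.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
    bundle["n_alleles"] = summary.n_alleles
    bundle["pct_unique"] = summary.pct_unique
    bundle["n_indel_classes"] = summary.n_indel_classes
    bundle["groups"] = {
        g: sum(1 for c in classifications if c.group == g) for g in ("A", "B", "atypical", "unassigned")
    }
    bundle["atypical_ids"] = sorted(c.id for c in classifications if c.group == "atypical")

    @stage("align")
    def _align():
        if config.alignment:
            aln = read_alignment(config.alignment)
        else:
            aln = align_panel(records, decs, threshold=config.unit_threshold, gap=config.unit_gap)
        write_alignment(aln, outdir / "alignment.fasta")
        return aln

    aln = _align
    sc = score_alignment(aln) if aln.nrows >= 2 else None
    if sc:
        bundle["alignment"] = {"length": sc.total_length, "match_fraction": round(sc.match_fraction, 4)}

    @stage("parsimony")
    def _parsimony():
        if config.tree:
            tree = read_tree(config.tree)
        elif panel is not None:
            tree = panel.tree
        elif aln.nrows <= config.max_taxa_exact:
            trees, _ = best_tree_small(aln, config.max_taxa_exact, config.gap_mode)
            tree = trees[0]
        else:
            log.warning("no tree supplied and too many taxa for exact search; skipping parsimony")
            return None, None
        rep = parsimony_report(tree, aln, config.gap_mode)
        with open(outdir / "parsimony.json", "w") as fh:
            json.dump(
                {
                    "gap_mode": rep.gap_mode,
                    "S": rep.S, "M": rep.M, "G": rep.G,
                    "CI": rep.ci, "RI": rep.ri,
                    "n_informative": rep.n_informative,
                    "n_variable": len(rep.columns),
                },
                fh,
                indent=2,
            )
        counts = bipartition_group_counts(tree, {c.id: c.group for c in classifications})
        return rep, counts

    rep, concordance = _parsimony
    if rep is not None:
        bundle["parsimony"] = {"RI": rep.ri, "CI": rep.ci, "n_informative": rep.n_informative}
        bundle["concordance"] = concordance

    @stage("geo")
    def _geo():
        if not config.metadata:
            return None
        meta = {m.id: m for m in read_metadata(config.metadata)}
        geo = geo_partition_summary(classifications, meta, config.latitude_cut)
        with open(outdir / "geo_summary.json", "w") as fh:
            json.dump(geo, fh, indent=2)
        return geo

    bundle["geo"] = _geo
    bundle["per_group"] = summary.per_group.to_dict(orient="records")

    log.info("pipeline done in %.2fs (stages: %s)", time.time() - t_start, timings)
    # wall-clock timings stay in the log so the manifest is deterministic
    manifest = {
        "package": "sgrtyping",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        "config": yaml.safe_load(config.to_yaml()),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = {k: manifest[k] for k in ("version", "seed", "config_sha256", "outputs")}
    return bundle


def report(bundle: dict) -> str:
    """One-page human-readable summary of a run bundle."""
    lines = ["SGR intron fingerprinting report", "=" * 34]
    lines.append(f"accessions        : {bundle.get('n_records', 0)}")
    lines.append(f"alleles           : {bundle.get('n_alleles', 0)}")
    lines.append(f"pct unique        : {bundle.get('pct_unique', 0.0)}")
    lines.append(f"indel classes     : {bundle.get('n_indel_classes', 0)}")
    groups = bundle.get("groups", {})
    lines.append(
        "groups            : "
        + "  ".join(f"{g}={groups.get(g, 0)}" for g in ("A", "B", "atypical", "unassigned"))
    )
    if bundle.get("atypical_ids"):
        lines.append(f"atypical ids      : {', '.join(bundle['atypical_ids'])}")
    for row in bundle.get("per_group", []):
        lines.append(
            f"  group {row['group']:<10}: n={row['n']} alleles={row['n_alleles']} "
            f"indel classes={row['n_indel_classes']} pct_unique={row['pct_unique']} "
            f"mean length={row['mean_length']}"
        )
    if "alignment" in bundle:
        a = bundle["alignment"]
        lines.append(f"alignment         : {a['length']} columns, match fraction {a['match_fraction']}")
    if "parsimony" in bundle:
        p = bundle["parsimony"]
        ri = f"{p['RI']:.4f}" if p["RI"] is not None else "undefined"
        ci = f"{p['CI']:.4f}" if p["CI"] is not None else "undefined"
        lines.append(f"parsimony         : RI={ri} CI={ci} informative sites={p['n_informative']}")
    if bundle.get("concordance"):
        s1, s2 = bundle["concordance"]
        lines.append(f"first dichotomy   : side1 {s1} | side2 {s2}")
    geo = bundle.get("geo")
    if geo:
        c = geo["counts"]
        lines.append(
            f"latitude {geo['latitude_cut']}N   : north A={c['north']['A']} B={c['north']['B']} "
            f"| south A={c['south']['A']} B={c['south']['B']}"
        )
    return "\n".join(lines) + "\n"
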