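"""Fitch/Hartigan step counts, CI/RI, informative sites, exact tree search,
bipartition tallies — each checked against an independent brute-force oracle."""

import itertools

import numpy as np
import pytest

from sgrtyping.io import Alignment, tree_from_string
from sgrtyping.parsimony import (
    best_tree_small,
    bipartition_group_counts,
    column_states,
    fitch_steps,
    informative_sites,
    parsimony_report,
)


def brute_force_steps(tree, states) -> int:
    """Oracle: exhaustive minimization over internal-node state assignments."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    observed = sorted({s for s in states.values() if s is not None})
    if not observed:
        return 0
    best = None
    for assign in itertools.product(observed, repeat=len(internals)):
        amap = {id(n): a for n, a in zip(internals, assign)}
        cost = 0
        for n in tree.preorder_node_iter():
            p = n.parent_node
            if p is None:
                continue
            sn = states.get(n.taxon.label) if n.is_leaf() else amap[id(n)]
            if sn is not None and sn != amap[id(p)]:
                cost += 1
        best = cost if best is None else min(best, cost)
    return best


def random_tree(taxa, rng):
    def rec(lv):
        if len(lv) == 1:
            return lv[0]
        k = int(rng.integers(1, len(lv)))
        return f"({rec(lv[:k])},{rec(lv[k:])})"

    return tree_from_string(rec(list(taxa)) + ";")


class TestFitchSteps:
    @pytest.mark.parametrize(
        "states,expected",
        [
            ({"a": "A", "b": "A", "c": "T", "d": "T"}, 1),
            ({"a": "A", "b": "T", "c": "A", "d": "T"}, 2),
            ({"a": "A", "b": "A", "c": "A", "d": "A"}, 0),
            ({"a": "A", "b": None, "c": "T", "d": None}, 1),
        ],
    )
    def test_four_leaf_examples(self, states, expected):
        tree = tree_from_string("((a,b),(c,d));")
        assert fitch_steps(tree, states) == expected

    def test_polytomy_star_tree(self):
        # three distinct states at a single polytomy need two changes
        tree = tree_from_string("(a,b,c);")
        assert fitch_steps(tree, {"a": "A", "b": "C", "c": "G"}) == 2

    def test_missing_leaf_without_policy_errors(self):
        tree = tree_from_string("((a,b),(c,d));")
        with pytest.raises(KeyError, match="d"):
            fitch_steps(tree, {"a": "A", "b": "A", "c": "T"})

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 8))
            taxa = [f"t{i}" for i in range(n)]
            tree = random_tree(taxa, rng)
            states = {
                t: (None if rng.random() < 0.2 else "ACGT"[rng.integers(4)]) for t in taxa
            }
            assert fitch_steps(tree, states) == brute_force_steps(tree, states)


class TestInformativeSites:
    def test_two_by_two_column_is_informative(self):
        aln = Alignment(ids=list("abcd"), rows=["A", "A", "T", "T"])
        assert informative_sites(aln)[0] == 1

    def test_singleton_column_is_not(self):
        aln = Alignment(ids=list("abcd"), rows=["A", "A", "A", "T"])
        assert informative_sites(aln)[0] == 0

    def test_random_alignment_matches_column_audit(self):
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("ACGT-N"), size=20)) for _ in range(6)]
        aln = Alignment(ids=[f"s{i}" for i in range(6)], rows=rows)
        for gap_mode in ("missing", "fifth_state"):
            n, cols = informative_sites(aln, gap_mode)
            audit = []
            for j in range(20):
                states = [s for s in column_states(aln.column(j), gap_mode) if s is not None]
                counts = {s: states.count(s) for s in set(states)}
                if sum(1 for v in counts.values() if v >= 2) >= 2:
                    audit.append(j)
            assert cols == audit and n == len(audit)

    def test_gap_modes_agree_on_gapless_alignment(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(5)]
        aln = Alignment(ids=[f"s{i}" for i in range(5)], rows=rows)
        assert informative_sites(aln, "missing") == informative_sites(aln, "fifth_state")


class TestParsimonyReport:
    def test_tree_compatible_data_gives_ri_one(self):
        tree = tree_from_string("((a,b),(c,d));")
        aln = Alignment(ids=list("abcd"), rows=["AAC", "AAC", "TAG", "TAG"])
        rep = parsimony_report(tree, aln)
        assert rep.ri == 1.0

    def test_conflicting_column_contributes_zero_retention(self):
        tree = tree_from_string("((a,b),(c,d));")
        aln = Alignment(ids=list("abcd"), rows=["A", "T", "A", "T"])
        rep = parsimony_report(tree, aln)
        assert rep.steps == [2] and rep.min_steps == [1] and rep.max_steps == [2]
        assert rep.ri == 0.0

    def test_column_invariant_m_le_s_le_g(self, small_panel, small_panel_annotated):
        from sgrtyping.align import align_panel

        _, decs = small_panel_annotated
        aln = align_panel(small_panel.records, decs)
        rep = parsimony_report(small_panel.tree, aln)
        for s, m, g in zip(rep.steps, rep.min_steps, rep.max_steps):
            assert m <= s <= g
        assert rep.ri is None or 0.0 <= rep.ri <= 1.0

    def test_constant_alignment_flagged_undefined(self):
        tree = tree_from_string("((a,b),(c,d));")
        aln = Alignment(ids=list("abcd"), rows=["AAAA"] * 4)
        rep = parsimony_report(tree, aln)
        assert not rep.ri_defined and rep.ri is None and rep.ci is None

    def test_gap_modes_identical_on_gapless(self):
        tree = tree_from_string("((a,b),(c,d),e);")
        rng = np.random.default_rng(11)
        rows = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(5)]
        aln = Alignment(ids=list("abcde"), rows=rows)
        r1 = parsimony_report(tree, aln, "missing")
        r2 = parsimony_report(tree, aln, "fifth_state")
        assert (r1.S, r1.M, r1.G, r1.ri) == (r2.S, r2.M, r2.G, r2.ri)


class TestBestTreeSmall:
    def test_informative_column_groups_the_pair(self):
        aln = Alignment(ids=list("abcd"), rows=["A", "A", "T", "T"])
        trees, score = best_tree_small(aln)
        assert score == 1
        labels = {frozenset(
            l.taxon.label for l in t.seed_node.child_nodes()[0].leaf_iter()
        ) for t in trees}
        # the winning topology separates {a,b} from {c,d}
        rep = parsimony_report(trees[0], aln)
        assert rep.S == 1

    def test_constant_alignment_all_topologies_tie(self):
        aln = Alignment(ids=list("abcde"), rows=["AAAA"] * 5)
        trees, score = best_tree_small(aln)
        assert score == 0 and len(trees) == 15

    def test_recovers_generating_topology_from_snps(self):
        # five leaves; clades {a,b} and {d,e} each supported by two columns
        rows = {
            "a": "AATTGGCC",
            "b": "AATTGGCA",
            "c": "TTTTGGCA",
            "d": "TTAAGGCA",
            "e": "TTAACGCA",
        }
        aln = Alignment(ids=list(rows), rows=list(rows.values()))
        trees, _ = best_tree_small(aln)
        found = False
        for t in trees:
            bips = {
                frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                for e in t.preorder_edge_iter()
                if e.head_node is not None
            }
            if frozenset("ab") in bips and (frozenset("de") in bips or frozenset("abc") in bips):
                found = True
        assert found

    def test_too_many_taxa_directs_elsewhere(self):
        aln = Alignment(ids=[f"s{i}" for i in range(12)], rows=["ACGT"] * 12)
        with pytest.raises(ValueError, match="external"):
            best_tree_small(aln, max_taxa=9)


class TestBipartitionCounts:
    def test_root_dichotomy(self):
        tree = tree_from_string("((a,b),(c,d));")
        s1, s2 = bipartition_group_counts(tree, {"a": "A", "b": "A", "c": "B", "d": "B"})
        assert s1 == {"A": 2} and s2 == {"B": 2}

    def test_single_label_sums_to_leaf_count(self):
        tree = tree_from_string("((a,b),(c,(d,e)));")
        s1, s2 = bipartition_group_counts(tree, {x: "A" for x in "abcde"})
        assert sum(s1.values()) + sum(s2.values()) == 5

    def test_unlabeled_leaves_counted_as_other(self):
        tree = tree_from_string("((a,b),(c,d));")
        s1, s2 = bipartition_group_counts(tree, {"a": "A"})
        assert s1.get("other", 0) + s2.get("other", 0) == 3

    def test_matches_leaf_set_oracle_on_random_trees(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(4, 10))
            taxa = [f"t{i}" for i in range(n)]
            tree = random_tree(taxa, rng)
            labels = {t: ("A" if rng.random() < 0.5 else "B") for t in taxa}
            s1, s2 = bipartition_group_counts(tree, labels)
            side1 = {l.taxon.label for l in tree.seed_node.child_nodes()[0].leaf_iter()}
            exp1 = {}
            exp2 = {}
            for t in taxa:
                d = exp1 if t in side1 else exp2
                d[labels[t]] = d.get(labels[t], 0) + 1
            assert s1 == exp1 and s2 == exp2

    def test_foreign_edge_rejected(self):
        tree = tree_from_string("((a,b),(c,d));")
        other = tree_from_string("((a,b),(c,d));")
        foreign = other.seed_node.child_nodes()[0].edge
        with pytest.raises(ValueError):
            bipartition_group_counts(tree, {}, edge=foreign)
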