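"""Repeat-aware alignment: unit similarity, token DP, tandem preservation,
nucleotide projection, homology-priority scoring."""

import itertools

import pytest

from sgrtyping.align import (
    AlignmentScore,
    UnitToken,
    align_panel,
    align_unit_strings,
    project_to_nucleotides,
    score_alignment,
    tokenize,
    unit_similarity,
)
from sgrtyping.annotate import annotate, decompose_units
from sgrtyping.io import Alignment, SequenceRecord, tree_from_string
from sgrtyping.simulate import ARCHETYPES, MutationModel, build_archetype, evolve_on_tree


def mk_tokens(owner: str, seqs: list[str]) -> list[UnitToken]:
    toks, pos = [], 0
    out = []
    for i, s in enumerate(seqs):
        out.append(UnitToken(owner=owner, index=i, span=(pos, pos + len(s)), sequence=s))
        pos += len(s)
    return out


X = "ACGTACGTACGTACGTACGT"
Y = "TTTTCCCCGGGGAAAATTCC"


class TestUnitSimilarity:
    def test_identical_units(self):
        assert unit_similarity(X, X) == 1.0

    def test_hand_alignment(self):
        assert unit_similarity("ACGTACGT", "ACGTACGA") == pytest.approx(7 / 8)

    def test_disjoint_alphabets(self):
        assert unit_similarity("AAAA", "GGGG") == 0.0

    def test_empty_unit(self):
        assert unit_similarity("", "ACGT") == 0.0


class TestAlignUnitStrings:
    def test_identical_lists_no_gaps(self):
        a = mk_tokens("a", [X, Y, X])
        b = mk_tokens("b", [X, Y, X])
        ua = align_unit_strings([a, b])
        assert ua.length == 3
        assert all(t is not None for row in ua.rows for t in row)

    def test_duplicate_kept_tandem(self):
        a = mk_tokens("a", [X, X, Y])
        b = mk_tokens("b", [X, Y])
        ua = align_unit_strings([a, b])
        assert ua.length == 3
        row_b = ua.rows[1]
        gap_cols = [i for i, t in enumerate(row_b) if t is None]
        assert len(gap_cols) == 1
        g = gap_cols[0]
        # the surplus X sits in a column adjacent to a matched X column
        row_a = ua.rows[0]
        assert row_a[g].sequence == X
        neighbors = [row_a[i] for i in (g - 1, g + 1) if 0 <= i < ua.length]
        assert any(t is not None and unit_similarity(t, row_a[g]) >= 0.9 for t in neighbors)

    def test_dissimilar_single_units_align_as_substitution_when_gaps_dear(self):
        a = mk_tokens("a", ["AAAAAAAA"])
        b = mk_tokens("b", ["GGGGGGGG"])
        # with 2*gap > 1 a single substitution column beats two gap columns
        ua = align_unit_strings([a, b], gap=0.6)
        assert ua.length == 1
        assert ua.rows[0][0] is not None and ua.rows[1][0] is not None

    def test_empty_token_list_gives_all_gap_row(self):
        a = mk_tokens("a", [X, Y])
        ua = align_unit_strings([a, []], ids=["a", "b"])
        assert ua.length == 2
        assert all(t is None for t in ua.rows[1])

    def test_matches_token_needleman_wunsch_oracle(self):
        """With threshold=1.0 and no duplicated units, the tandem re-pack is
        inert and the result must be plain score-optimal token-level
        Needleman-Wunsch; verified by exhaustive alignment enumeration."""
        gap = 0.45
        threshold = 1.0

        def sub(u, v):
            s = unit_similarity(u, v)
            return s if s >= threshold else 0.1 * s - 2.0 * gap

        def brute_best(sa, sb):
            # enumerate all monotone matchings
            best = -1e9
            na, nb = len(sa), len(sb)
            for k in range(min(na, nb) + 1):
                for ia in itertools.combinations(range(na), k):
                    for ib in itertools.combinations(range(nb), k):
                        sc = sum(sub(sa[x], sb[y]) for x, y in zip(ia, ib))
                        sc -= gap * (na - k + nb - k)
                        best = max(best, sc)
            return best

        units = ["AAAACCCC", "GGGGTTTT", "ACACACAC", "GTGTGTGT", "AATTCCGG"]
        cases = [
            (units[:3], units[1:4]),
            (units[:4], [units[0], units[2]]),
            ([units[4]], units[:3]),
        ]
        for sa, sb in cases:
            a = mk_tokens("a", sa)
            b = mk_tokens("b", sb)
            ua = align_unit_strings([a, b], threshold=threshold, gap=gap)
            got = 0.0
            for ta, tb in zip(ua.rows[0], ua.rows[1]):
                if ta is not None and tb is not None:
                    got += sub(ta, tb)
                else:
                    got -= gap
            assert got == pytest.approx(brute_best(sa, sb), abs=1e-9)


class TestProjection:
    def _decomposed(self, records):
        decs = {}
        for r in records:
            decs[r.id] = decompose_units(r, annotate(r))
        return decs

    def test_identical_sequences_gapless(self):
        root = build_archetype(ARCHETYPES["A-1-b"], seed=3)
        r1 = SequenceRecord(id="a", seq=root.seq)
        r2 = SequenceRecord(id="b", seq=root.seq)
        recs = [r1, r2]
        aln = align_panel(recs, self._decomposed(recs))
        assert "-" not in aln.rows[0] and "-" not in aln.rows[1]
        assert aln.ungapped("a") == root.seq

    def test_single_duplication_gives_one_unit_gap_block(self):
        # head-to-tail copy of one whole unit, by construction
        root = build_archetype(ARCHETYPES["A-1-b"], seed=5)
        a = SequenceRecord(id="a", seq=root.seq)
        dec = decompose_units(a, annotate(a))
        s, e = dec.units[2].start, dec.units[2].end
        b = SequenceRecord(id="b", seq=a.seq[:e] + a.seq[s:e] + a.seq[e:])
        recs = [a, b]
        aln = align_panel(recs, self._decomposed(recs))
        row_a = aln.row("a")
        runs, i = [], 0
        while i < len(row_a):
            if row_a[i] == "-":
                j = i
                while j < len(row_a) and row_a[j] == "-":
                    j += 1
                runs.append(j - i)
                i = j
            else:
                i += 1
        assert runs == [e - s]

    def test_round_trip_on_panel(self, small_panel, small_panel_annotated):
        _, decs = small_panel_annotated
        aln = align_panel(small_panel.records, decs)  # raises internally if lossy
        for r in small_panel.records:
            assert aln.ungapped(r.id) == r.seq


class TestScoreAlignment:
    def test_identical_rows(self):
        aln = Alignment(ids=["a", "b"], rows=["ACGT", "ACGT"])
        assert score_alignment(aln).match_fraction == 1.0

    def test_hand_count_with_gap(self):
        aln = Alignment(ids=["a", "b"], rows=["AC-T", "ACGT"])
        sc = score_alignment(aln)
        assert sc.match_fraction == 1.0  # 3 aligned non-gap columns, 3 matches
        assert sc.total_length == 4

    def test_homology_priority_comparator(self):
        better = AlignmentScore(match_fraction=0.90, total_length=5200)
        worse = AlignmentScore(match_fraction=0.88, total_length=5000)
        assert better < worse  # homology beats length
        assert sorted([worse, better])[0] is better

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            score_alignment(Alignment(ids=["a"], rows=["ACGT"]))
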