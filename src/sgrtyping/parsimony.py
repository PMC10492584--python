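"""Parsimony statistics on tree + alignment pairs.

Implements unweighted (Fitch) parsimony step counts — via Hartigan's
bottom-up algorithm, which is exact for multifurcating trees and reduces to
the familiar two-pass Fitch count on binary trees — plus the derived
consistency index CI = M/S and retention index RI = (G - S)/(G - M), where
per column s is the observed step count on the tree, m = (number of
distinct states) - 1 is the minimum on any tree, and g = (non-missing
leaves) - (count of the most frequent state) is the maximum, attained on
the star tree.  RI near 1 means character change concentrates on internal
branches (shared, homology-like); RI near 0 means change concentrates on
terminal branches (homoplasy-like).

Gap handling is the main lever when comparing against published numbers, so
both treatments are first-class: ``gap_mode="missing"`` (gaps and N carry no
state, the common parsimony-software default) and ``gap_mode="fifth_state"``
(a gap is a fifth character state; N stays missing).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .io import Alignment, tree_from_string

GAP_MODES = ("missing", "fifth_state")


def column_states(column: str, gap_mode: str = "missing") -> list[str | None]:
    """Per-row character states; None marks missing data."""
    if gap_mode not in GAP_MODES:
        raise ValueError(f"gap_mode must be one of {GAP_MODES}")
    out: list[str | None] = []
    for c in column:
        if c == "N":
            out.append(None)
        elif c == "-":
            out.append("-" if gap_mode == "fifth_state" else None)
        else:
            out.append(c)
    return out


def informative_sites(alignment: Alignment, gap_mode: str = "missing") -> tuple[int, list[int]]:
    """Columns where >= 2 distinct states each occur in >= 2 rows."""
    cols: list[int] = []
    for j in range(alignment.length):
        states = [s for s in column_states(alignment.column(j), gap_mode) if s is not None]
        counts: dict[str, int] = {}
        for s in states:
            counts[s] = counts.get(s, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            cols.append(j)
    return len(cols), cols


def fitch_steps(tree: dendropy.Tree, leaf_states: Mapping[str, str | None]) -> int:
    """Minimum number of state changes on the tree for one character.

    ``leaf_states`` maps leaf labels to states; ``None`` marks missing data,
    which never forces a change.  Every non-missing leaf must be present in
    the mapping's domain of tree leaves; a tree leaf absent from the mapping
    is an error.  The tree may be multifurcating; an unrooted tree is scored
    from its seed node (the count is root-invariant).
    """
    steps = 0
    sets: dict[int, frozenset[str] | None] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in leaf_states:
                raise KeyError(f"leaf {label!r} has no character state and no missing-policy")
            s = leaf_states[label]
            sets[id(node)] = frozenset([s]) if s is not None else None
        else:
            child_sets = [sets[id(c)] for c in node.child_nodes()]
            child_sets = [s for s in child_sets if s is not None]
            if not child_sets:
                sets[id(node)] = None
                continue
            counts: dict[str, int] = {}
            for s in child_sets:
                for st in s:
                    counts[st] = counts.get(st, 0) + 1
            k = max(counts.values())
            sets[id(node)] = frozenset(st for st, v in counts.items() if v == k)
            steps += len(child_sets) - k
    return steps


@dataclass
class ParsimonyReport:
    gap_mode: str
    columns: list[int]
    steps: list[int]           # s_i, observed on the tree
    min_steps: list[int]       # m_i
    max_steps: list[int]       # g_i
    S: int
    M: int
    G: int
    ci: float | None
    ri: float | None
    n_informative: int
    ri_defined: bool = True

    def summary(self) -> str:
        lines = [
            f"variable columns : {len(self.columns)}",
            f"informative sites: {self.n_informative}",
            f"steps S={self.S}  min M={self.M}  max G={self.G}",
            f"CI = {self.ci:.4f}" if self.ci is not None else "CI undefined",
            f"RI = {self.ri:.4f}" if self.ri is not None else "RI undefined (no homoplasy-informative columns)",
        ]
        return "\n".join(lines)


def parsimony_report(
    tree: dendropy.Tree,
    alignment: Alignment,
    gap_mode: str = "missing",
) -> ParsimonyReport:
    """Per-column and total parsimony statistics for a tree+alignment pair.

    Totals run over variable columns (>= 2 observed states); columns with
    g = m carry no retention information and are excluded from the RI sums.
    """
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    missing_rows = [i for i in alignment.ids if i not in leaf_labels]
    if missing_rows:
        raise ValueError(f"alignment rows absent from tree: {missing_rows}")
    cols: list[int] = []
    s_list: list[int] = []
    m_list: list[int] = []
    g_list: list[int] = []
    ri_G = ri_M = ri_S = 0
    for j in range(alignment.length):
        states = column_states(alignment.column(j), gap_mode)
        observed = [s for s in states if s is not None]
        uniq: dict[str, int] = {}
        for s in observed:
            uniq[s] = uniq.get(s, 0) + 1
        if len(uniq) < 2:
            continue
        m = len(uniq) - 1
        g = len(observed) - max(uniq.values())
        leaf_states = dict(zip(alignment.ids, states))
        s = fitch_steps(tree, leaf_states)
        cols.append(j)
        s_list.append(s)
        m_list.append(m)
        g_list.append(g)
        if g > m:
            ri_G += g
            ri_M += m
            ri_S += s
    S, M, G = sum(s_list), sum(m_list), sum(g_list)
    ci = M / S if S > 0 else None
    ri_defined = ri_G > ri_M
    ri = (ri_G - ri_S) / (ri_G - ri_M) if ri_defined else None
    n_inf, _ = informative_sites(alignment, gap_mode)
    return ParsimonyReport(
        gap_mode=gap_mode,
        columns=cols,
        steps=s_list,
        min_steps=m_list,
        max_steps=g_list,
        S=S,
        M=M,
        G=G,
        ci=ci,
        ri=ri,
        n_informative=n_inf,
        ri_defined=ri_defined,
    )


# ---------------------------------------------------------------------------
# exhaustive small-scale tree search

N_UNROOTED = {3: 1, 4: 3, 5: 15, 6: 105, 7: 945, 8: 10395, 9: 135135}


def _enumerate_topologies(taxa: Sequence[str]):
    """Yield all unrooted binary topologies as (edges, next_node_id).

    Nodes 0..n-1 are the taxa; internal nodes get higher ids.  Trees are
    built by stepwise addition: taxon k is attached to every edge of every
    (k-1)-taxon tree.
    """
    n = len(taxa)
    base = [frozenset([(0, n), (1, n), (2, n)])] if n >= 3 else []
    trees = [(e, n + 1) for e in base]
    for k in range(3, n):
        nxt = []
        for edges, nid in trees:
            for u, v in edges:
                new_edges = set(edges)
                new_edges.remove((u, v))
                new_edges |= {(u, nid), (v, nid), (k, nid)}
                nxt.append((frozenset(new_edges), nid + 1))
        trees = nxt
    return trees


def _edges_to_newick(edges: Iterable[tuple[int, int]], taxa: Sequence[str]) -> str:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = max(adj)  # an internal node

    def sub(node: int, parent: int) -> str:
        children = [c for c in adj[node] if c != parent]
        if not children:
            return taxa[node]
        return "(" + ",".join(sub(c, node) for c in children) + ")"

    return sub(root, -1) + ";"


def _score_topology(edges, n_taxa: int, columns: list[dict[int, str | None]]) -> int:
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = max(adj)
    order: list[tuple[int, int]] = []  # (node, parent) postorder
    stack = [(root, -1)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        for c in adj[node]:
            if c != parent:
                stack.append((c, node))
    order.reverse()
    total = 0
    for col in columns:
        sets: dict[int, frozenset | None] = {}
        steps = 0
        for node, parent in order:
            if node < n_taxa:
                s = col.get(node)
                sets[node] = frozenset([s]) if s is not None else None
            else:
                child_sets = [sets[c] for c in adj[node] if c != parent]
                child_sets = [s for s in child_sets if s is not None]
                if not child_sets:
                    sets[node] = None
                    continue
                counts: dict[str, int] = {}
                for s in child_sets:
                    for st in s:
                        counts[st] = counts.get(st, 0) + 1
                k = max(counts.values())
                sets[node] = frozenset(st for st, v in counts.items() if v == k)
                steps += len(child_sets) - k
        total += steps
    return total


def best_tree_small(
    alignment: Alignment,
    max_taxa: int = 9,
    gap_mode: str = "missing",
) -> tuple[list[dendropy.Tree], int]:
    """Exhaustive most-parsimonious search over unrooted binary topologies.

    Practical only at desk scale (3, 15, 105, 945, 10395, 135135 topologies
    for 4-9 taxa); beyond ``max_taxa`` use external heuristic-search tools
    and feed the resulting newick to :func:`parsimony_report`.  Returns all
    minimal-score trees and the score.
    """
    taxa = list(alignment.ids)
    n = len(taxa)
    if n > max_taxa:
        raise ValueError(
            f"{n} taxa exceeds max_taxa={max_taxa}; run an external heuristic "
            "tree search and supply the tree instead"
        )
    if n < 3:
        raise ValueError("need at least 3 taxa")
    columns: list[dict[int, str | None]] = []
    for j in range(alignment.length):
        states = column_states(alignment.column(j), gap_mode)
        uniq = {s for s in states if s is not None}
        if len(uniq) >= 2:
            columns.append({i: s for i, s in enumerate(states)})
    best: list = []
    best_score: int | None = None
    for edges, _ in _enumerate_topologies(taxa):
        score = _score_topology(edges, n, columns)
        if best_score is None or score < best_score:
            best_score = score
            best = [edges]
        elif score == best_score:
            best.append(edges)
    trees = [tree_from_string(_edges_to_newick(e, taxa)) for e in best]
    return trees, int(best_score or 0)


def bipartition_group_counts(
    tree: dendropy.Tree,
    labels: Mapping[str, str],
    edge: dendropy.Edge | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Tally group labels on the two sides of a branch.

    Default branch: the tree's first dichotomy (the edge below the first
    child of the root).  Leaves absent from ``labels`` count as ``other``.
    """
    if edge is None:
        children = tree.seed_node.child_nodes()
        if not children:
            raise ValueError("tree has no internal structure")
        edge = children[0].edge
    else:
        if edge not in set(tree.preorder_edge_iter()):
            raise ValueError("edge is not part of the tree")
    side1_leaves = {l.taxon.label for l in edge.head_node.leaf_iter()}
    all_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    side2_leaves = all_leaves - side1_leaves

    def tally(leaves) -> dict[str, int]:
        out: dict[str, int] = {}
        for l in sorted(leaves):
            g = labels.get(l, "other")
            out[g] = out.get(g, 0) + 1
        return out

    return tally(side1_leaves), tally(side2_leaves)
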