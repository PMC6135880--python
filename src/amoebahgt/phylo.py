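"""Distance trees and transfer-direction inference.

Trees are built by classical neighbor joining on Poisson-corrected protein
distances from pre-aligned, equal-length sequences (multiple-alignment
construction is delegated to an external aligner when real data demand it;
the synthetic gene families here are generated ungapped).  Direction calls
operationalise the "most parsimonious scenario" reading of a gene tree as
explicit nesting rules:

* ``virus_to_amoeba`` — the amoebal leaves (query included) form a clade whose
  sister is exclusively viral, while the viral leaves themselves are
  paraphyletic with respect to that clade (the amoebal gene is nested inside
  viral diversity);
* ``amoeba_to_virus`` — the mirror image; viral leaves form a clade nested
  inside amoebal paraphyly;
* anything else — ``inconclusive``.

Rooting prefers an ``other_cellular`` outgroup leaf and falls back to
midpoint rooting; the choice is recorded in the call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import ArgumentError, DataError

GROUPS = ("query", "amoeba", "virus", "other_cellular")

#: distance assigned when the observed mismatch fraction p >= 0.95
DISTANCE_CEILING = 3.0


@dataclass(frozen=True)
class LabeledTree:
    """A gene tree with leaves assigned to query/amoeba/virus/other_cellular."""

    newick: str
    groups: dict[str, str]

    def __post_init__(self):
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ArgumentError("leaf labels must be unique")
        unknown = [l for l in labels if l not in self.groups]
        if unknown:
            raise ArgumentError(f"leaves without group assignment: {unknown}")
        bad = {g for g in self.groups.values() if g not in GROUPS}
        if bad:
            raise ArgumentError(f"unknown groups {sorted(bad)}")

    def leaf_labels(self) -> list[str]:
        t = dendropy.Tree.get(data=self.newick, schema="newick")
        return [leaf.taxon.label for leaf in t.leaf_node_iter()]

    def leaves_in_group(self, group: str) -> set[str]:
        return {l for l, g in self.groups.items() if g == group}


@dataclass(frozen=True)
class DirectionCall:
    """Outcome of transfer-direction inference on one gene tree."""

    direction: str  # virus_to_amoeba | amoeba_to_virus | inconclusive
    rooting: str
    note: str


# ---------------------------------------------------------------------------
# distances


def pairwise_distances(aligned: list[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    """Poisson-corrected distances d = −ln(1 − p) from an ungapped-column
    mismatch fraction p, computed over all column pairs where neither
    sequence has a gap.  p >= 0.95 clamps to ``DISTANCE_CEILING``."""
    if len(aligned) < 3:
        raise ArgumentError("need at least 3 sequences")
    length = len(aligned[0][1])
    for name, seq in aligned:
        if len(seq) != length:
            raise ArgumentError(f"sequence {name!r} has length {len(seq)} != {length}")
    labels = [name for name, _ in aligned]
    n = len(aligned)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aligned[i][1], aligned[j][1]
            comparable = mismatch = 0
            for x, y in zip(a, b):
                if x == "-" or y == "-":
                    continue
                comparable += 1
                if x != y:
                    mismatch += 1
            if comparable == 0:
                dist = DISTANCE_CEILING
            else:
                p = mismatch / comparable
                dist = DISTANCE_CEILING if p >= 0.95 else -math.log(1.0 - p)
            d[i, j] = d[j, i] = dist
    return labels, d


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(labels: list[str], matrix: np.ndarray) -> str:
    """Classical NJ agglomeration; returns an unrooted Newick string with a
    trifurcating root.

    Ties in the Q criterion are broken by the lexicographically smallest pair
    of cluster labels (a cluster carries the smallest leaf label it contains),
    so the output is deterministic and invariant to input order.  Negative
    branch lengths are clamped to 0 with the deficit moved to the sister edge.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ArgumentError("matrix shape does not match label count")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ArgumentError("distance matrix must be symmetric")
    if n < 2:
        raise ArgumentError("need at least 2 taxa")
    order = sorted(range(n), key=lambda i: labels[i])
    nodes = [(labels[i], labels[i]) for i in order]  # (newick, tie label)
    d = matrix[np.ix_(order, order)].copy()

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, min(nodes[i][1], nodes[j][1]), max(nodes[i][1], nodes[j][1]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp_pair(li, lj)
        children = sorted([(nodes[i][1], nodes[i][0], li), (nodes[j][1], nodes[j][0], lj)])
        newick = "(" + ",".join(f"{nw}:{ln:.10g}" for _, nw, ln in children) + ")"
        tie = children[0][0]
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = dk[keep]
        d_new[:-1, -1] = dk[keep]
        d_new[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [(newick, tie)]
        d = d_new

    if len(nodes) == 2:
        half = d[0, 1] / 2
        children = sorted([(nodes[0][1], nodes[0][0], half), (nodes[1][1], nodes[1][0], half)])
        return "(" + ",".join(f"{nw}:{ln:.10g}" for _, nw, ln in children) + ");"
    lengths = [
        0.5 * (d[0, 1] + d[0, 2] - d[1, 2]),
        0.5 * (d[0, 1] + d[1, 2] - d[0, 2]),
        0.5 * (d[0, 2] + d[1, 2] - d[0, 1]),
    ]
    lengths = [max(0.0, l) for l in lengths]
    children = sorted(
        (nodes[k][1], nodes[k][0], lengths[k]) for k in range(3)
    )
    return "(" + ",".join(f"{nw}:{ln:.10g}" for _, nw, ln in children) + ");"


def nj_tree(aligned: list[tuple[str, str]]) -> str:
    """Distance-tree convenience wrapper: Poisson distances then NJ."""
    labels, d = pairwise_distances(aligned)
    return neighbor_joining(labels, d)


# ---------------------------------------------------------------------------
# direction inference


def _rooted_tree(ltree: LabeledTree) -> tuple[dendropy.Tree, str]:
    tree = dendropy.Tree.get(data=ltree.newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 1.0
    outgroups = sorted(ltree.leaves_in_group("other_cellular"))
    if outgroups:
        node = tree.find_node_with_taxon_label(outgroups[0])
        tree.reroot_at_edge(node.edge, update_bipartitions=True)
        return tree, f"outgroup:{outgroups[0]}"
    tree.reroot_at_midpoint(update_bipartitions=True)
    return tree, "midpoint"


def _clade_info(tree: dendropy.Tree, leaves: set[str]) -> tuple[bool, set[str]]:
    """(is the leaf set monophyletic, sister-group leaf labels)."""
    mrca = tree.mrca(taxon_labels=sorted(leaves))
    under = {l.taxon.label for l in mrca.leaf_iter()}
    if under != leaves:
        return False, set()
    parent = mrca.parent_node
    if parent is None:
        return True, set()
    sister = {
        l.taxon.label
        for child in parent.child_nodes()
        if child is not mrca
        for l in child.leaf_iter()
    }
    return True, sister


def infer_transfer_direction(ltree: LabeledTree) -> DirectionCall:
    """Rule-based direction call on a labeled gene tree (see module docstring)."""
    queries = ltree.leaves_in_group("query")
    if len(queries) != 1:
        raise ArgumentError("tree must carry exactly one query leaf")
    viral = ltree.leaves_in_group("virus")
    if not viral:
        return DirectionCall("inconclusive", "unrooted", "no viral leaves to test against")
    amoebal = ltree.leaves_in_group("amoeba") | queries
    tree, rooting = _rooted_tree(ltree)

    a_mono, a_sister = _clade_info(tree, amoebal)
    v_mono, v_sister = _clade_info(tree, viral)
    if a_mono and a_sister and a_sister <= viral and not v_mono:
        return DirectionCall(
            "virus_to_amoeba",
            rooting,
            f"amoebal clade {sorted(amoebal)} nested within paraphyletic viral leaves",
        )
    if v_mono and v_sister and v_sister <= amoebal and not a_mono:
        return DirectionCall(
            "amoeba_to_virus",
            rooting,
            f"viral clade {sorted(viral)} nested within paraphyletic amoebal leaves",
        )
    return DirectionCall("inconclusive", rooting, "no exclusive nested clade configuration")


# ---------------------------------------------------------------------------
# Fitch parsimony ancestral reconstruction


def fitch_ancestral(
    newick: str,
    leaf_sequences: dict[str, str],
) -> tuple[str, int]:
    """Fitch parsimony ancestral sequence at the root of a rooted tree.

    Per column, state sets are propagated bottom-up (intersection when
    non-empty, else union at +1 parsimony cost); the root state is the
    alphabetically smallest member of the root set.  Gap characters are
    treated as missing and excluded from state sets; a column with gaps at
    every leaf reconstructs as ``-``.

    Returns ``(root_sequence, total_parsimony_score)``.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    for label in leaves:
        if label not in leaf_sequences:
            raise DataError(f"leaf {label!r} has no sequence")
    lengths = {len(leaf_sequences[l]) for l in leaves}
    if len(lengths) != 1:
        raise ArgumentError("leaf sequences must have equal length")
    ncol = lengths.pop()

    root_chars = []
    score = 0
    for col in range(ncol):
        sets: dict[int, frozenset[str] | None] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                ch = leaf_sequences[node.taxon.label][col]
                sets[id(node)] = None if ch == "-" else frozenset(ch)
                continue
            acc: frozenset[str] | None = None
            for child in node.child_nodes():
                s = sets[id(child)]
                if s is None:
                    continue
                if acc is None:
                    acc = s
                elif acc & s:
                    acc = acc & s
                else:
                    acc = acc | s
                    score += 1
            sets[id(node)] = acc
        root_set = sets[id(tree.seed_node)]
        root_chars.append("-" if root_set is None else min(root_set))
    return "".join(root_chars), score
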