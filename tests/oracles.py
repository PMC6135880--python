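"""Independent brute-force oracles used only by the test suite.

Kept deliberately separate from the package: these re-derive the quantities
the implementation computes, by direct dynamic programming or exhaustive
enumeration, and must never import the code paths they check.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_MATRICES: dict[str, object] = {}


def _matrix(name: str):
    if name not in _MATRICES:
        _MATRICES[name] = substitution_matrices.load(name)
    return _MATRICES[name]


def sub_score(matrix_name: str, a: str, b: str) -> float:
    return float(_matrix(matrix_name)[a, b])


def sw_affine_score(
    query: str,
    subject: str,
    matrix_name: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> int:
    """Optimal Smith–Waterman local score under affine gaps where a gap of
    length k costs ``gap_open + k*gap_extend``.  Quadratic-space three-state
    DP, no traceback."""
    m, n = len(query), len(subject)
    NEG = float("-inf")
    open_cost = gap_open + gap_extend
    best = 0.0
    # M[j]: best alignment ending in a match at (i, j); Ix: gap in subject
    # (query residue against gap); Iy: gap in query.
    M = [NEG] * (n + 1)
    Ix = [NEG] * (n + 1)
    Iy = [NEG] * (n + 1)
    for i in range(1, m + 1):
        prev_M, prev_Ix, prev_Iy = M[:], Ix[:], Iy[:]
        M[0] = Ix[0] = Iy[0] = NEG
        for j in range(1, n + 1):
            s = sub_score(matrix_name, query[i - 1], subject[j - 1])
            diag = max(prev_M[j - 1], prev_Ix[j - 1], prev_Iy[j - 1], 0.0)
            M[j] = diag + s
            Ix[j] = max(prev_M[j] - open_cost, prev_Ix[j] - gap_extend)
            Iy[j] = max(M[j - 1] - open_cost, Iy[j - 1] - gap_extend)
            best = max(best, M[j])
    return int(round(best))


def score_alignment_blocks(
    query: str,
    subject: str,
    blocks: tuple[tuple[int, int, int, int], ...],
    matrix_name: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> tuple[int, int, int]:
    """Re-score an explicit local-alignment path given as gapless blocks
    (0-based half-open (qs, qe, ss, se)).

    Returns (score, identities, columns).  Identities never count X or ``*``.
    Raises AssertionError if the path is not a consistent local alignment.
    """
    score = 0.0
    identities = 0
    columns = 0
    prev_qe = prev_se = None
    for qs, qe, ss, se in blocks:
        assert qe - qs == se - ss > 0, "gapless block must pair equal-length runs"
        if prev_qe is not None:
            dq, ds = qs - prev_qe, ss - prev_se
            assert dq >= 0 and ds >= 0 and (dq > 0 or ds > 0), "blocks must advance"
            for gap in (dq, ds):
                if gap > 0:
                    score -= gap_open + gap * gap_extend
                    columns += gap
        for a, b in zip(query[qs:qe], subject[ss:se]):
            score += sub_score(matrix_name, a, b)
            columns += 1
            if a == b and a not in ("X", "*"):
                identities += 1
        prev_qe, prev_se = qe, se
    return int(round(score)), identities, columns


def fitch_min_score(adjacency: dict[int, list[int]], root: int, leaf_states: dict[int, str]) -> int:
    """Exhaustive minimum-parsimony cost of one character on a small rooted
    tree: enumerate every internal-node state assignment over the observed
    state set and count edges whose endpoints differ.  Leaves with missing
    state (gap) contribute no edge cost."""
    internal = [n for n in adjacency if adjacency[n]]
    states = sorted({s for s in leaf_states.values() if s != "-"})
    if not states:
        return 0
    edges = [(p, c) for p in adjacency for c in adjacency[p]]
    best = None
    for assignment in itertools.product(states, repeat=len(internal)):
        state = dict(zip(internal, assignment))
        state.update({n: s for n, s in leaf_states.items() if s != "-"})
        cost = sum(
            1
            for p, c in edges
            if p in state and c in state and state[p] != state[c]
        )
        if best is None or cost < best:
            best = cost
    return best


def random_additive_tree(rng, labels: list[str]):
    """Random binary unrooted tree topology with branch lengths in [0.1, 2];
    returns (newick, leaf-to-leaf path-distance dict)."""
    import collections

    nodes = list(labels)
    nwk = {l: l for l in labels}
    graph = collections.defaultdict(dict)
    next_id = 0
    while len(nodes) > 3:
        a, b = rng.sample(nodes, 2)
        la, lb = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        new = f"_i{next_id}"
        next_id += 1
        graph[new][a] = la
        graph[a][new] = la
        graph[new][b] = lb
        graph[b][new] = lb
        nwk[new] = f"({nwk[a]}:{la:.6f},{nwk[b]}:{lb:.6f})"
        nodes = [n for n in nodes if n not in (a, b)] + [new]
    center = "_center"
    parts = []
    for n in nodes:
        ln = rng.uniform(0.1, 2.0)
        graph[center][n] = ln
        graph[n][center] = ln
        parts.append(f"{nwk[n]}:{ln:.6f}")
    newick = "(" + ",".join(parts) + ");"

    dists = {}
    for src in labels:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in graph[u].items():
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for dst in labels:
            dists[(src, dst)] = seen[dst]
    return newick, dists
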