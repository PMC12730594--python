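"""Independent brute-force oracles used by the test suite.

Each oracle is a deliberately simple reimplementation (full-matrix DP,
exhaustive enumeration, least squares) kept separate from the package code
paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

NEG = float("-inf")


def gotoh_score(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-2.0,
                gap_extend=-1.0) -> float:
    """Full-matrix affine-gap global alignment score (Gotoh).

    gap_open is the score of the first gapped position, gap_extend of each
    additional one.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a aligned to '-')
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def brute_tsd(genome: str, start: int, end: int, k_max: int = 12) -> str:
    """Longest k in [1, k_max] with equal flanks, by direct scan."""
    best = ""
    for k in range(1, k_max + 1):
        if start - k < 0 or end + k > len(genome):
            break
        if genome[start - k : start] == genome[end : end + k]:
            best = genome[start - k : start]
    return best


def brute_cmct(protein: str, bounds: dict) -> list[tuple[int, ...]]:
    """All (D1,D2,C1,C2,H1,H2,E) tuples satisfying the motif grammar."""
    p = protein
    out = []
    ds = [i for i, c in enumerate(p) if c == "D"]
    es = [i for i, c in enumerate(p) if c == "E"]
    for d1, d2 in itertools.product(ds, ds):
        if not bounds["d1_d2"][0] <= d2 - d1 <= bounds["d1_d2"][1]:
            continue
        for c1 in range(len(p) - 3):
            if p[c1] != "C" or p[c1 + 3] != "C":
                continue
            if not bounds["d2_c1"][0] <= c1 - d2 <= bounds["d2_c1"][1]:
                continue
            c2 = c1 + 3
            for h1 in range(len(p)):
                if p[h1] != "H":
                    continue
                if not bounds["c2_h1"][0] <= h1 - c2 <= bounds["c2_h1"][1]:
                    continue
                for gap in (4, 5):
                    h2 = h1 + gap
                    if h2 >= len(p) or p[h2] != "H":
                        continue
                    for e in es:
                        if bounds["h2_e"][0] <= e - h2 <= bounds["h2_e"][1]:
                            out.append((d1, d2, c1, c2, h1, h2, e))
    return sorted(out)


def ls_best_quartet(labels, D) -> frozenset:
    """Least-squares branch-length fit over the 3 quartet topologies.

    Returns the winning split as a frozenset pair partition of labels,
    e.g. frozenset({frozenset({a,b}), frozenset({c,d})}).
    """
    a, b, c, d = range(4)
    pairs = [(a, b), (a, c), (a, d), (b, c), (b, d), (c, d)]
    y = np.array([D[i][j] for i, j in pairs], dtype=float)
    best = None
    for split in [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]:
        (p, q), (r, s) = split
        # branches: ep, eq, er, es, internal
        rows = []
        for i, j in pairs:
            row = [0.0] * 5
            for leaf, col in zip((p, q, r, s), range(4)):
                if leaf in (i, j):
                    row[col] = 1.0
            same_side = {i, j} in ({p, q}, {r, s})
            row[4] = 0.0 if same_side else 1.0
            rows.append(row)
        A = np.array(rows)
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(((A @ x - y) ** 2).sum())
        key = frozenset({frozenset({labels[p], labels[q]}),
                         frozenset({labels[r], labels[s]})})
        if best is None or resid < best[0]:
            best = (resid, key)
    return best[1]


def exhaustive_midpoint_edge(tree) -> tuple[frozenset, float]:
    """Best rooting edge by brute force over all edges of a dendropy tree.

    For each edge and each division point on it, the optimal achievable
    max root-to-leaf distance is max over the two sides; the best edge
    minimizes it. Returns (bipartition leafset of the child side, minimized
    max distance) — the minimized value always equals half the diameter.
    """
    taxa = [lf.taxon for lf in tree.leaf_node_iter()]
    best = None
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.length is None:
            continue
        below = {lf.taxon for lf in edge.head_node.leaf_iter()}
        above = [t for t in taxa if t not in below]
        if not above:
            continue
        d_below = _leaf_depths(edge.head_node)
        d_above_via_tail = _leaf_depths_excluding(tree, edge)
        L = edge.length
        # place root at x from head (0 <= x <= L)
        # max_below = max(d_below) + x ; max_above = max(d_above) + (L - x)
        mb, ma = max(d_below.values()), max(d_above_via_tail.values())
        # optimal x balances them
        x = min(max((ma - mb + L) / 2.0, 0.0), L)
        val = max(mb + x, ma + (L - x))
        key = frozenset(t.label for t in below)
        if best is None or val < best[1] - 1e-12:
            best = (key, val)
    return best


def _leaf_depths(node) -> dict:
    out = {}

    def rec(n, acc):
        if n.is_leaf():
            out[n.taxon] = acc
            return
        for ch in n.child_nodes():
            rec(ch, acc + (ch.edge.length or 0.0))

    rec(node, 0.0)
    return out


def _leaf_depths_excluding(tree, edge) -> dict:
    """Depths from edge.tail_node to all leaves not below edge.head_node."""
    head = edge.head_node
    tail = edge.tail_node
    out = {}
    seen = set()

    def down(n, acc):
        if n.is_leaf():
            out[n.taxon] = acc
            return
        for ch in n.child_nodes():
            if ch is head:
                continue
            down(ch, acc + (ch.edge.length or 0.0))

    node = tail
    acc = 0.0
    down(node, 0.0)
    while node.parent_node is not None:
        acc += node.edge.length or 0.0
        parent = node.parent_node
        for ch in parent.child_nodes():
            if ch is node:
                continue
            down(ch, acc + (ch.edge.length or 0.0))
        node = parent
    return out
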