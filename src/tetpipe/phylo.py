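"""Desk-scale phylogenetics: p-distances, neighbor joining, midpoint
rooting, gap-column trimming, and clade-composition summaries.

Trees are dendropy objects throughout; Newick I/O goes through dendropy.
Neighbor joining is the distance-based stand-in used to examine cargo-gene
phylogenies (e.g. whether a well-supported clade mixes host superfamilies,
the signature of horizontal transfer of the cargo gene).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "CladeComposition",
    "trim_gap_columns",
    "p_distance_matrix",
    "nj_tree",
    "midpoint_root",
    "clade_composition",
    "read_newick",
    "write_newick",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if np.any(self.matrix < 0) or np.any(np.diag(self.matrix) != 0):
            raise ValueError("distances must be nonnegative with zero diagonal")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")


@dataclass(frozen=True)
class CladeComposition:
    leaves: frozenset
    counts: dict
    pure: bool


def trim_gap_columns(rows: dict[str, str], max_gap_fraction: float = 0.5) -> dict[str, str]:
    """Drop alignment columns whose gap fraction exceeds the threshold."""
    if not rows:
        raise ValueError("empty alignment")
    labels = list(rows)
    n = len(labels)
    ncols = len(rows[labels[0]])
    keep = [
        c for c in range(ncols)
        if sum(rows[lab][c] == "-" for lab in labels) / n <= max_gap_fraction
    ]
    if not keep:
        raise ValueError("no columns survive gap trimming")
    return {lab: "".join(rows[lab][c] for c in keep) for lab in labels}


def p_distance_matrix(rows: dict[str, str]) -> DistanceMatrix:
    """Pairwise mismatch fractions with pairwise deletion of gap columns."""
    labels = list(rows)
    if len(labels) < 2:
        raise ValueError("need at least 2 rows")
    arrs = {lab: np.frombuffer(rows[lab].encode(), dtype="S1") for lab in labels}
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[labels[i]], arrs[labels[j]]
            ok = (a != b"-") & (b != b"-")
            if not ok.any():
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and {labels[j]!r}"
                )
            m[i, j] = m[j, i] = (a[ok] != b[ok]).mean()
    return DistanceMatrix(labels, m)


def _clamp(li: float, lj: float) -> tuple[float, float]:
    """Zero a negative branch, moving the deficit to its sister."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining (Saitou–Nei, Q-criterion agglomeration).

    Returns an unrooted tree (trifurcating seed node). Negative branch
    lengths are clamped to zero with the deficit moved to the sister branch.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = d.matrix.astype(float).copy()
    # Each active entry is a newick fragment string.
    nodes = list(d.labels)
    active = list(range(n))

    def fragment(i: int) -> str:
        return nodes[i]

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        a, b = np.unravel_index(np.argmin(q), q.shape)
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = D[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, lj)
        new = D.shape[0]
        du = 0.5 * (D[i, active] + D[j, active] - dij)
        du = np.clip(du, 0.0, None)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new, active] = du
        D[active, new] = du
        D[new, new] = 0.0
        nodes.append(f"({fragment(i)}:{li:.10g},{fragment(j)}:{lj:.10g})")
        active = [x for x in active if x not in (i, j)] + [new]
    # Final three-point formulas.
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    li, lj, lk = (max(0.0, x) for x in (li, lj, lk))
    newick = f"({fragment(i)}:{li:.10g},{fragment(j)}:{lj:.10g},{fragment(k)}:{lk:.10g});"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    With all branch lengths zero the midpoint is undefined; the tree is
    returned rooted where it stands, with a warning.
    """
    t = tree.clone(depth=1)
    lengths = [e.length or 0.0 for e in t.edges()]
    if max(lengths, default=0.0) == 0.0:
        warnings.warn("all branch lengths zero; midpoint undefined, root left as-is")
        t.is_rooted = True
        return t
    t.deroot()  # midpoint placement requires the unrooted (trifurcating) form
    t.seed_node.edge.length = None  # a root edge has no length
    t.reroot_at_midpoint(update_bipartitions=True)
    t.seed_node.edge.length = None
    t.is_rooted = True
    return t


def clade_composition(
    tree: dendropy.Tree, label_map: dict[str, str]
) -> list[CladeComposition]:
    """Category multiset under every internal node, with a purity flag."""
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in label_map:
            raise ValueError(f"unmapped leaf: {leaf.taxon.label!r}")
    out = []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        counts = Counter(label_map[l] for l in leaves)
        out.append(CladeComposition(frozenset(leaves), dict(counts), len(counts) == 1))
    return out


def read_newick(path_or_str, from_path: bool = True) -> dendropy.Tree:
    if from_path:
        return dendropy.Tree.get(path=str(path_or_str), schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(data=path_or_str, schema="newick",
                             preserve_underscores=True)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True,
                       real_value_format_specifier=".6f")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s
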