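"""Family clustering and 50%-majority-rule consensus building.

Extracted hit sequences are clustered by single linkage: an edge joins two
sequences when their global alignment reaches both the identity and the
coverage threshold (75%/75% by default, coverage measured on the shorter
sequence), and clusters are the connected components. Each cluster is star-
aligned against its longest member and collapsed to a majority-rule
consensus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .elongate import ConsensusRecord
from .search import align_global

__all__ = ["Cluster", "MSA", "cluster_sequences", "build_msa", "consensus_from_msa"]


@dataclass
class Cluster:
    id: str
    members: list[tuple[str, str]]  # (label, sequence)
    sources: list[object] = field(default_factory=list)

    @property
    def representative(self) -> tuple[str, str]:
        """Longest member; ties broken by lexicographic sequence."""
        return max(self.members, key=lambda m: (len(m[1]), *[-ord(c) for c in m[1]]))


@dataclass
class MSA:
    rows: list[str]
    labels: list[str]
    row_sources: list[object] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert len({len(r) for r in self.rows}) <= 1, "rows must be equal length"

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def cluster_sequences(
    seqs: list[tuple[str, str]],
    min_coverage: float = 75.0,
    min_identity: float = 75.0,
) -> list[Cluster]:
    """Single-linkage clustering at the identity/coverage thresholds.

    ``seqs`` is a list of (label, sequence). The returned clusters are sorted
    by the genome-order of their first member, so output is independent of
    input permutation up to cluster ids.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    uf = _UnionFind(len(seqs))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            _, _, ident, cov = align_global(seqs[i][1], seqs[j][1])
            if ident >= min_identity and cov >= min_coverage:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(seqs)):
        groups.setdefault(uf.find(i), []).append(i)
    # Canonical order: by the lexicographically smallest (sequence, label) in
    # each component, so permuting the input never changes membership.
    comps = sorted(
        (sorted(idx, key=lambda i: (seqs[i][1], seqs[i][0])) for idx in groups.values()),
        key=lambda idx: (seqs[idx[0]][1], seqs[idx[0]][0]),
    )
    return [
        Cluster(id=f"cluster{n}", members=[seqs[i] for i in idx])
        for n, idx in enumerate(comps, start=1)
    ]


def build_msa(cluster: Cluster) -> MSA:
    """Star alignment of every member against the cluster representative."""
    if not cluster.members:
        raise ValueError("empty cluster")
    rep_label, rep = cluster.representative
    n_pos = len(rep)
    # Per member: residues aligned to each representative position, plus the
    # run of inserted residues before each position (and one trailing slot).
    aligned: list[tuple[list[str], list[str]]] = []
    for label, seq in cluster.members:
        ga, gb, _, _ = align_global(rep, seq)
        segs = [""] * n_pos
        inserts = [""] * (n_pos + 1)
        p = 0
        for x, y in zip(ga, gb):
            if x == "-":
                inserts[p] += y
            else:
                segs[p] = y
                p += 1
        aligned.append((segs, inserts))
    max_ins = [max(a[1][p] and len(a[1][p]) or 0 for a in aligned) for p in range(n_pos + 1)]
    rows = []
    for segs, inserts in aligned:
        parts = []
        for p in range(n_pos):
            parts.append(inserts[p].ljust(max_ins[p], "-"))
            parts.append(segs[p])
        parts.append(inserts[n_pos].ljust(max_ins[n_pos], "-"))
        rows.append("".join(parts))
    return MSA(rows=rows, labels=[m[0] for m in cluster.members])


def consensus_from_msa(
    msa: MSA,
    majority_fraction: float = 0.5,
    name: str = "consensus",
) -> ConsensusRecord:
    """Majority-rule consensus.

    Columns whose gap fraction is >= ``majority_fraction`` are dropped
    (insertions present in a minority of copies). Otherwise the most frequent
    non-gap residue is emitted — confidently when its fraction of non-gap
    residues is >= ``majority_fraction``, with a low-confidence mark below.
    Ties break lexicographically (A < C < G < T).
    """
    if not msa.rows:
        raise ValueError("empty alignment")
    n = len(msa.rows)
    seq: list[str] = []
    support: list[int] = []
    confident: list[bool] = []
    for col in range(msa.n_cols):
        column = [r[col] for r in msa.rows]
        residues = [c for c in column if c != "-"]
        if (n - len(residues)) / n >= majority_fraction:
            continue
        counts = Counter(residues)
        top = max(counts.items(), key=lambda kv: (kv[1], *[-ord(c) for c in kv[0]]))
        seq.append(top[0])
        support.append(top[1])
        confident.append(top[1] / len(residues) >= majority_fraction)
    if not seq:
        raise ValueError("all columns were gap-majority")
    return ConsensusRecord(
        name=name, sequence="".join(seq), support=support, confident=confident
    )
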