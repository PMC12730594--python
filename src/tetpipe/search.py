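"""Genome homology search and pairwise-alignment primitives.

``align_global`` is the identity/coverage primitive used by the clustering
and consensus stages; ``find_hits`` is a desk-scale homology search: exact
k-mer seeds chained along diagonals, candidate windows verified by infix
(semi-global) alignment with edlib. Hits on the minus strand are reported in
forward genome coordinates with strand "-".
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib
from Bio import Align

from ._seq import revcomp
from .seqsim import GenomeSequence

__all__ = ["Hit", "align_global", "find_hits", "extract_hit_sequence"]


@dataclass(frozen=True)
class Hit:
    query: str
    contig: str
    start: int
    end: int
    strand: str
    identity: float   # percent of matched columns over alignment columns
    coverage: float   # percent of the query length aligned

    def __post_init__(self) -> None:
        assert self.start < self.end
        assert 0.0 <= self.identity <= 100.0
        assert 0.0 <= self.coverage <= 100.0


def _aligner(match: float = 1, mismatch: float = -1,
             gap_open: float = -2, gap_extend: float = -1) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap_open
    a.extend_gap_score = gap_extend
    return a


def align_global(
    a: str,
    b: str,
    match: float = 1,
    mismatch: float = -1,
    gap_open: float = -2,
    gap_extend: float = -1,
) -> tuple[str, str, float, float]:
    """Optimal global alignment under affine-gap scoring.

    Returns (aligned_a, aligned_b, identity, coverage): identity is
    100*matches/alignment_columns (gap columns count in the denominator);
    coverage is the percentage of the shorter sequence's residues aligned to
    a residue (not a gap) of the other.
    """
    if not a or not b:
        raise ValueError("align_global requires nonempty sequences")
    aln = _aligner(match, mismatch, gap_open, gap_extend).align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(x == y for x, y in zip(ga, gb))
    identity = 100.0 * matches / len(ga)
    short = min(len(a), len(b))
    paired = sum((x != "-") and (y != "-") for x, y in zip(ga, gb))
    coverage = 100.0 * paired / short
    return ga, gb, identity, coverage


def alignment_score(a: str, b: str, **scoring) -> float:
    """Score of the optimal global alignment (see ``align_global``)."""
    return float(_aligner(**scoring).score(a, b))


def _cigar_identity(cigar: str) -> tuple[int, int]:
    """(matches, columns) from an edlib extended cigar."""
    matches = cols = 0
    n = ""
    for c in cigar:
        if c.isdigit():
            n += c
        else:
            k = int(n)
            n = ""
            cols += k
            if c == "=":
                matches += k
    return matches, cols


def _seed_windows(query: str, target: str, k: int, merge_dist: int = 50):
    """Candidate target intervals from shared k-mers chained along diagonals."""
    index = defaultdict(list)
    for i in range(len(query) - k + 1):
        index[query[i : i + k]].append(i)
    # diagonal -> list of target positions of seeds on that diagonal
    diags: dict[int, list[int]] = defaultdict(list)
    for j in range(len(target) - k + 1):
        for i in index.get(target[j : j + k], ()):
            diags[j - i].append(j)
    # Merge nearby diagonals into bands, then chain seeds within a band.
    chains: list[tuple[int, int]] = []  # (t_lo, t_hi) covered by seeds
    band: dict[int, list[int]] = defaultdict(list)
    for d, pts in diags.items():
        band[d // merge_dist].extend(pts)
        band[d // merge_dist + 1].extend(pts)
    for pts in band.values():
        pts.sort()
        lo = prev = pts[0]
        for p in pts[1:]:
            if p - prev > max(merge_dist, len(query) // 4):
                chains.append((lo, prev + k))
                lo = p
            prev = p
        chains.append((lo, prev + k))
    # Expand each chain into a window generously covering the full query.
    margin = len(query) // 5 + 50
    windows = []
    for lo, hi in chains:
        windows.append((max(0, lo - len(query) - margin), min(len(target), hi + len(query) + margin)))
    # Merge overlapping windows.
    windows.sort()
    merged: list[list[int]] = []
    for w in windows:
        if merged and w[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], w[1])
        else:
            merged.append(list(w))
    return [(a, b) for a, b in merged]


def _hits_one_strand(
    query: str,
    qname: str,
    genome: GenomeSequence,
    strand: str,
    min_identity: float,
    min_length: int,
    k: int,
) -> list[Hit]:
    q = query if strand == "+" else revcomp(query)
    target = genome.seq
    hits = []
    max_ed = int(len(q) * (1 - min_identity / 100) * 1.5) + 8
    todo = list(_seed_windows(q, target, k))
    while todo:
        lo, hi = todo.pop()
        if hi - lo < min_length:
            continue
        window = target[lo:hi]
        res = edlib.align(q, window, mode="HW", task="path", k=max_ed)
        if res["editDistance"] < 0:
            continue
        s, e = res["locations"][0]
        e += 1
        matches, cols = _cigar_identity(res["cigar"])
        identity = 100.0 * matches / cols
        aligned_len = e - s
        if identity >= min_identity and aligned_len >= min_length:
            hits.append(
                Hit(qname, genome.name, lo + s, lo + e, strand, identity,
                    100.0 * min(1.0, aligned_len / len(q)))
            )
        # A window can hold several copies; re-scan on both sides of this one.
        todo.append((lo, lo + s))
        todo.append((lo + e, hi))
    return hits


def _dedupe(hits: list[Hit]) -> list[Hit]:
    """Merge overlapping hits of the same query/strand, keeping the best."""
    out: list[Hit] = []
    for h in sorted(hits, key=lambda h: (h.contig, h.start, -h.identity)):
        if out and h.contig == out[-1].contig and h.strand == out[-1].strand \
                and h.start < out[-1].end:
            if h.identity > out[-1].identity:
                out[-1] = h
            continue
        out.append(h)
    return out


def find_hits(
    query: str,
    genome: GenomeSequence,
    min_identity: float = 80.0,
    min_length: int = 100,
    k: int = 12,
    qname: str = "query",
) -> list[Hit]:
    """All genomic copies of ``query`` above the identity/length thresholds.

    Both strands are searched; minus-strand hits carry forward coordinates.
    """
    if k > len(query):
        raise ValueError("seed size k exceeds query length")
    hits = _hits_one_strand(query, qname, genome, "+", min_identity, min_length, k)
    hits += _hits_one_strand(query, qname, genome, "-", min_identity, min_length, k)
    return _dedupe(hits)


def extract_hit_sequence(genome: GenomeSequence, hit: Hit) -> str:
    """Strand-normalized hit sequence (reverse-complemented for "-")."""
    s = genome.seq[hit.start : hit.end]
    return s if hit.strand == "+" else revcomp(s)
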