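"""Iterative consensus elongation and terminus (alignment-border) calling.

Starting from a core consensus (typically covering only the seed-matched
region of a family), genomic copies are extracted with flanking sequence and
re-aligned to the consensus each round. The consensus grows outward into the
flanks; a terminus is called where per-column copy support drops from
element-like to background-like. Called borders are then refined by the
positions' target-site-duplication (TSD) concordance across copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from ._seq import revcomp
from .search import Hit, find_hits
from .seqsim import GenomeSequence

__all__ = [
    "ConsensusRecord",
    "BorderCall",
    "FlankedCopy",
    "ElongationResult",
    "select_copies",
    "extend_and_call",
]

_CODE = {c: i for i, c in enumerate("ACGTN")}
_GAP, _ABSENT = 6, 7


@dataclass
class ConsensusRecord:
    """A family consensus with per-column support and border status."""

    name: str
    sequence: str
    support: list[int]
    confident: list[bool] = field(default_factory=list)
    left_status: str = "open"     # open | terminus_called
    right_status: str = "open"
    rounds: int = 0

    def __post_init__(self) -> None:
        assert len(self.support) == len(self.sequence)


@dataclass(frozen=True)
class BorderCall:
    position: int          # consensus column (0-based; 3' border is half-open)
    side: str              # "5'" or "3'"
    support_inside: float
    support_outside: float
    tsd_concordant_copies: int = 0


@dataclass
class FlankedCopy:
    """A strand-normalized genomic copy with flanking context.

    ``gstart``/``gend`` are forward-genome coordinates of the whole extracted
    window (flanks included); ``seq`` is reverse-complemented when strand is
    "-", so local coordinates always run 5'->3' along the element.
    """

    seq: str
    contig: str
    gstart: int
    gend: int
    strand: str
    hit: Hit | None = None

    def to_genome(self, a: int, b: int) -> tuple[int, int]:
        """Map a local half-open interval to forward genome coordinates."""
        if self.strand == "+":
            return self.gstart + a, self.gstart + b
        return self.gend - b, self.gend - a


@dataclass
class ElongationResult:
    consensus: ConsensusRecord
    border5: BorderCall | None
    border3: BorderCall | None
    copies: list[FlankedCopy]
    copy_intervals: list[tuple[str, int, int, str]]  # (contig, start, end, strand)


def select_copies(
    consensus: str,
    genome: GenomeSequence,
    max_copies: int = 10,
    min_identity: float = 80.0,
    flank: int = 5000,
    k: int = 12,
) -> list[FlankedCopy]:
    """Up to ``max_copies`` best genomic copies, with flanking sequence.

    Hits above ``min_identity`` are ranked by identity (descending, ties by
    genomic position) and extracted with up to ``flank`` bp of context per
    side (less at contig ends). Minus-strand copies are strand-normalized
    together with their flanks.
    """
    if not consensus:
        raise ValueError("empty consensus")
    hits = find_hits(consensus, genome, min_identity=min_identity,
                     min_length=max(k, len(consensus) // 3), k=k)
    hits.sort(key=lambda h: (-h.identity, h.start))
    out = []
    for h in hits[:max_copies]:
        lo = max(0, h.start - flank)
        hi = min(len(genome.seq), h.end + flank)
        s = genome.seq[lo:hi]
        out.append(FlankedCopy(
            seq=s if h.strand == "+" else revcomp(s),
            contig=h.contig, gstart=lo, gend=hi, strand=h.strand, hit=h,
        ))
    return out


def _align_rows(W: str, copies: list[FlankedCopy]):
    """Per copy: (si, ei, colmap) — copy positions for each consensus column.

    colmap[c] is the copy position aligned to consensus column c, or -1 where
    the copy has a gap. Copies the consensus fails to align to are skipped.
    """
    rows = []
    for copy in copies:
        res = edlib.align(W, copy.seq, mode="HW", task="path",
                          k=max(64, int(len(W) * 0.6)))
        if res["editDistance"] < 0:
            rows.append(None)
            continue
        s, e = res["locations"][0]
        colmap = np.full(len(W), -1, dtype=np.int64)
        qi, ti = 0, s
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "=X":
                colmap[qi : qi + n] = np.arange(ti, ti + n)
                qi += n
                ti += n
            elif ch == "I":      # consensus base missing from the copy
                qi += n
            elif ch == "D":      # copy insertion relative to the consensus
                ti += n
        rows.append((s, e + 1, colmap))
    return rows


def _profile(W: str, copies: list[FlankedCopy], rows, lext: int, rext: int):
    """Residue matrix over [ -lext, len(W)+rext ) and support/majority arrays."""
    ncols = lext + len(W) + rext
    mat = np.full((len(copies), ncols), _ABSENT, dtype=np.uint8)
    for r, (copy, row) in enumerate(zip(copies, rows)):
        if row is None:
            continue
        si, ei, colmap = row
        seq = copy.seq
        for d in range(1, lext + 1):
            p = si - d
            if p < 0:
                break
            mat[r, lext - d] = _CODE.get(seq[p], 4)
        for c in range(len(W)):
            p = colmap[c]
            mat[r, lext + c] = _GAP if p < 0 else _CODE.get(seq[p], 4)
        for d in range(rext):
            p = ei + d
            if p >= len(seq):
                break
            mat[r, lext + len(W) + d] = _CODE.get(seq[p], 4)
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])  # ACGT only
    majority = counts.argmax(axis=0)            # argmax ties -> lowest index = lex
    best = counts.max(axis=0)
    covering = (mat != _ABSENT).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        support = np.where(covering >= 2, best / np.maximum(covering, 1), 0.0)
    seq = np.array(list("ACGT"))[majority]
    seq[covering == 0] = "N"
    return mat, "".join(seq), support, best, covering


def _window_means(s: np.ndarray, w: int) -> np.ndarray:
    """means[i] = mean(s[i:i+w]) for i in 0..len(s)-w."""
    c = np.concatenate([[0.0], np.cumsum(s)])
    return (c[w:] - c[:-w]) / w


def _call_border(s: np.ndarray, w: int, thr: float, side: str):
    """Best border column under the inside/outside window rule.

    A candidate column c has mean support >= ``thr`` over the w columns on
    its element side and < ``thr`` over the w columns on its flank side; the
    winner maximizes the inside-outside contrast, ties going outermost.
    Returns (column, inside, outside) or None.
    """
    if len(s) < 2 * w:
        return None
    means = _window_means(s, w)  # means[i] over s[i:i+w]
    best = None
    for c in range(w, len(s) - w + 1):
        if side == "5'":
            inside, outside = means[c], means[c - w]
        else:
            inside, outside = means[c - w], means[c]
        if inside >= thr and outside < thr:
            contrast = inside - outside
            outer = -c if side == "5'" else c
            if best is None or (contrast, outer) > (best[0], best[1]):
                best = (contrast, outer, c, inside, outside)
    if best is None:
        return None
    return best[2], best[3], best[4]


def _local_tsd_len(seq: str, a: int, b: int, k_max: int = 12, k_min: int = 2) -> int:
    """Longest exact direct repeat flanking [a, b) within one copy sequence."""
    for k in range(min(k_max, a, len(seq) - b), k_min - 1, -1):
        if seq[a - k : a] == seq[b : b + k]:
            return k
    return 0


def _percopy_adjust(copies, locs, consensus_seq: str, radius: int = 2, w: int = 8):
    """Per-copy border adjustment by terminal fit to the consensus.

    Alignment ends can slip a base or two on an individual copy when a
    mutated terminal base lets the aligner borrow a flank base. Each end is
    re-phased independently within +/-``radius`` to the offset maximizing
    the match between the copy's terminal ``w`` bases and the consensus
    termini (ties prefer no shift). Family-level divergence makes the true
    offset score ~w(1-d) against ~w/4 elsewhere.
    """
    c5, c3 = consensus_seq[:w], consensus_seq[-w:]
    out = []
    for copy, loc in zip(copies, locs):
        if loc is None:
            out.append(None)
            continue
        a0, b0 = loc

        def matches(x: str, y: str) -> int:
            return sum(p == q for p, q in zip(x, y))

        best5 = max(
            (d for d in range(-radius, radius + 1) if 0 <= a0 + d <= len(copy.seq)),
            key=lambda d: (matches(copy.seq[a0 + d : a0 + d + w], c5), -abs(d), d),
        )
        best3 = max(
            (d for d in range(-radius, radius + 1) if 0 <= b0 + d <= len(copy.seq)),
            key=lambda d: (matches(copy.seq[max(0, b0 + d - w) : b0 + d], c3), -abs(d), -d),
        )
        a, b = a0 + best5, b0 + best3
        out.append((a, b) if a < b else loc)
    return out


def _copy_locations(rows, lext: int, W_len: int, b5: int, b3: int, copies):
    """Map border columns [b5, b3) in profile space to per-copy positions."""
    locs = []
    for copy, row in zip(copies, rows):
        if row is None:
            locs.append(None)
            continue
        si, ei, colmap = row

        def to_pos(c: int, left: bool) -> int | None:
            if c < lext:                      # left extension region
                p = si - (lext - c)
                return p if p >= 0 else None
            if c >= lext + W_len:             # right extension region
                p = ei + (c - lext - W_len)
                return p if p <= len(copy.seq) else None
            # interior: nearest aligned copy position
            cc = c - lext
            if left:
                for x in range(cc, W_len):
                    if colmap[x] >= 0:
                        return int(colmap[x])
                return ei
            for x in range(cc - 1, -1, -1):
                if colmap[x] >= 0:
                    return int(colmap[x]) + 1
            return si
        a = to_pos(b5, left=True)
        b = to_pos(b3, left=False)
        locs.append((a, b) if a is not None and b is not None and a < b else None)
    return locs


def extend_and_call(
    consensus: ConsensusRecord,
    flanked_copies: list[FlankedCopy],
    border_threshold: float = 0.6,
    window: int = 10,
    max_rounds: int = 20,
    extend_step: int = 500,
    tsd_refine_radius: int = 3,
) -> ElongationResult:
    """Elongate a consensus into copy flanks and call both termini.

    Each round the copies are re-aligned to the current consensus, which is
    extended outward by up to ``extend_step`` bp per side using the majority
    base across copies. A border is called where windowed support drops below
    ``border_threshold`` (see :func:`_call_border`); called borders are
    refined within +/-``tsd_refine_radius`` bp to the offset maximizing the
    number of copies with identical left/right TSDs (ties innermost). The
    loop stops when both borders are stable across a round, or at
    ``max_rounds`` (remaining sides flagged "open").
    """
    if len(flanked_copies) < 2:
        raise ValueError("need at least 2 copies to call borders")
    W = consensus.sequence
    prev_intervals = None
    result_state = None
    rounds = 0
    while rounds < max_rounds:
        rounds += 1
        rows = _align_rows(W, flanked_copies)
        if all(r is None for r in rows):
            break
        lext = min(extend_step, max((r[0] for r in rows if r), default=0))
        rext = min(extend_step,
                   max((len(c.seq) - r[1] for c, r in zip(flanked_copies, rows) if r),
                       default=0))
        mat, newW, support, best, covering = _profile(W, flanked_copies, rows, lext, rext)
        call5 = _call_border(support, window, border_threshold, "5'")
        call3 = _call_border(support, window, border_threshold, "3'")
        if call5 and call3 and call5[0] < call3[0]:
            b5, b3 = call5[0], call3[0]
            locs = _copy_locations(rows, lext, len(W), b5, b3, flanked_copies)
            # Re-phase each copy's ends to the candidate consensus termini
            # first, so a single slipped alignment end cannot drag the
            # family-level refinement below off target.
            locs = _percopy_adjust(flanked_copies, locs, newW[b5:b3])
            # TSD-concordance refinement of the border pair: maximize the
            # number of TSD-bearing copies, then total TSD length (a real
            # k bp duplication outweighs a chance 2-mer such as the TA that
            # flanks TA-terminal elements when borders slip inward), then
            # prefer the smallest shift, ties innermost.
            bestref = None
            for d5 in range(-tsd_refine_radius, tsd_refine_radius + 1):
                for d3 in range(-tsd_refine_radius, tsd_refine_radius + 1):
                    n = total = 0
                    for copy, loc in zip(flanked_copies, locs):
                        if loc is None:
                            continue
                        a, b = loc[0] + d5, loc[1] + d3
                        if 0 < a < b < len(copy.seq):
                            t = _local_tsd_len(copy.seq, a, b)
                            if t >= 2:
                                n += 1
                                total += t
                    key = (n, total, -(abs(d5) + abs(d3)), d5, -d3)
                    if bestref is None or key > bestref[0]:
                        bestref = (key, d5, d3)
            _, d5, d3 = bestref
            # Families without TSDs give only chance repeats; never move the
            # borders unless a majority of copies agree on a duplication.
            n_valid = sum(loc is not None for loc in locs)
            if bestref[0][0] <= n_valid / 2:
                d5 = d3 = 0
            b5, b3 = b5 + d5, b3 + d3
            locs = [
                (loc[0] + d5, loc[1] + d3)
                if loc and 0 <= loc[0] + d5 < loc[1] + d3 <= len(copy.seq) else None
                for copy, loc in zip(flanked_copies, locs)
            ]
            n_tsd = sum(
                1 for copy, loc in zip(flanked_copies, locs)
                if loc and 0 < loc[0] < loc[1] < len(copy.seq)
                and _local_tsd_len(copy.seq, loc[0], loc[1]) >= 2
            )
            intervals = [
                copy.to_genome(*loc) if loc else None
                for copy, loc in zip(flanked_copies, locs)
            ]
            result_state = (b5, b3, newW, support, best, call5, call3, n_tsd, locs, rows, lext)
            if prev_intervals is not None and intervals == prev_intervals:
                break
            prev_intervals = intervals
            W = newW[b5:b3]
        else:
            grown = newW
            if grown == W:            # nothing left to extend; cannot resolve
                break
            W = grown
    if result_state is None:
        # No border could be called (e.g. shared/duplicated flanks).
        rec = ConsensusRecord(
            name=consensus.name, sequence=W, support=[0] * len(W),
            confident=[False] * len(W), left_status="open",
            right_status="open", rounds=rounds,
        )
        return ElongationResult(rec, None, None, flanked_copies, [])
    b5, b3, newW, support, best, call5, call3, n_tsd, locs, rows, lext = result_state
    seq = newW[b5:b3]
    sup = [int(x) for x in best[b5:b3]]
    conf = [s >= border_threshold for s in support[b5:b3]]
    rec = ConsensusRecord(
        name=consensus.name, sequence=seq, support=sup, confident=conf,
        left_status="terminus_called", right_status="terminus_called",
        rounds=rounds,
    )
    border5 = BorderCall(0, "5'", call5[1], call5[2], n_tsd)
    border3 = BorderCall(len(seq), "3'", call3[1], call3[2], n_tsd)
    intervals = []
    copies_out = []
    for copy, loc in zip(flanked_copies, locs):
        if loc is None:
            continue
        g = copy.to_genome(*loc)
        intervals.append((copy.contig, g[0], g[1], copy.strand))
        copies_out.append(copy)
    return ElongationResult(rec, border5, border3, copies_out, intervals)
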