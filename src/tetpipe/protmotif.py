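"""Protein extraction and catalytic-motif scanning.

Two motif systems are covered. CMCT-clade DDE transposases (EnSpm/CACTA,
Mirage, Chapaev, Transib, Plavaka, ESTA, Lanisha, RAG1) carry C-x(2)-C and
H-x(3-4)-H motifs between the second catalytic D and the final E.
TET/JBP dioxygenases carry the 2-His-1-carboxylate facial triad
H-x-(D/E) ... H that binds Fe(II); an HxE in place of HxD is the hallmark of
the PE type, while PU and AG types are separated by type-specific conserved
residues supplied as an editable profile. Two further residue positions
(aligned to Gly331 and Asp337 of the Coprinopsis cinerea enzyme CcTET)
report whether a dioxygenase also has the residues that enable 6mA
recognition: Gly/Ser at the 331-position and Asp at the 337-position.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml
from Bio.Seq import Seq

from ._seq import revcomp

__all__ = [
    "OrfRecord",
    "MotifHit",
    "TETDomainCall",
    "six_frame_orfs",
    "scan_cmct",
    "enumerate_cmct",
    "find_tet_triad",
    "assign_tet_type",
    "check_6ma_residues",
    "load_type_profiles",
]

DEFAULT_CMCT_BOUNDS = {
    "d1_d2": (50, 250),   # residues between the two catalytic aspartates
    "d2_c1": (5, 150),    # second D to the first C of C-x(2)-C
    "c2_h1": (1, 250),    # C-x(2)-C block to the H-x(3,4)-H block
    "h2_e": (5, 150),     # second H to the final catalytic E
}


@dataclass(frozen=True)
class OrfRecord:
    source: str
    frame: int            # 1..3 forward, 4..6 reverse
    start: int            # nucleotide coords, 0-based half-open, forward strand
    end: int
    protein: str


@dataclass(frozen=True)
class MotifHit:
    kind: str                          # "CMCT" | "TET_triad"
    residue_positions: dict            # name -> 0-based protein position
    acid_type: str | None = None       # "D" or "E" (TET triad only)

    @property
    def span(self) -> tuple[int, int]:
        pos = self.residue_positions.values()
        return min(pos), max(pos) + 1


@dataclass
class TETDomainCall:
    type: str                          # PU | AG | PE | ambiguous
    triad: MotifHit
    profile_score: dict = field(default_factory=dict)
    sixmA_flags: tuple[bool, bool] | None = None


def six_frame_orfs(dna: str, min_orf_len: int = 300, source: str = "seq") -> list[OrfRecord]:
    """Longest stop-free protein per reading frame, length-filtered.

    Stop-to-stop definition (no start codon required). Reverse-frame
    coordinates are mapped back to the forward strand.
    """
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    out = []
    L = len(dna)
    for frame in range(1, 7):
        offset = (frame - 1) % 3
        template = dna if frame <= 3 else revcomp(dna)
        usable = (len(template) - offset) // 3 * 3
        if usable == 0:
            continue
        prot = str(Seq(template[offset : offset + usable]).translate())
        # longest stop-free stretch; leftmost wins ties
        best, besti = "", 0
        i = 0
        for piece in prot.split("*"):
            if len(piece) > len(best):
                best, besti = piece, i
            i += len(piece) + 1
        if len(best) < min_orf_len:
            continue
        nt_s = offset + 3 * besti
        nt_e = offset + 3 * (besti + len(best))
        if frame > 3:
            nt_s, nt_e = L - nt_e, L - nt_s
        out.append(OrfRecord(source=source, frame=frame, start=nt_s, end=nt_e, protein=best))
    return out


def enumerate_cmct(protein: str, bounds: dict | None = None) -> list[MotifHit]:
    """Every residue assignment D..D..C-x(2)-C..H-x(3,4)-H..E within bounds."""
    if not protein:
        raise ValueError("empty protein")
    b = dict(DEFAULT_CMCT_BOUNDS)
    if bounds:
        b.update(bounds)
    p = protein
    ds = [i for i, c in enumerate(p) if c == "D"]
    cc = [i for i in range(len(p) - 3) if p[i] == "C" and p[i + 3] == "C"]
    hh = [
        (i, i + 4 + x)
        for x in (0, 1)
        for i in range(len(p) - 4 - x)
        if p[i] == "H" and p[i + 4 + x] == "H"
    ]
    es = [i for i, c in enumerate(p) if c == "E"]
    hits = []
    for d2 in ds:
        for d1 in ds:
            if not (b["d1_d2"][0] <= d2 - d1 <= b["d1_d2"][1]):
                continue
            for c1 in cc:
                if not (b["d2_c1"][0] <= c1 - d2 <= b["d2_c1"][1]):
                    continue
                c2 = c1 + 3
                for h1, h2 in hh:
                    if not (b["c2_h1"][0] <= h1 - c2 <= b["c2_h1"][1]):
                        continue
                    for e in es:
                        if not (b["h2_e"][0] <= e - h2 <= b["h2_e"][1]):
                            continue
                        hits.append(MotifHit(
                            kind="CMCT",
                            residue_positions={
                                "D1": d1, "D2": d2, "C1": c1, "C2": c2,
                                "H1": h1, "H2": h2, "E": e,
                            },
                        ))
    hits.sort(key=lambda h: (h.span[1], h.span[0], sorted(h.residue_positions.values())))
    return hits


def scan_cmct(protein: str, bounds: dict | None = None) -> list[MotifHit]:
    """Maximal set of non-overlapping CMCT motif hits (greedy by end)."""
    chosen: list[MotifHit] = []
    for hit in enumerate_cmct(protein, bounds):
        s, e = hit.span
        if all(e <= c.span[0] or s >= c.span[1] for c in chosen):
            chosen.append(hit)
    return chosen


def find_tet_triad(
    protein: str,
    min_gap: int = 15,
    max_gap: int = 120,
) -> MotifHit | None:
    """The 2-His-1-carboxylate facial triad H-x-(D|E) ... H, or None.

    The downstream His must lie ``min_gap``..``max_gap`` residues after the
    acidic residue. When several triads exist the most compact one wins
    (ties leftmost) — in real domains the facial triad is the tightest
    H/acid/H arrangement present.
    """
    if not protein:
        raise ValueError("empty protein")
    best = None
    for i in range(len(protein) - 2):
        if protein[i] != "H" or protein[i + 2] not in "DE":
            continue
        acid = i + 2
        for j in range(acid + min_gap, min(len(protein), acid + max_gap + 1)):
            if protein[j] == "H":
                key = (j - i, i)
                if best is None or key < best[0]:
                    best = (key, i, acid, j, protein[acid])
                break  # nearest downstream H only
    if best is None:
        return None
    _, h_a, acid, h_b, acid_type = best
    return MotifHit(
        kind="TET_triad",
        residue_positions={"H_a": h_a, "acid": acid, "H_b": h_b},
        acid_type=acid_type,
    )


def load_type_profiles(path=None) -> dict[str, dict[int, str]]:
    """Per-type conserved-residue profiles: type -> {alignment column: residues}."""
    if path is None:
        fh = importlib.resources.files("tetpipe.data").joinpath(
            "tet_type_profiles.yaml"
        ).open()
    else:
        fh = open(path)
    with fh:
        raw = yaml.safe_load(fh)
    return {t: {int(c): str(r) for c, r in cols.items()} for t, cols in raw.items()}


def assign_tet_type(
    aligned_row: str,
    triad: MotifHit,
    type_profiles: dict[str, dict[int, str]] | None = None,
) -> TETDomainCall:
    """PU/AG/PE typing of one dioxygenase from its aligned row.

    PE is called directly from the triad's HxE hallmark. Otherwise the type
    with more matched conserved residues wins; equal counts -> ambiguous.
    """
    if type_profiles is None:
        type_profiles = load_type_profiles()
    scores = {}
    for t, cols in type_profiles.items():
        for col in cols:
            if col >= len(aligned_row):
                raise ValueError(
                    f"profile column {col} outside alignment of length {len(aligned_row)}"
                )
        scores[t] = sum(aligned_row[col] in res for col, res in cols.items())
    if triad.acid_type == "E":
        return TETDomainCall(type="PE", triad=triad, profile_score=scores)
    pu, ag = scores.get("PU", 0), scores.get("AG", 0)
    t = "PU" if pu > ag else "AG" if ag > pu else "ambiguous"
    return TETDomainCall(type=t, triad=triad, profile_score=scores)


def check_6ma_residues(
    rows: dict[str, str],
    query_row: str,
    reference_row: str = "CcTET",
    g_position: int = 331,
    d_position: int = 337,
) -> tuple[bool, bool]:
    """6mA-capability residue flags for one aligned dioxygenase.

    ``rows`` is a gapped protein alignment keyed by label and must contain
    the reference row. Reference residue numbering is 1-based and ungapped.
    Returns (g331_like, d337_like): Gly or Ser at the 331-column, Asp at the
    337-column (a gap never qualifies).
    """
    if reference_row not in rows:
        raise ValueError(f"reference row {reference_row!r} absent from alignment")
    if query_row not in rows:
        raise ValueError(f"query row {query_row!r} absent from alignment")
    ref = rows[reference_row]
    cols = {}
    residue = 0
    for col, c in enumerate(ref):
        if c != "-":
            residue += 1
            if residue in (g_position, d_position):
                cols[residue] = col
    if g_position not in cols or d_position not in cols:
        raise ValueError("reference row too short for the requested positions")
    q = rows[query_row]
    g_like = q[cols[g_position]] in "GS"
    d_like = q[cols[d_position]] == "D"
    return g_like, d_like
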