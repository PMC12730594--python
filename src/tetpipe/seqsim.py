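"""Synthetic genomes with planted DNA-transposon families.

The simulator is the ground-truth side of the pipeline: every planted copy's
coordinates, strand, target-site duplication (TSD) and truncation state are
recorded, so that boundary calls, TSD/TIR annotation and superfamily
classification can be scored exactly.

A family is described by a :class:`FamilySpec`: element length, terminal
motifs (IUPAC), terminal-inverted-repeat (TIR) length, a TSD rule (fixed
length k, or the literal dinucleotide "TA" marking insertion into TA sites),
per-copy substitution divergence, optional truncation, and copy number.
Copies are planted into i.i.d. random background DNA at non-overlapping
sites; integration duplicates the k bases at the target site so they flank
the element, exactly as a staggered-cut transposase would.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import DNA, complement_set, iupac_set, revcomp

__all__ = [
    "FamilySpec",
    "InsertionTruth",
    "GenomeSequence",
    "ImpossibleSpecError",
    "make_family_consensus",
    "plant_insertions",
    "mutate_sequence",
    "archetype_specs",
    "simulate_cargo_transfer_alignment",
    "write_truth_tsv",
    "read_truth_tsv",
]

TRUTH_COLUMNS = [
    "family", "contig", "start", "end", "strand",
    "tsd_seq", "truncated5", "truncated3",
]


class ImpossibleSpecError(ValueError):
    """Terminal motifs are incompatible with the requested TIR."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA string; the substrate for search and simulation."""

    name: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FamilySpec:
    """Structural description of one transposon family.

    ``tsd_spec`` is either an int (fixed TSD length in bp, 0 = none) or the
    literal string "TA" (insertion at, and duplication of, a TA dinucleotide).
    """

    name: str
    superfamily: str
    element_length: int
    motif5: str = ""
    motif3: str = ""
    tir_length: int = 0
    tsd_spec: int | str = 0
    divergence: float = 0.05
    truncation_prob: float = 0.0
    copy_number: int = 10

    def __post_init__(self) -> None:
        if self.element_length < len(self.motif5) + len(self.motif3):
            raise ValueError("element_length shorter than the two terminal motifs")
        if self.tir_length > self.element_length // 2:
            raise ValueError("tir_length exceeds half the element length")
        if isinstance(self.tsd_spec, str):
            if not self.tsd_spec or any(c not in DNA for c in self.tsd_spec):
                raise ValueError("literal tsd_spec must be a nonempty ACGT string")
        elif self.tsd_spec < 0:
            raise ValueError("fixed TSD length must be >= 0")
        if not (0.0 <= self.divergence < 0.5):
            raise ValueError("divergence must be in [0, 0.5)")
        if not (0.0 <= self.truncation_prob < 1.0):
            raise ValueError("truncation_prob must be in [0, 1)")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        for m in (self.motif5, self.motif3):
            for c in m:
                iupac_set(c)  # raises on non-IUPAC


@dataclass(frozen=True)
class InsertionTruth:
    """Ground truth for one planted copy (coordinates exclude the TSD)."""

    family: str
    contig: str
    start: int
    end: int
    strand: str
    tsd_seq: str
    truncated5: int
    truncated3: int


def make_family_consensus(spec: FamilySpec, seed: int) -> str:
    """Draw the family's true consensus sequence.

    The sequence starts with a concrete resolution of ``motif5`` and ends
    with one of ``motif3``; if ``tir_length`` > 0 the first ``tir_length``
    bases are the reverse complement of the last ``tir_length`` bases, with
    motif bases taking precedence (incompatible constraints raise
    :class:`ImpossibleSpecError`).
    """
    rng = np.random.default_rng(seed)
    L = spec.element_length
    # Per-position allowed-base sets, narrowed by the motifs.
    allowed = ["ACGT"] * L
    for i, c in enumerate(spec.motif5):
        allowed[i] = iupac_set(c)
    for j, c in enumerate(spec.motif3):
        pos = L - len(spec.motif3) + j
        allowed[pos] = "".join(sorted(set(allowed[pos]) & set(iupac_set(c))))
        if not allowed[pos]:
            raise ImpossibleSpecError(
                f"{spec.name}: motif5/motif3 overlap incompatibly at position {pos}"
            )
    seq: list[str | None] = [None] * L
    # TIR constraint: seq[i] == complement(seq[L-1-i]) for i < tir_length.
    for i in range(spec.tir_length):
        j = L - 1 - i
        choices = sorted(set(allowed[i]) & set(complement_set(allowed[j])))
        if not choices:
            raise ImpossibleSpecError(
                f"{spec.name}: terminal motifs incompatible with a "
                f"{spec.tir_length} bp TIR at offset {i}"
            )
        base = choices[int(rng.integers(len(choices)))]
        seq[i] = base
        seq[j] = complement_set(base)
    for i in range(L):
        if seq[i] is None:
            opts = allowed[i]
            seq[i] = opts[int(rng.integers(len(opts)))]
    return "".join(seq)  # type: ignore[arg-type]


def mutate_sequence(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """i.i.d. point substitutions, uniform over the 3 alternative bases."""
    if divergence == 0.0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < divergence)
    for i in hits:
        alts = DNA.replace(out[i], "")
        out[i] = alts[int(rng.integers(3))]
    return "".join(out)


def random_background(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(DNA))[rng.choice(4, size=length, p=p)])


def _draw_copy(
    consensus: str, spec: FamilySpec, rng: np.random.Generator
) -> tuple[str, str, int, int]:
    """One mutated, possibly truncated, stranded copy.

    Returns (inserted sequence, strand, truncated5, truncated3); the sequence
    is already reverse-complemented for minus-strand copies.
    """
    t5 = t3 = 0
    if spec.truncation_prob > 0 and rng.random() < spec.truncation_prob:
        cut = int(rng.integers(1, max(2, spec.element_length // 3)))
        if rng.random() < 0.5:
            t5 = cut
        else:
            t3 = cut
    core = consensus[t5 : len(consensus) - t3]
    core = mutate_sequence(core, spec.divergence, rng)
    strand = "+" if rng.random() < 0.5 else "-"
    return (core if strand == "+" else revcomp(core)), strand, t5, t3


def plant_insertions(
    background_length: int,
    specs: list[FamilySpec],
    seed: int,
    gc: float = 0.5,
    contig: str = "chr1",
    min_separation: int = 30,
) -> tuple[GenomeSequence, list[InsertionTruth]]:
    """Plant every family's copies into random background DNA.

    Insertion points are drawn uniformly and rejected when closer than
    ``min_separation`` bp to a previous point, so planted copies never nest.
    Fixed-length TSDs duplicate the k background bases at the target site;
    literal "TA" specs insert at (and duplicate) a TA dinucleotide.
    Truncated copies are inserted without any duplication.
    """
    rng = np.random.default_rng(seed)
    bg = random_background(background_length, rng, gc=gc)

    events = []  # (position_in_bg, tsd_len, element_seq, strand, t5, t3, family)
    used: list[int] = []

    def _free(p: int) -> bool:
        return all(abs(p - q) >= min_separation for q in used)

    for spec in specs:
        consensus = make_family_consensus(spec, int(rng.integers(2**31)))
        literal = spec.tsd_spec if isinstance(spec.tsd_spec, str) else None
        k = len(literal) if literal else int(spec.tsd_spec)
        for _ in range(spec.copy_number):
            elem, strand, t5, t3 = _draw_copy(consensus, spec, rng)
            tsd_len = 0 if (t5 or t3) else k
            lo, hi = 16, len(bg) - 16
            if literal:
                sites = [
                    i for i in range(lo, hi - len(literal))
                    if bg[i : i + len(literal)] == literal and _free(i)
                ]
                for _retry in range(3):
                    if sites:
                        break
                    ext = random_background(background_length, rng, gc=gc)
                    off = len(bg)
                    bg += ext
                    hi = len(bg) - 16
                    sites = [
                        off + i for i in range(len(ext) - len(literal))
                        if ext[i : i + len(literal)] == literal and _free(off + i)
                    ]
                if not sites:
                    raise RuntimeError(
                        f"{spec.name}: no free {literal!r} target site in background"
                    )
                p = int(sites[int(rng.integers(len(sites)))])
            else:
                for _retry in range(1000):
                    p = int(rng.integers(lo, hi))
                    if _free(p):
                        break
                else:
                    raise RuntimeError("could not place insertion without overlap")
            used.append(p)
            events.append((p, tsd_len, elem, strand, t5, t3, spec.name))

    events.sort(key=lambda e: e[0])
    pieces, truths = [], []
    prev = 0
    offset = 0
    for p, tsd_len, elem, strand, t5, t3, family in events:
        tsd = bg[p : p + tsd_len]
        pieces.append(bg[prev:p])
        pieces.append(tsd)
        pieces.append(elem)
        start = p + offset + len(tsd)
        truths.append(
            InsertionTruth(family, contig, start, start + len(elem), strand, tsd, t5, t3)
        )
        offset += len(tsd) + len(elem)
        prev = p
    pieces.append(bg[prev:])
    return GenomeSequence(contig, "".join(pieces)), truths


def write_truth_tsv(truths: list[InsertionTruth], path) -> None:
    pd.DataFrame([dataclasses.asdict(t) for t in truths], columns=TRUTH_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_truth_tsv(path) -> list[InsertionTruth]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"tsd_seq": str})
    return [InsertionTruth(**{c: row[c] for c in TRUTH_COLUMNS}) for _, row in df.iterrows()]


def archetype_specs(
    element_length: int = 2000,
    divergence: float = 0.05,
    copy_number: int = 10,
    truncation_prob: float = 0.0,
) -> dict[str, FamilySpec]:
    """One simulated archetype per superfamily in the shipped rule file.

    TSD lengths, TA-site specificity, TIR presence and the stated terminal
    motifs (TAYGG..CCRTA, CAC..GTG, CA..TG, TGT..ACA, CATCA..TGATG) follow the
    described superfamily structures; motifs and TIR lengths for superfamilies
    whose termini are not on record (Zisupton/Dileera, hAT, PHISTA) are
    invented here solely so that families are distinguishable on structure.
    """

    def mk(name, superfamily, **kw):
        return FamilySpec(
            name=name,
            superfamily=superfamily,
            element_length=element_length,
            divergence=divergence,
            copy_number=copy_number,
            truncation_prob=truncation_prob,
            **kw,
        )

    return {
        "Zisupton": mk("Zisupton-sim", "Zisupton/Dileera", tsd_spec=8,
                       tir_length=14, motif5="GGGTTA", motif3="TAACCC"),
        "Kyakuja": mk("Kyakuja-sim", "Kyakuja", tsd_spec=7,
                      tir_length=0, motif5="CAGCT", motif3="TCCTG"),
        "hAT7": mk("hAT7-sim", "hAT7", tsd_spec=7,
                   tir_length=12, motif5="TAGGG", motif3="CCCTA"),
        "hAT5": mk("hAT5-sim", "hAT5", tsd_spec=5,
                   tir_length=12, motif5="TAGGG", motif3="CCCTA"),
        "hAT6": mk("hAT6-sim", "hAT6", tsd_spec=6,
                   tir_length=12, motif5="TAGGG", motif3="CCCTA"),
        "IS3EU": mk("IS3EU-sim", "IS3EU", tsd_spec=6,
                    tir_length=40, motif5="TAYGG", motif3="CCRTA"),
        "PHISTA": mk("PHISTA-sim", "PHISTA", tsd_spec="TA",
                     tir_length=10, motif5="GAGGC", motif3="GCCTC"),
        "EnSpm": mk("EnSpm-sim", "EnSpm", tsd_spec=3,
                    tir_length=0, motif5="CACTA", motif3="TAGTG"),
        "ESTA": mk("ESTA-sim", "ESTA", tsd_spec="TA",
                   tir_length=0, motif5="CACGC", motif3="GCGTG"),
        "PlavakaA": mk("PlavakaA-sim", "PlavakaA", tsd_spec=2,
                       tir_length=0, motif5="TGT", motif3="ACA"),
        "PlavakaB": mk("PlavakaB-sim", "PlavakaB", tsd_spec=2,
                       tir_length=0, motif5="CATCA", motif3="TGATG"),
    }


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _mutate_protein(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False):
        alts = AMINO_ACIDS.replace(out[i], "")
        out[i] = alts[int(rng.integers(len(alts)))]
    return "".join(out)


def simulate_cargo_transfer_alignment(
    seed: int,
    n_per_group: int = 5,
    length: int = 200,
    deep_subs: int = 80,
    shallow_subs: int = 10,
) -> tuple[dict[str, str], dict[str, str]]:
    """Cargo-gene protein alignment with one cross-superfamily transfer.

    Two host superfamilies, A and B, each carry the cargo gene descended from
    its own deep ancestor — except one B-hosted copy that descends from the A
    ancestor (a horizontal transfer). Returns (rows, leaf->superfamily map);
    rows are equal-length (substitution-only evolution), i.e. pre-aligned.
    A correct tree therefore contains a well-populated clade of mixed
    superfamily composition.
    """
    rng = np.random.default_rng(seed)
    root = "".join(AMINO_ACIDS[int(rng.integers(20))] for _ in range(length))
    anc = {
        "A": _mutate_protein(root, deep_subs, rng),
        "B": _mutate_protein(root, deep_subs, rng),
    }
    rows: dict[str, str] = {}
    cats: dict[str, str] = {}
    for g in ("A", "B"):
        for i in range(n_per_group):
            label = f"{g}{i}"
            rows[label] = _mutate_protein(anc[g], shallow_subs, rng)
            cats[label] = g
    # The transferred copy: hosted by superfamily B, gene descends from A.
    rows["B_transfer"] = _mutate_protein(anc["A"], shallow_subs, rng)
    cats["B_transfer"] = "B"
    return rows, cats
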