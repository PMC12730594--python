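"""TSD/TIR detection, terminal-motif matching and superfamily classification.

Superfamilies of DNA transposons are diagnosable from three structural
features of a reconstructed family: the modal length (or literal sequence)
of the target site duplication, the presence/length of terminal inverted
repeats, and short terminal motifs (e.g. CAC..GTG for EnSpm/CACTA,
TAYGG..CCRTA for IS3EU, TGT..ACA / CATCA..TGATG for the two Plavaka
lineages, CA..TG for Kyakuja and the broader CMCT clade). The shipped rule
file encodes one rule per superfamily; classification applies the rules
most-specific-first.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from ._seq import iupac_set
from .seqsim import GenomeSequence

__all__ = [
    "BoundaryAnnotation",
    "ClassificationRule",
    "detect_tsd",
    "detect_tir",
    "match_motif",
    "classify_family",
    "load_rules",
    "default_rules",
    "annotate_family",
]


@dataclass
class BoundaryAnnotation:
    """Per-family boundary features feeding classification."""

    family: str
    per_copy_tsds: list[str]
    tsd_call: int | str        # modal length, or the literal string (e.g. "TA")
    tir_length: int
    tir_identity: float | None
    motif5_observed: str
    motif3_observed: str


@dataclass(frozen=True)
class ClassificationRule:
    superfamily: str
    tsd: frozenset[int] | str = frozenset()   # set of lengths, or literal "TA"
    motif5: str = ""
    motif3: str = ""
    tir_required: str = "either"              # required | forbidden | either
    min_tir: int = 12

    def specificity(self) -> tuple:
        """Sort key: longest motifs first, then literal TSD, then TIR rules."""
        return (
            -(len(self.motif5) + len(self.motif3)),
            0 if isinstance(self.tsd, str) else 1,
            0 if self.tir_required != "either" else 1,
            self.superfamily,
        )


def detect_tsd(
    genome: GenomeSequence,
    interval: tuple[int, int],
    strand: str = "+",
    k_max: int = 12,
) -> str:
    """Longest exact direct repeat flanking ``interval`` (empty if none).

    TSDs are direct repeats on the forward strand regardless of element
    orientation, so ``strand`` only controls the reading direction of the
    returned string's element-relative sense; the comparison itself is done
    on forward coordinates.
    """
    start, end = interval
    if not (0 <= start <= end <= len(genome.seq)):
        raise ValueError("interval outside genome")
    avail = min(k_max, start, len(genome.seq) - end)
    for k in range(avail, 0, -1):
        if genome.seq[start - k : start] == genome.seq[end : end + k]:
            return genome.seq[start - k : start]
    return ""


def detect_tir(
    consensus: str,
    min_len: int = 8,
    max_len: int = 60,
    min_identity: float = 80.0,
) -> tuple[int, float | None]:
    """Terminal-inverted-repeat call on a consensus.

    The 5' prefix is compared position-wise against the reverse complement
    of the 3' suffix (substitution-diverged TIRs stay in register, so the
    comparison is ungapped). The call localizes the TIR boundary as the
    maximum-scoring prefix segment, subject to a ``min_identity`` cumulative
    identity and a ``min_len`` minimum length.
    Returns (length, identity), or (0, None) when no TIR qualifies.
    """
    if len(consensus) < 2 * min_len:
        raise ValueError("consensus too short for TIR detection")
    from ._seq import revcomp

    hi = min(max_len, len(consensus) // 2)
    prefix = consensus[:hi]
    suffix_rc = revcomp(consensus[-hi:])
    match = [p == q for p, q in zip(prefix, suffix_rc)]
    # Maximum-scoring prefix segment: +1 per match, -penalty per mismatch
    # (the 3:1 penalty mirrors the 75% background mismatch rate of random
    # DNA), subject to the overall identity threshold and ending on a match.
    penalty = 3.0
    score = best_score = 0.0
    cum = 0
    best: tuple[int, float | None] = (0, None)
    for i, m in enumerate(match):
        cum += m
        score += 1.0 if m else -penalty
        L = i + 1
        if m and score > best_score and L >= min_len \
                and 100.0 * cum / L >= min_identity:
            best_score = score
            best = (L, 100.0 * cum / L)
    return best


def match_motif(sequence: str, motif: str, end: str) -> bool:
    """Position-wise IUPAC match of a terminal motif at the 5' or 3' end."""
    if end not in ("5'", "3'"):
        raise ValueError("end must be \"5'\" or \"3'\"")
    if len(sequence) < len(motif):
        return False
    terminal = sequence[: len(motif)] if end == "5'" else sequence[-len(motif) :]
    return all(b in iupac_set(m) for b, m in zip(terminal, motif))


def _rule_matches(rule: ClassificationRule, ann: BoundaryAnnotation) -> bool:
    if isinstance(rule.tsd, str):
        if ann.tsd_call != rule.tsd:
            return False
    elif rule.tsd:
        length = len(ann.tsd_call) if isinstance(ann.tsd_call, str) else ann.tsd_call
        if length not in rule.tsd:
            return False
    if rule.motif5 and not match_motif(ann.motif5_observed, rule.motif5, "5'"):
        return False
    if rule.motif3 and not match_motif(ann.motif3_observed, rule.motif3, "3'"):
        return False
    # A TIR shorter than the rule's min_tir counts as absent for that rule:
    # spurious self-complementarity of a few terminal bases is not a TIR.
    has_tir = ann.tir_length >= rule.min_tir
    if rule.tir_required == "required" and not has_tir:
        return False
    if rule.tir_required == "forbidden" and has_tir:
        return False
    return True


def classify_family(
    annotation: BoundaryAnnotation,
    rules: list[ClassificationRule] | None = None,
) -> tuple[str, ClassificationRule | None]:
    """First matching rule in most-specific-first order, or "Unclassified"."""
    if rules is None:
        rules = default_rules()
    for rule in sorted(rules, key=ClassificationRule.specificity):
        if _rule_matches(rule, annotation):
            return rule.superfamily, rule
    return "Unclassified", None


def _parse_tsd_field(s: str) -> frozenset[int] | str:
    s = s.strip()
    if not s or s == "-":
        return frozenset()
    if s.replace(",", "").replace(" ", "").isdigit():
        return frozenset(int(x) for x in s.split(","))
    return s  # literal, e.g. "TA"


def load_rules(path) -> list[ClassificationRule]:
    """Read a rule table (TSV: superfamily, tsd, motif5, motif3, tir, min_tir)."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    rules = []
    for _, row in df.iterrows():
        rules.append(ClassificationRule(
            superfamily=row["superfamily"],
            tsd=_parse_tsd_field(str(row["tsd"])),
            motif5=str(row["motif5"]).strip() or "",
            motif3=str(row["motif3"]).strip() or "",
            tir_required=str(row["tir"]).strip() or "either",
            min_tir=int(row["min_tir"]),
        ))
    return rules


def default_rules() -> list[ClassificationRule]:
    with importlib.resources.files("tetpipe.data").joinpath(
        "superfamily_rules.tsv"
    ).open() as fh:
        return load_rules(fh)


def annotate_family(
    family: str,
    consensus: str,
    genome: GenomeSequence,
    copy_intervals: list[tuple[str, int, int, str]],
    k_max: int = 12,
    tir_min_len: int = 8,
    tir_max_len: int = 60,
    tir_min_identity: float = 80.0,
) -> BoundaryAnnotation:
    """Assemble the boundary annotation for one reconstructed family.

    The TSD call is the modal length over copies with a nonempty TSD (ties
    to the shorter length); when every modal-length TSD is the same literal
    string (the TA-targeting superfamilies), the call is that literal.
    """
    tsds = [
        detect_tsd(genome, (s, e), strand, k_max=k_max)
        for _, s, e, strand in copy_intervals
    ]
    nonempty = [t for t in tsds if t]
    if nonempty:
        lengths = Counter(len(t) for t in nonempty)
        top = max(lengths.values())
        modal_len = min(k for k, v in lengths.items() if v == top)
        modal_tsds = [t for t in nonempty if len(t) == modal_len]
        same = len(set(modal_tsds)) == 1
        call: int | str = modal_tsds[0] if (same and len(modal_tsds) > 1) else modal_len
    else:
        call = 0
    if len(consensus) >= 2 * tir_min_len:
        tir_len, tir_ident = detect_tir(
            consensus, min_len=tir_min_len, max_len=tir_max_len,
            min_identity=tir_min_identity,
        )
    else:
        tir_len, tir_ident = 0, None
    return BoundaryAnnotation(
        family=family,
        per_copy_tsds=tsds,
        tsd_call=call,
        tir_length=tir_len,
        tir_identity=tir_ident,
        motif5_observed=consensus[:8],
        motif3_observed=consensus[-8:],
    )
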