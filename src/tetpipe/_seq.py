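"""Small shared sequence helpers (alphabet tables, reverse complement)."""

from __future__ import annotations

DNA = "ACGT"

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# IUPAC nucleotide degeneracy codes -> the set of concrete bases they admit.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def iupac_set(code: str) -> str:
    """Concrete bases admitted by a single IUPAC code (raises on junk)."""
    try:
        return IUPAC[code.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC nucleotide code: {code!r}") from None


def complement_set(bases: str) -> str:
    return "".join(sorted(b.translate(COMPLEMENT) for b in bases))
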