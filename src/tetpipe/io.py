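"""FASTA reading/writing with validation.

Sequences are normalized to upper case on read; duplicate ids and
non-IUPAC characters are hard errors (the offending position is named).
Output wraps at 60 columns.
"""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import IUPAC

_VALID = {
    "dna": set(IUPAC) | {"U"},
    "protein": set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-"),
}

__all__ = ["read_fasta", "write_fasta"]


def read_fasta(path, alphabet: str = "dna") -> list[tuple[str, str]]:
    """Read FASTA into (id, upper-case sequence) pairs, validating both."""
    valid = _VALID[alphabet]
    out = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for i, c in enumerate(seq):
            if c not in valid:
                raise ValueError(
                    f"non-IUPAC character {c!r} at position {i} of record {rec.id!r}"
                )
        out.append((rec.id, seq))
    return out


def write_fasta(records: list[tuple[str, str]], path, descriptions: dict | None = None) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description=(descriptions or {}).get(name, ""))
        for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")
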