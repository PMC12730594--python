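"""Six-frame ORF extraction and catalytic-motif scanning."""

from hypothesis import given, settings
from hypothesis import strategies as st
import pytest

from _oracles import brute_cmct
from conftest import random_dna
from tetpipe._seq import revcomp
from tetpipe.protmotif import (
    DEFAULT_CMCT_BOUNDS,
    MotifHit,
    assign_tet_type,
    check_6ma_residues,
    enumerate_cmct,
    find_tet_triad,
    scan_cmct,
    six_frame_orfs,
)

# one codon per amino acid (no stops)
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
AA = "".join(sorted(CODON))


def encode(protein: str) -> str:
    return "".join(CODON[c] for c in protein)


def random_protein(rng, n, alphabet=AA):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


class TestSixFrameOrfs:
    def test_minus_strand_protein(self, rng):
        prot = random_protein(rng, 900)
        dna = revcomp("TAA" + encode(prot) + "TAA")
        recs = [r for r in six_frame_orfs(dna, min_orf_len=300) if r.protein == prot]
        assert len(recs) == 1
        assert recs[0].frame in (4, 5, 6)

    def test_length_cutoff_at_300(self, rng):
        p299 = random_protein(rng, 299)
        recs = six_frame_orfs("TAA" + encode(p299) + "TAA", 300)
        assert all(r.frame != 1 for r in recs)  # the 299-residue ORF is dropped
        assert all(len(r.protein) >= 300 for r in recs)
        p300 = random_protein(rng, 300)
        recs = six_frame_orfs("TAA" + encode(p300) + "TAA", 300)
        assert [r.protein for r in recs if r.frame == 1] == [p300]

    def test_coordinates_retranslate(self, rng):
        """Reported coordinates re-translate to the reported protein."""
        from Bio.Seq import Seq

        for _ in range(5):
            dna = random_dna(rng, 10_000)
            for rec in six_frame_orfs(dna, min_orf_len=50):
                sub = dna[rec.start : rec.end]
                if rec.frame > 3:
                    sub = revcomp(sub)
                assert str(Seq(sub).translate()) == rec.protein

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            six_frame_orfs("AC")

    @given(dna=st.text(alphabet="ACGT", min_size=60, max_size=400))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_orfs_are_stop_free_and_retranslate(self, dna):
        from Bio.Seq import Seq

        for rec in six_frame_orfs(dna, min_orf_len=5):
            assert "*" not in rec.protein
            sub = dna[rec.start : rec.end]
            if rec.frame > 3:
                sub = revcomp(sub)
            assert str(Seq(sub).translate()) == rec.protein


def _cmct_protein(h_gap=3):
    return (
        "M" + "A" * 10 + "D" + "A" * 80 + "D" + "A" * 20 + "CAAC" + "A" * 30
        + "H" + "A" * h_gap + "H" + "A" * 40 + "E" + "A" * 10
    )


class TestScanCmct:
    def test_constructed_motif_found(self):
        hits = scan_cmct(_cmct_protein())
        assert len(hits) == 1
        pos = hits[0].residue_positions
        p = _cmct_protein()
        assert p[pos["D1"]] == p[pos["D2"]] == "D"
        assert p[pos["C1"]] == p[pos["C2"]] == "C"
        assert p[pos["H1"]] == p[pos["H2"]] == "H"
        assert p[pos["E"]] == "E"
        assert pos["C2"] - pos["C1"] == 3
        assert pos["H2"] - pos["H1"] in (4, 5)

    def test_h_spacing_outside_3_4_rejected(self):
        assert scan_cmct(_cmct_protein(h_gap=5)) == []
        assert scan_cmct(_cmct_protein(h_gap=4)) != []

    def test_enumeration_matches_brute_force(self, rng):
        alphabet = "DCEHGLIVST"  # D/C/H/E at ~10% so motifs actually occur
        for _ in range(6):
            p = random_protein(rng, 250, alphabet)
            got = {
                tuple(h.residue_positions[k] for k in ("D1", "D2", "C1", "C2", "H1", "H2", "E"))
                for h in enumerate_cmct(p)
            }
            assert got == set(brute_cmct(p, DEFAULT_CMCT_BOUNDS))

    def test_nonoverlapping_selection(self):
        hits = scan_cmct(_cmct_protein())
        spans = [h.span for h in hits]
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                assert spans[i][1] <= spans[j][0] or spans[j][1] <= spans[i][0]


class TestFindTetTriad:
    def test_hxd(self):
        p = "AAHADAA" + "G" * 30 + "HAA"
        hit = find_tet_triad(p)
        assert hit is not None and hit.acid_type == "D"
        assert p[hit.residue_positions["H_a"]] == "H"
        assert p[hit.residue_positions["acid"]] == "D"
        assert p[hit.residue_positions["H_b"]] == "H"

    def test_hxe_candidate_pe(self):
        p = "AAHAEAA" + "G" * 30 + "HAA"
        hit = find_tet_triad(p)
        assert hit is not None and hit.acid_type == "E"

    def test_no_histidine(self):
        assert find_tet_triad("ACDEFG" * 50) is None

    def test_gap_bounds(self):
        p = "AAHADAA" + "G" * 5 + "HAA"  # downstream H too close (<15)
        assert find_tet_triad(p) is None


PROFILES = {"PU": {2: "K", 5: "W"}, "AG": {3: "S", 7: "F"}}
TRIAD_D = MotifHit("TET_triad", {"H_a": 0, "acid": 2, "H_b": 30}, acid_type="D")
TRIAD_E = MotifHit("TET_triad", {"H_a": 0, "acid": 2, "H_b": 30}, acid_type="E")


class TestAssignTetType:
    def test_ag_profile_match(self):
        row = "AAASAAAFAA"
        call = assign_tet_type(row, TRIAD_D, PROFILES)
        assert call.type == "AG"

    def test_pe_from_acid_e(self):
        row = "AAKAAWAAAA"  # PU-like columns, but the HxE hallmark wins
        assert assign_tet_type(row, TRIAD_E, PROFILES).type == "PE"

    def test_no_matches_ambiguous(self):
        assert assign_tet_type("AAAAAAAAAA", TRIAD_D, PROFILES).type == "ambiguous"

    def test_trailing_gap_padding_invariant(self):
        row = "AAASAAAFAA"
        assert assign_tet_type(row + "----", TRIAD_D, PROFILES).type == \
               assign_tet_type(row, TRIAD_D, PROFILES).type

    def test_profile_column_out_of_range(self):
        with pytest.raises(ValueError):
            assign_tet_type("AAA", TRIAD_D, PROFILES)


class TestCheck6maResidues:
    @staticmethod
    def _alignment(query_331="S", query_337="D"):
        # reference: 340 residues, G at 331 and D at 337 (1-based)
        ref = ["A"] * 340
        ref[330] = "G"
        ref[336] = "D"
        q = ["L"] * 340
        q[330] = query_331
        q[336] = query_337
        return {"CcTET": "".join(ref), "query": "".join(q)}

    def test_ser_and_asp(self):
        assert check_6ma_residues(self._alignment("S", "D"), "query") == (True, True)

    def test_gap_is_not_asp(self):
        flags = check_6ma_residues(self._alignment("G", "-"), "query")
        assert flags == (True, False)

    def test_reference_against_itself(self):
        rows = self._alignment()
        assert check_6ma_residues(rows, "CcTET") == (True, True)

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError):
            check_6ma_residues({"query": "AAAA"}, "query")
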