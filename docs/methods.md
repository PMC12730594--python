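# Methods

## Problem and overall procedure

A DNA-transposon family in a genome assembly is a set of diverged copies of
a common ancestral element. Reconstruction proceeds from the inside out: a
probe (in practice a cargo-gene region such as a *TET/JBP dioxygenase*
fragment) finds genomic copies; mutually similar hit sequences are
clustered into families; each family's copies are collapsed into a
majority-rule consensus; the consensus is then elongated with genomic
flanking sequence until it spans the whole element; and the element's
termini are fixed where copy-to-copy agreement collapses into unrelated
flanking DNA. The terminal features — target-site duplication (TSD) length
or sequence, terminal inverted repeats (TIRs), and short terminal motifs —
then identify the superfamily, and the consensus's open reading frames are
scanned for transposase and dioxygenase catalytic motifs.

The package keeps the protocol's published numeric parameters as defaults:
clustering at 75% length coverage and 75% sequence identity (single
linkage, coverage measured on the shorter sequence of a globally aligned
pair); 50%-majority consensus; up to 10 copies at ≥80% identity with
5000 bp of flanking sequence per side for elongation; six-frame translation
keeping the longest protein per frame and discarding proteins shorter than
300 residues; midpoint rooting of trees. All of these are config-exposed
(`PipelineConfig`).

## Synthetic genomes (seqsim)

The simulator is the package's ground-truth instrument, not a fixture: it
emulates the *input* side of the survey (a genome containing transposon
families) with every structural property known exactly.

* **Background** is i.i.d. uniform ACGT (GC configurable, default 0.5) —
  deliberately structure-free so that boundary calls can only come from the
  planted elements.
* **Family consensus**: element of given length whose first/last bases are
  concrete resolutions of the IUPAC terminal motifs; if a TIR length t is
  requested, the first t bases are drawn jointly with the last t so that
  prefix = revcomp(suffix), with motif constraints intersected (an
  unsatisfiable intersection raises an impossible-spec error).
* **Integration mechanics**: an insertion point is drawn uniformly,
  rejected within 30 bp of a previous one (no nesting, unambiguous truth).
  A fixed-k TSD duplicates the k background bases at the site so they flank
  the element; a literal "TA" spec targets an existing TA dinucleotide
  (retrying with extended background before giving up). Copies are
  substitution-diverged (i.i.d., uniform over the 3 alternative bases; no
  indels by default) and inserted on a random strand. A truncated copy
  (one randomly chosen end, up to a third of the element) is inserted
  without any duplication: the duplication is a single integration event,
  so a copy that has lost an end contributes no TSD evidence at all. Modal
  TSD calls are computed over copies with nonempty TSDs, so this choice
  does not bias them.
* **Archetypes** (`archetype_specs`): one spec per shipped classification
  rule. TSD lengths, TA specificity, TIR presence and the recorded motifs
  (TAYGG..CCRTA, CAC..GTG, CA..TG, TGT..ACA, CATCA..TGATG) follow the
  described superfamily structures; where no termini are on record
  (Zisupton/Dileera, the hAT variants, PHISTA) the motifs and TIR lengths
  are invented, chosen only so that the archetypes are structurally
  separable. Default conditions: 2 kb elements, 10 copies, divergence 0.05
  (divergence levels of real families are not on record; 0.05–0.15 spans
  what the method must tolerate), no truncation.

The transfer-signature generator (`simulate_cargo_transfer_alignment`)
evolves a cargo protein down two deep host-superfamily lineages
(substitution-only, so rows are pre-aligned) and grafts one extra leaf
whose gene descends from lineage A but whose host label is B — the minimal
phylogenetic signature of a horizontal cargo-gene transfer.

## Search and alignment

`align_global` delegates to biopython's `PairwiseAligner` (match +1,
mismatch −1, gap open −2, gap extend −1). Identity is defined as
100·matches/alignment-columns *including* gap columns; the denominator
convention is stated because repeat-annotation tools differ and the source
protocol does not define one. Coverage is the fraction of the shorter
sequence's residues aligned to a residue of the other.

`find_hits` seeds with exact shared 12-mers, groups seeds into diagonal
bands (50 bp tolerance), and verifies each candidate window by infix
(semi-global) alignment with edlib, computing identity from the extended
CIGAR. A window can contain several copies, so after each located hit the
window is split and re-scanned on both sides. Minus-strand hits are found
by scanning with the reverse-complemented query and reported in forward
coordinates. This is a desk-scale stand-in for a repeat-annotation search
engine: behaviorally compatible (thresholds act on identity and aligned
length), not bit-compatible.

## Consensus building

Clusters are connected components of the 75/75 pairwise graph (single
linkage, as in the clustering tool the protocol names, whose internals are
otherwise unspecified). Each cluster is star-aligned against its longest
member (ties: lexicographically smallest sequence) — a star MSA is exact
for substitution-dominated divergence and deterministic, which matters for
the permutation-invariance guarantee. Majority-rule consensus: columns
with ≥50% gaps are dropped (insertions private to a minority of copies);
otherwise the most frequent non-gap residue is emitted, marked
low-confidence when its fraction of non-gap residues is below the majority
threshold; ties break lexicographically (A<C<G<T). Whether the published
50% rule counts gaps in the denominator is not stated; the non-gap
denominator used here is a documented package decision.

## Elongation and terminus calling

Each round, every flanked copy is re-aligned to the current consensus
(edlib infix alignment; per-column copy positions from the CIGAR), the
consensus is extended outward by up to 500 bp per side using the
cross-copy majority base, and per-column support is computed as the
fraction of covering copies that carry the majority base (gaps count
against support; columns covered by fewer than two copies get support 0).

The published rule — termini sit at "clear alignment borders" — is made
operational as follows. With window w = 10 and threshold 0.6 (both
config-exposed), a candidate border column must have mean support ≥ 0.6
over the w columns on its element side and < 0.6 over the w columns on its
flank side. The threshold rule alone admits a band of columns around a
sharp support step (roughly ±w/2), so among candidates the call maximizes
the inside-outside contrast, with ties going outermost. With 10 copies,
random flanks sit near support 0.45 and element columns near 1 −
divergence, so the contrast peak localizes the true step.

Two refinements then implement "…and their adjacent TSDs":

1. **Per-copy re-phasing.** An individual copy's alignment end can slip a
   base or two when a mutated terminal base lets the aligner borrow a
   flank base. Each copy end is independently shifted within ±2 bp to
   maximize the match between its terminal 8 bases and the consensus
   termini (ties: no shift). At divergence d the true offset scores ≈
   8(1−d) against ≈ 2 at wrong offsets.
2. **Family-level TSD concordance.** The border pair is shifted within
   ±3 bp to maximize, in order: the number of copies whose refined
   interval is flanked by an exact direct repeat of ≥2 bp; the summed
   repeat length (so a genuine k-bp duplication outweighs the chance 2-mer
   that appears when, e.g., a TA-terminal element's borders slip inward by
   2); smallness of the shift; innermost position. A nonzero shift is
   only applied when a majority of copies support it — TSD-less families
   would otherwise be dragged around by chance repeats.

The loop stops when both borders map to the same genome intervals in two
consecutive rounds, or at 20 rounds; sides that never show a support drop
(e.g. copies inside a segmental duplication, where flanks are identical
across copies) are reported `open` rather than called.

## TSD, TIR and classification

`detect_tsd` returns the longest exact direct repeat (≤12 bp) flanking an
interval; TSDs are exact because reconstructed insertions show clean
duplications, and a mismatch-tolerant mode would only blur the modal
length. The family's TSD call is the modal length over TSD-bearing copies
(ties to the shorter length); when all modal-length TSDs are the same
literal string the call is that literal — this is what separates the
TA-targeting superfamilies (PHISTA, ESTA) from superfamilies with 2 bp
TSDs of arbitrary sequence (PlavakaA).

`detect_tir` compares the 5′ prefix against the reverse complement of the
3′ suffix position-wise (substitution-diverged TIRs stay in register, so
the comparison is ungapped; a gapped aligner systematically overshoots the
TIR boundary by trading flanking chance matches against gap cost). The
reported length is the maximum-scoring prefix segment (+1 per match, −3
per mismatch, mirroring the 75% background mismatch rate), subject to a
cumulative identity ≥80% and a minimum length of 8. On planted TIRs of
10–60 bp with ≤2 interior mismatches this recovers the planted length to
±2 bp.

Classification applies the shipped rule table most-specific-first (longest
motifs, then literal TSD, then TIR constraints; remaining ties
alphabetical, which never decides between rules with overlapping
constraints). Each rule carries a `min_tir`: a detected TIR shorter than
that is treated as absent for the rule, so the few terminal bases of
chance self-complementarity that any CA..TG-terminal element carries do
not violate a "TIR forbidden" rule (Kyakuja) or satisfy "TIR required"
(IS3EU, min 30 bp). Families matching no rule are reported `Unclassified`
rather than forced.

## Protein motifs

ORFs are stop-to-stop (no start-codon requirement — the protocol collects
the longest protein per frame, not ATG-initiated ORFs), standard genetic
code, reverse-frame coordinates mapped back to the forward strand.

The CMCT scan enumerates every residue assignment
D..D..C-x2-C..H-x(3,4)-H..E with inter-block spacing bounds (defaults:
D1–D2 50–250, D2–C1 5–150, C2–H1 1–250, H2–E 5–150 residues) and then
reports a greedy maximal set of non-overlapping assignments; the
enumeration itself is exposed (`enumerate_cmct`) and is checked against a
brute-force oracle in the tests. The TET/JBP triad scan finds
H-x-(D/E) ... H with the downstream His 15–120 residues after the acidic
residue; when several triads exist the most compact wins (ties leftmost) —
no conservation profile is assumed at detection time, compactness being
the only structure-free prior. PE-type assignment needs nothing further
(the HxE hallmark); separating PU from AG requires per-type conserved
columns, shipped as an editable YAML profile whose default content is a
synthetic placeholder (the authoritative per-type columns exist only in a
published alignment figure that is not machine-readable; users supply
their own columns). The 6mA-capability check maps reference residues 331
and 337 of CcTET through a user-provided alignment and flags Gly/Ser and
Asp respectively; a gap never qualifies.

## Phylogenetics

Maximum-likelihood inference is out of scope; the package's tree layer is
the distance stand-in adequate for clade-composition questions: pairwise
p-distances with pairwise gap deletion, canonical neighbor joining
(Q-criterion; negative branch lengths clamped to zero with the deficit
moved to the sister branch), and midpoint rooting via dendropy (the tree
is derooted first; the root edge length is cleared). Gap-column trimming
(drop columns with more than 50% gaps) stands in for the alignment-masking
step of the original protocol. `clade_composition` reports, for every
internal node, the multiset of leaf categories beneath it and whether the
clade is category-pure; a cargo-gene tree with one cross-superfamily
transfer necessarily contains a well-populated mixed clade, which the
acceptance suite checks end-to-end. Newick I/O preserves underscores and
prints branch lengths at 6 decimals (round-trip stability).

## Numerical/degenerate-input choices

* All randomness flows from explicit integer seeds (numpy Generators);
  identical inputs and seeds give byte-identical outputs, including the
  pipeline report.
* Consensus/majority ties break lexicographically; cluster and report
  ordering is canonicalized so input permutation cannot change results.
* `extend_and_call` requires ≥2 copies; empty genomes or probe sets yield
  empty reports (exit success); all-gap alignments, zero-length inputs and
  asymmetric distance matrices raise informative errors.
* Trees with all-zero branch lengths cannot be midpoint-rooted; the tree
  is returned as-is with a warning.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run entirely on simulated data:
100 kb genomes with 10-copy, 2 kb families at divergence 0.05 for the
per-superfamily structural checks (flank set to 1500 bp — the 5000 bp
default is aimed at real genomes with introns and long cargo regions), and
fifty 50 kb genomes with 1 kb families at divergence 0.08 for the
border/classification recovery suite. These sizes are the package's own
choice of a representative desk-scale regime.

## Known limitations

* Substitution-only evolution by default: the simulator, the star MSA and
  the ungapped TIR comparison all lean on indel-free divergence. Real
  families with indel-rich histories would need the optional indel rate
  and a profile re-alignment step this package does not implement.
* Random background lacks the repeat mosaic of real genomes; passing
  tests demonstrate correctness of the method's logic, not robustness to
  nested or fragmented repeats.
* Classification is purely structural; homology-based classification
  against a curated repeat database (the original protocol's primary
  criterion) is out of scope, as is Helitron1 vs Helitron2 subtyping, for
  which no structural criteria are recorded.
* Hit finding requires exact 12-mer seeds: families beyond ~25%
  divergence from the probe fall below seeding sensitivity — consistent
  with the ≥75–80% identity regime the protocol operates in.
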