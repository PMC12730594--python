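# Synthetic default PU/AG type profiles (editable).
#
# Per-type conserved residues distinguishing the PU (Pucciniomycetes-
# associated) from the AG (Agaricomycetes-associated) transposon-encoded
# TET/JBP dioxygenases. Keys are 0-based columns of the user's domain
# alignment; values are the residues accepted at that column. The column
# choices shipped here are a synthetic placeholder profile: the real
# per-type conserved columns live in a published alignment figure that is
# not machine-readable, so users should replace these with columns taken
# from their own alignment. The PE type is not profiled — it is called from
# its HxE triad hallmark.
PU:
  12: "KR"
  40: "W"
  77: "NQ"
  103: "Y"
AG:
  8: "ST"
  33: "F"
  61: "DE"
  95: "L"
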