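# Structural classification rules, one superfamily per row.
# tsd: comma-separated modal TSD lengths, or a literal duplicated string
# (e.g. TA for the TA-targeting superfamilies). motif5/motif3: IUPAC terminal
# motifs. tir: required | forbidden | either; min_tir: minimum length for a
# terminal inverted repeat to count for this rule.
superfamily	tsd	motif5	motif3	tir	min_tir
Zisupton/Dileera	8			either	12
Kyakuja	7	CA	TG	forbidden	12
hAT7	7			either	12
hAT6	6			either	12
hAT5	5			either	12
IS3EU	6	TAYGG	CCRTA	required	30
PHISTA	TA			either	12
EnSpm	3	CAC	GTG	either	12
ESTA	TA	CA	TG	either	12
PlavakaA	2	TGT	ACA	either	12
PlavakaB	2,3	CATCA	TGATG	either	12
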