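# Through-line presence (+) / absence (-) in the three creative-process
# descriptions (musical group SLT, writer SW, musician WC).
theme	label	SLT	SW	WC
LH	Lion-human hybrid	+	+	+
S	Subtractive sculpting / negative space	+	-	-
D	Deterioration / erosion by natural forces	+	+	-
W	Waiting to be found (with a story to tell)	-	+	+
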