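protein_a	protein_b
TERF1	DMD
TERF1	RASGEF1C
TERF2	DMD
TERF2	MACROD2
TRIM25	RASGEF1C
TRIM25	DOCK1
KIAA1429	MACROD2
KIAA1429	PGAM1P5
PRKACA	DOCK1
PRKACA	PGAM1P5
APP	DMD
GAD2	DOCK1
SNTB1	DMD
ELAVL1	APP
CTBP2	MACROD2
RACK1	DOCK1
TERF1	TERF2
ELAVL1	RACK1
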