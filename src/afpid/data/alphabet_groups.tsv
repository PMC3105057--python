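# Group tables for the coarser reduced alphabets (name, group symbol, residues).
# These partitions are documented approximations of common physicochemical
# groupings; override with your own TSV if you need a different convention.
# F: 4 groups -- charged / polar-uncharged / aromatic / nonpolar-aliphatic
F	1	DEKRH
F	2	STNQC
F	3	FWY
F	4	GAVLIMP
# S: 7 groups -- conjoint-triad style physicochemical classes
S	1	AGV
S	2	ILFP
S	3	YMTS
S	4	HNQW
S	5	RK
S	6	DE
S	7	C
# E: 8 groups -- fine physicochemical partition
E	1	AG
E	2	ST
E	3	C
E	4	DENQ
E	5	KRH
E	6	ILMV
E	7	FWY
E	8	P
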