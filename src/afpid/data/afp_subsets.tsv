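# PDB-derived AFP cross-validation subset listing (subset, type, pdb_id).
# Subset membership is user-supplied input; it is never recomputed.
1	insect AFP	1c3y
2	Type III fish AFP	1c89
2	Type III fish AFP	3nla
2	Type III fish AFP	1ucs
2	Type III fish AFP	1ops
2	Type III fish AFP	1kde
2	Type III fish AFP	1ame
2	Type III fish AFP	1msi
2	Type III fish AFP	1b7i
2	Type III fish AFP	1b7j
2	Type III fish AFP	1b7k
2	Type III fish AFP	1ekl
2	Type III fish AFP	1gzi
2	Type III fish AFP	1hg7
2	Type III fish AFP	1jab
2	Type III fish AFP	1msj
2	Type III fish AFP	2ame
2	Type III fish AFP	2jia
2	Type III fish AFP	2msi
2	Type III fish AFP	2msj
2	Type III fish AFP	2spg
2	Type III fish AFP	3ame
2	Type III fish AFP	3msi
2	Type III fish AFP	4ame
2	Type III fish AFP	4msi
2	Type III fish AFP	5msi
2	Type III fish AFP	6ame
2	Type III fish AFP	6msi
2	Type III fish AFP	7ame
2	Type III fish AFP	7msi
2	Type III fish AFP	8ame
2	Type III fish AFP	8msi
2	Type III fish AFP	9ame
2	Type III fish AFP	9msi
3	beta-helical insect AFP	1ezg
4	Type I fish AFP	1wfa
4	Type I fish AFP	1j5b
4	Type I fish AFP	1y03
5	beta-helical insect AFP	1eww
5	beta-helical insect AFP	1l0s
5	beta-helical insect AFP	1m8n
6	insect AFP	2pne
7	Type II fish AFP	2py2
7	Type II fish AFP	2afp
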