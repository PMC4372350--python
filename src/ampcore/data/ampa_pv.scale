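# Bactericidal propensity values (antimicrobial index)
# provenance: AMPA antimicrobial-region scale; per-residue index averaged from
# the IC50 values of a high-throughput bactenecin-2a 12-mer substitution screen
# (Torrent et al. 2012, Bioinformatics 28:130-131; Hilpert et al. 2005).
# LOWER value = more bactericidal. Default stretch threshold 0.225, window 7.
# format: residue<TAB>value
A	0.307
R	0.106
N	0.322
D	0.382
C	0.165
Q	0.324
E	0.414
G	0.331
H	0.202
I	0.301
L	0.281
K	0.111
M	0.221
F	0.195
P	0.463
S	0.300
T	0.308
W	0.172
Y	0.185
V	0.297
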