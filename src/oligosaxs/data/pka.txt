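# Canonical side-chain and termini pKa values (EMBOSS-like set).
# Override by passing an explicit table to oligosaxs.thermo.protein_charge.
nterm 9.00
cterm 3.10
D 3.65
E 4.25
H 6.00
C 8.30
Y 10.07
K 10.53
R 12.48
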