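# RNA nearest-neighbor stack free energies, dG37 (kcal/mol)
# source: Chen et al. 2012 dH/dS set (Bio.SeqUtils.MeltingTemp.RNA_NN3), dG = dH - 310.15*dS/1000
# doublet: top strand 5'->3' / bottom strand 3'->5', aligned position-by-position
doublet	delta_g
AA/UU	-0.9490
AU/UA	-1.1081
AC/UG	-2.2723
AG/UC	-2.0607
AG/UU	-0.3623
AU/UG	-0.8769
UA/AU	-1.3976
UU/AA	-0.9490
UC/AG	-2.3858
UG/AC	-2.0977
UG/AU	-0.4017
UU/AG	-0.5172
CA/GU	-2.0977
CU/GA	-2.0607
CC/GG	-3.3247
CG/GC	-2.3819
CG/GU	-1.2489
CU/GG	-1.7793
GA/CU	-2.3858
GU/CA	-2.2723
GC/CG	-3.4479
GG/CC	-3.3247
GG/CU	-1.8195
GU/CG	-2.1577
GA/UU	-0.5172
GU/UA	-0.8769
GC/UG	-2.1577
GG/UC	-1.7793
GG/UU	-0.2345
GU/UG	0.7160
UA/GU	-0.4017
UU/GA	-0.3623
UC/GG	-1.8195
UG/GC	-1.2489
UG/GU	-0.5752
UU/GG	-0.2345
init	4.2321
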