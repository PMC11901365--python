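# Additive per-residue unfolding enthalpy/entropy in the style of
# Oobatake & Ooi, Prog. Biophys. Mol. Biol. 59 (1993) 237-284.
# Approximate transcription; overridable via ThermoTables.from_csv.
# dG_i at 298.15 K = dH_i - T*dS_i.
residue,dH_kJ_mol,dS_kJ_mol_K
A,87.6298,0.0920
C,90.8391,0.0870
D,82.8076,0.1040
E,83.0928,0.1120
F,111.5910,0.1130
G,78.8557,0.0780
H,93.9761,0.1210
I,112.1669,0.1260
K,80.7502,0.1350
L,108.6743,0.1220
M,102.9817,0.1180
N,82.3002,0.1080
P,78.6242,0.0950
Q,83.2835,0.1170
R,84.3576,0.1310
S,78.7353,0.0890
T,84.2187,0.0980
V,102.8946,0.1110
W,122.5650,0.1270
Y,104.6873,0.1150
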