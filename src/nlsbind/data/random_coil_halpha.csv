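# Random-coil 1H chemical shifts (ppm from TSP/DSS) for Halpha protons of
# the 20 canonical residues, with the dominant neighbor correction applied
# to the Halpha of a residue immediately preceding a proline (pre_pro_corr,
# added to delta_rc when residue i+1 is Pro).  Values are data, not code:
# swap this file to use an alternative random-coil scale.
residue,atom,delta_rc,pre_pro_corr
A,HA,4.35,0.11
R,HA,4.38,0.11
N,HA,4.75,0.11
D,HA,4.76,0.11
C,HA,4.69,0.11
Q,HA,4.37,0.11
E,HA,4.29,0.11
G,HA,3.97,0.11
H,HA,4.63,0.11
I,HA,4.23,0.11
L,HA,4.38,0.11
K,HA,4.36,0.11
M,HA,4.52,0.11
F,HA,4.66,0.11
P,HA,4.44,0.11
S,HA,4.50,0.11
T,HA,4.35,0.11
W,HA,4.70,0.11
Y,HA,4.60,0.11
V,HA,4.18,0.11
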