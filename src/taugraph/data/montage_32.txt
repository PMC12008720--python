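Fp1
Fpz
Fp2
AF3
AF4
F7
F3
Fz
F4
F8
FC5
FC1
FC2
FC6
T7
C3
Cz
C4
T8
CP5
CP1
CP2
CP6
P7
P3
Pz
P4
P8
PO3
PO4
O1
O2
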