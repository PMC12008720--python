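Fp1
AF7
AF3
F1
F3
F5
F7
FT7
FC5
FC3
FC1
C1
C3
C5
T7
TP7
CP5
CP3
CP1
P1
P3
P5
P7
P9
PO7
PO3
O1
Iz
Oz
POz
Pz
CPz
Fpz
Fp2
AF8
AF4
AFz
Fz
F2
F4
F6
F8
FT8
FC6
FC4
FC2
FCz
Cz
C2
C4
C6
T8
TP8
CP6
CP4
CP2
P2
P4
P6
P8
P10
PO8
PO4
O2
AFp9h
AFp7h
AFp5h
AFp3h
AFp1h
AFp2h
AFp4h
AFp6h
AFp8h
AFp10h
AFF9h
AFF7h
AFF5h
AFF3h
AFF1h
AFF2h
AFF4h
AFF6h
AFF8h
AFF10h
FFT9h
FFT7h
FFC5h
FFC3h
FFC1h
FFC2h
FFC4h
FFC6h
FFT8h
FFT10h
FTT9h
FTT7h
FCC5h
FCC3h
FCC1h
FCC2h
FCC4h
FCC6h
FTT8h
FTT10h
TTP9h
TTP7h
CCP5h
CCP3h
CCP1h
CCP2h
CCP4h
CCP6h
TTP8h
TTP10h
TPP9h
TPP7h
CPP5h
CPP3h
CPP1h
CPP2h
CPP4h
CPP6h
TPP8h
TPP10h
PPO9h
PPO7h
PPO5h
PPO3h
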