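label,x,y
Fp1,-0.496189,1.527114
AF3,-0.545830,1.170536
F3,-0.659023,0.813825
F7,-1.299041,0.943808
FC5,-1.173172,0.450338
FC1,-0.394923,0.394923
C3,-0.802851,-0.000000
T7,-1.605703,-0.000000
CP5,-1.173172,-0.450338
CP1,-0.394923,-0.394923
P3,-0.659023,-0.813825
P7,-1.299041,-0.943808
PO3,-0.545830,-1.170536
O1,-0.496189,-1.527114
Oz,0.000000,-1.605703
Pz,0.000000,-0.802851
Fp2,0.496189,1.527114
AF4,0.545830,1.170536
Fz,0.000000,0.802851
F4,0.659023,0.813825
F8,1.299041,0.943808
FC6,1.173172,0.450338
FC2,0.394923,0.394923
Cz,0.000000,0.000000
C4,0.802851,0.000000
T8,1.605703,0.000000
CP6,1.173172,-0.450338
CP2,0.394923,-0.394923
P4,0.659023,-0.813825
P8,1.299041,-0.943808
PO4,0.545830,-1.170536
O2,0.496189,-1.527114
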