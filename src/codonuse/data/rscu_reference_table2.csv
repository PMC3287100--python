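codon,amino_acid,hbv_rscu,human_rscu
TTT,F,1.06,0.87
TTC,F,0.94,1.13
TTA,L,0.67,0.39
TTG,L,1.08,0.73
CTT,L,1.11,0.73
CTC,L,1.22,1.22
CTA,L,0.85,0.40
CTG,L,1.06,2.53
ATT,I,1.27,1.04
ATC,I,1.26,1.52
ATA,I,0.48,0.44
GTT,V,1.27,0.69
GTC,V,0.91,1.00
GTA,V,0.65,0.42
GTG,V,1.17,1.90
TCT,S,1.69,1.11
TCC,S,1.48,1.39
TCA,S,1.28,0.84
TCG,S,0.58,0.33
AGT,S,1.48,0.84
AGC,S,1.01,1.50
CCT,P,0.99,1.12
CCC,P,0.51,1.35
CCA,P,1.37,1.07
CCG,P,1.38,0.46
ACT,T,0.89,0.94
ACC,T,0.37,1.52
ACA,T,1.32,1.07
ACG,T,1.24,0.46
GCT,A,0.99,1.09
GCC,A,0.45,1.64
GCA,A,1.27,0.85
GCG,A,0.73,0.42
TAT,Y,1.05,0.84
TAC,Y,0.95,1.16
CAT,H,1.21,0.81
CAC,H,0.79,1.19
CAA,Q,1.08,0.51
CAG,Q,0.92,1.49
AAT,N,1.36,0.89
AAC,N,0.64,1.11
AAA,K,0.73,0.82
AAG,K,1.27,1.18
GAT,D,1.04,0.89
GAC,D,0.96,1.11
GAA,E,1.23,0.81
GAG,E,0.77,1.19
TGT,C,0.80,0.86
TGC,C,1.06,1.14
CGT,R,0.48,0.51
CGC,R,0.78,1.20
CGA,R,0.61,0.63
CGG,R,0.37,1.20
AGA,R,1.49,1.20
AGG,R,1.39,1.26
GGT,G,0.60,0.64
GGC,G,0.81,1.40
GGA,G,1.36,0.98
GGG,G,1.22,0.98
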