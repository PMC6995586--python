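name	mutations
WT
apo-SOD1	H63F
Cu-SOD1	H120F
Zn-SOD1	H71F
L4_SOD1	N65S, L67P, G72S, D76Y, H80A
L7_SOD1	D124G, D125H, L126S, S134N, N139K, L144F
L4S_SOD1	G72S, D76Y, H80A, L84F, A89T, D90A, G93C, A95G
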