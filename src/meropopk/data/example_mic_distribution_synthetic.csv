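mic_mg_per_L,frequency
0.06,0.02
0.125,0.08
0.25,0.18
0.5,0.24
1,0.20
2,0.12
4,0.08
8,0.05
16,0.03
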