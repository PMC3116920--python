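receptor,logEC50,SE
AncCR,-10.870,0.34
AncGR1.1,-8.144,0.20
C71S,-10.690,0.64
A107S,-10.350,0.24
K83Q,-10.330,0.41
L1M,-10.250,0.30
Q211E,-10.170,0.43
Q113K,-9.773,0.43
R116H,-8.812,0.28
V43A,-8.443,0.15
43/71/116,-8.387,0.54
43/116,-6.418,0.06
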