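musp_cm1,mua_cm1,cf
5,0.1,1.19
5,0.3,1.33
5,0.5,1.48
5,0.7,1.62
5,1.0,1.89
10,0.1,0.88
10,0.3,1.00
10,0.5,1.12
10,0.7,1.23
10,1.0,1.43
15,0.1,0.80
15,0.3,0.87
15,0.5,0.97
15,0.7,1.08
15,1.0,1.25
20,0.1,0.74
20,0.3,0.84
20,0.5,0.91
20,0.7,1.00
20,1.0,1.18
40,0.1,0.74
40,0.3,0.83
40,0.5,0.90
40,0.7,1.02
40,1.0,1.17
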