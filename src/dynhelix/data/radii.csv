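name,radius_A
BB,2.3
SC1,2.3
SC2,2.3
SC3,2.3
SC4,2.3
NT,2.3
H,1.20
C,1.70
N,1.55
O,1.52
S,1.80
P,1.80
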