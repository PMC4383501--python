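element,charge,radius,well_depth,desolv_type
C,0.00,1.90,0.070,CNP
N,-0.20,1.80,0.170,NPL
O,-0.30,1.70,0.150,OPL
P,0.60,2.10,0.200,PHO
S,0.00,2.00,0.250,SUL
H,0.10,1.10,0.020,HYD
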