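type,CNP,NPL,OPL,NPOS,ONEG,PHO,SUL,HYD,NONE
CNP,-0.12,0.02,0.03,0.05,0.05,0.04,-0.06,0.00,0.00
NPL,0.02,0.08,-0.04,0.06,-0.05,0.03,0.02,0.00,0.00
OPL,0.03,-0.04,0.09,-0.06,0.08,0.04,0.03,0.00,0.00
NPOS,0.05,0.06,-0.06,0.16,-0.14,0.10,0.04,0.00,0.00
ONEG,0.05,-0.05,0.08,-0.14,0.17,0.12,0.04,0.00,0.00
PHO,0.04,0.03,0.04,0.10,0.12,0.08,0.03,0.00,0.00
SUL,-0.06,0.02,0.03,0.04,0.04,0.03,-0.09,0.00,0.00
HYD,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
NONE,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00
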