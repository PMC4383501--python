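res_name,atom_name,charge,radius,well_depth,desolv_type
*,BB,-1.00,2.10,0.200,PHO
*,P,1.17,2.10,0.200,PHO
*,OP1,-0.78,1.66,0.210,ONEG
*,OP2,-0.78,1.66,0.210,ONEG
*,O5',-0.50,1.68,0.170,OPL
*,C5',0.06,2.01,0.080,CNP
*,C4',0.11,2.01,0.080,CNP
*,O4',-0.35,1.68,0.170,OPL
*,C3',0.20,2.01,0.080,CNP
*,O3',-0.52,1.68,0.170,OPL
*,C2',0.07,2.01,0.080,CNP
*,O2',-0.61,1.72,0.210,OPL
*,C1',0.09,2.01,0.080,CNP
A,N9,-0.03,1.83,0.170,NPL
A,C8,0.16,1.91,0.090,CNP
A,N7,-0.62,1.82,0.170,NPL
A,C5,0.07,1.91,0.090,CNP
A,C6,0.70,1.91,0.090,CNP
A,N6,-0.90,1.82,0.170,NPL
A,N1,-0.76,1.82,0.170,NPL
A,C2,0.61,1.91,0.090,CNP
A,N3,-0.69,1.82,0.170,NPL
A,C4,0.31,1.91,0.090,CNP
G,N9,0.05,1.83,0.170,NPL
G,C8,0.14,1.91,0.090,CNP
G,N7,-0.57,1.82,0.170,NPL
G,C5,0.20,1.91,0.090,CNP
G,C6,0.48,1.91,0.090,CNP
G,O6,-0.56,1.66,0.210,OPL
G,N1,-0.48,1.82,0.170,NPL
G,C2,0.76,1.91,0.090,CNP
G,N2,-0.97,1.82,0.170,NPL
G,N3,-0.63,1.82,0.170,NPL
G,C4,0.12,1.91,0.090,CNP
C,N1,-0.05,1.83,0.170,NPL
C,C6,0.00,1.91,0.090,CNP
C,C5,-0.52,1.91,0.090,CNP
C,C4,0.82,1.91,0.090,CNP
C,N4,-0.95,1.82,0.170,NPL
C,N3,-0.76,1.82,0.170,NPL
C,C2,0.75,1.91,0.090,CNP
C,O2,-0.63,1.66,0.210,OPL
U,N1,0.04,1.83,0.170,NPL
U,C6,-0.11,1.91,0.090,CNP
U,C5,-0.36,1.91,0.090,CNP
U,C4,0.59,1.91,0.090,CNP
U,O4,-0.58,1.66,0.210,OPL
U,N3,-0.35,1.82,0.170,NPL
U,C2,0.47,1.91,0.090,CNP
U,O2,-0.55,1.66,0.210,OPL
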