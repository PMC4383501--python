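res_name,atom_name,charge,radius,well_depth,desolv_type
*,N,-0.47,1.85,0.200,NPL
*,CA,0.07,2.06,0.070,CNP
*,C,0.51,2.00,0.110,CNP
*,O,-0.51,1.70,0.120,OPL
*,CB,0.00,2.06,0.080,CNP
*,OXT,-0.67,1.70,0.120,ONEG
LYS,NZ,0.33,1.85,0.200,NPOS
LYS,CE,0.21,2.06,0.080,CNP
ARG,NE,-0.40,1.85,0.200,NPL
ARG,CZ,0.50,2.00,0.110,CNP
ARG,NH1,0.30,1.85,0.200,NPOS
ARG,NH2,0.30,1.85,0.200,NPOS
ASP,CG,0.36,2.00,0.110,CNP
ASP,OD1,-0.58,1.70,0.120,ONEG
ASP,OD2,-0.58,1.70,0.120,ONEG
GLU,CD,0.36,2.00,0.110,CNP
GLU,OE1,-0.58,1.70,0.120,ONEG
GLU,OE2,-0.58,1.70,0.120,ONEG
HIS,ND1,-0.36,1.85,0.170,NPL
HIS,NE2,-0.36,1.85,0.170,NPL
ASN,OD1,-0.55,1.70,0.120,OPL
ASN,ND2,-0.60,1.85,0.200,NPL
GLN,OE1,-0.55,1.70,0.120,OPL
GLN,NE2,-0.60,1.85,0.200,NPL
SER,OG,-0.66,1.72,0.150,OPL
THR,OG1,-0.66,1.72,0.150,OPL
TYR,OH,-0.53,1.72,0.150,OPL
TYR,CZ,0.11,2.00,0.070,CNP
TRP,NE1,-0.51,1.85,0.170,NPL
CYS,SG,-0.23,2.00,0.380,SUL
MET,SD,-0.09,2.00,0.380,SUL
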