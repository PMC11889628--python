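name,x,y,z,radius
VWFA_lex,-42,-58,-10,4
VWFA_per,-39,-72,-8,4
STG,-52,-22,6,4
PCG,-44,6,30,4
IFG,-56,12,15,4
IPL,-40,-48,42,4
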