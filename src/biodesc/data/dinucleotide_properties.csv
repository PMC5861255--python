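oligo,gc_content,purine_content,keto_content,santalucia_dH,santalucia_dS,santalucia_dG
AA,0,2,0,-7.9,-22.2,-1.0
AC,1,1,0,-8.4,-22.4,-1.44
AG,1,2,1,-7.8,-21.0,-1.28
AT,0,1,1,-7.2,-20.4,-0.88
CA,1,1,0,-8.5,-22.7,-1.45
CC,2,0,0,-8.0,-19.9,-1.84
CG,2,1,1,-10.6,-27.2,-2.17
CT,1,0,1,-7.8,-21.0,-1.28
GA,1,2,1,-8.2,-22.2,-1.3
GC,2,1,1,-9.8,-24.4,-2.24
GG,2,2,2,-8.0,-19.9,-1.84
GT,1,1,2,-8.4,-22.4,-1.44
TA,0,1,1,-7.2,-21.3,-0.58
TC,1,0,1,-8.2,-22.2,-1.3
TG,1,1,2,-8.5,-22.7,-1.45
TT,0,0,2,-7.9,-22.2,-1.0
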