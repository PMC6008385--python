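name,region,brodmann,x,y,z,module
aMPFC.L,Anterior medial prefrontal cortex,"10,32",-6,52,-2,anterior
aMPFC.R,Anterior medial prefrontal cortex,"10,32",6,52,-2,anterior
PCC.L,Posterior cingulate cortex,"23,31",-8,-56,26,posterior
PCC.R,Posterior cingulate cortex,"23,31",8,-56,26,posterior
dMPFC,Dorsal medial prefrontal cortex,"9,32",0,52,26,anterior
TPJ.L,Temporal parietal junction,"40,39",-54,-54,28,posterior
TPJ.R,Temporal parietal junction,"40,39",54,-54,28,posterior
LTC.L,Lateral temporal cortex,"21,22",-60,-24,-18,anterior
LTC.R,Lateral temporal cortex,"21,22",60,-24,-18,anterior
TempP.L,Temporal pole,21,-50,14,-40,anterior
TempP.R,Temporal pole,21,50,14,-40,anterior
vMPFC,Ventral medial prefrontal cortex,"11,24,25,32",0,26,-18,anterior
pIPL.L,Posterior inferior parietal lobule,39,-44,-74,32,posterior
pIPL.R,Posterior inferior parietal lobule,39,44,-74,32,posterior
Rsp.L,Retrosplenial cortex,"29,30,19",-14,-52,8,posterior
Rsp.R,Retrosplenial cortex,"29,30,19",14,-52,8,posterior
PHC.L,Parahippocampal cortex,"20,36,19",-28,-40,-12,posterior
PHC.R,Parahippocampal cortex,"20,36,19",28,-40,-12,posterior
HF.L,Hippocampal formation,"20,36",-22,-20,-26,posterior
HF.R,Hippocampal formation,"20,36",22,-20,-26,posterior
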