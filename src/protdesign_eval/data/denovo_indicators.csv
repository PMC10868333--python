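Method,Recovery,Diversity,Time (s),SS score,RMSD (Å),Nonpolar loss
Structured Transformer,0.441,0.074,13,0.966,1.526,1.352
ProteinSolver,0.246,0.186,180,0.792,5.354,1.389
3D CNN (Energy),0.421,0.325,536544,0.931,2.130,1.085
3D CNN (LogP),0.445,0.272,536544,0.952,1.620,1.027
ABACUS-R,0.457,0.124,233280,0.972,1.482,0.968
ESM-IF1,0.477,0.184,1980,0.965,1.265,1.201
ProteinMPNN (T=0.1),0.487,0.168,112,0.975,1.019,1.061
ProteinMPNN (T=0.5),0.430,0.299,112,0.965,1.320,1.174
GPD,0.462,0.219,35,0.967,1.758,1.333
PiFold,0.428,0.141,221,0.945,1.592,1.464
Noise,0.049,0.111,–,0.185,11.830,1.628
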