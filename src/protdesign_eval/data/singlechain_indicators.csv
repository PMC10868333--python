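Method,Recovery,Diversity,Time (s),SS score,Nonpolar loss,RMSD (Å),Qualified rate
Structured Transformer,0.279,0.105,13,0.738,0.759,1.763,0.151
ProteinSolver,0.176,0.511,180,0.632,1.157,1.827,0.001
ESM-IF1,0.320,0.277,1980,0.735,0.805,1.534,0.248
ProteinMPNN,0.264,0.226,112,0.749,0.805,1.477,0.278
GPD,0.280,0.278,35,0.740,0.923,1.782,0.045
PiFold,0.256,0.114,221,0.680,1.074,1.707,0.076
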