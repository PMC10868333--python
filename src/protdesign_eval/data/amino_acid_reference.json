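{
  "comment": "background: average amino-acid composition of UniProtKB/Swiss-Prot (release 2023), fractions; max_sasa: theoretical maximal solvent-accessible surface area per residue type in Å² (Tien et al. 2013); nonpolar: default hydrophobic residue set.",
  "background": {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686
  },
  "max_sasa": {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0
  },
  "nonpolar": ["A", "V", "L", "I", "M", "F", "W", "P"]
}
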