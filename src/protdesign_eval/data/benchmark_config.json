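{
  "orientations": {
    "Recovery": "benefit",
    "Diversity": "benefit",
    "Time (s)": "cost-linear",
    "SS score": "benefit",
    "RMSD (Å)": "cost-reciprocal",
    "Nonpolar loss": "cost-linear",
    "Qualified rate": "benefit"
  },
  "denovo_subjective_weights": {
    "Recovery": 0.050,
    "Diversity": 0.163,
    "Time (s)": 0.038,
    "SS score": 0.089,
    "RMSD (Å)": 0.48,
    "Nonpolar loss": 0.177
  },
  "singlechain_subjective_weights": {
    "Recovery": 0.036,
    "Diversity": 0.104,
    "Time (s)": 0.028,
    "SS score": 0.062,
    "Nonpolar loss": 0.112,
    "RMSD (Å)": 0.329,
    "Qualified rate": 0.329
  },
  "denovo_published_critic_weights": {
    "Recovery": 0.100,
    "Diversity": 0.196,
    "Time (s)": 0.367,
    "SS score": 0.099,
    "RMSD (Å)": 0.104,
    "Nonpolar loss": 0.135
  },
  "singlechain_published_critic_weights": {
    "Recovery": 0.103,
    "Diversity": 0.216,
    "Time (s)": 0.237,
    "SS score": 0.106,
    "Nonpolar loss": 0.109,
    "RMSD (Å)": 0.120,
    "Qualified rate": 0.108
  },
  "lambda_subjective": 0.5,
  "missing_policy": "worst-impute",
  "qualified_rmsd_cutoff": 2.0
}
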