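# protdesign-eval

Multi-indicator evaluation of fixed-backbone (inverse-folding) protein
sequence design methods.

Deep-learning sequence design models — ProteinMPNN, ESM-IF1, ABACUS-R,
PiFold and friends — are usually compared by sequence recovery alone,
which ignores diversity, foldability and the physical plausibility of
the designed structures. This package implements a complete evaluation
system for such methods, aimed at both users choosing a design tool and
developers probing where their model loses ground:

- **Indicators** computed from designed sequences and folded structures:
  *Recovery* (positional identity to the native sequence), *Diversity*
  (1 − mean pairwise identity among designs), *Time*, *SS score* (3-state
  secondary-structure identity, assigned from Cα geometry), *RMSD*
  (minimal Cα RMSD after Kabsch superposition; optionally split into the
  mean RMSD of *qualified* designs with RMSD < 2 Å and the *Qualified
  rate*), and *Nonpolar loss* (exposure-weighted hydrophobic surface
  content relative to the native, via a coarse Shrake–Rupley SASA).
- **Ranking** by weighted TOPSIS. Cost indicators are first converted to
  benefits (max-minus for Time and Nonpolar loss, reciprocal for RMSD)
  and Z-scored. Objective weights come from CRITIC
  (w_j ∝ σ_j·Σ_k(1−r_jk)), subjective weights from a fuzzy-AHP pairwise
  comparison matrix (or an explicit weight row), combined 50:50 by
  default. Each method's relative closeness is
  C_i = D⁻_i/(D⁺_i + D⁻_i), the distances being to the ideal worst and
  best solutions; larger C_i is better.
- **Sensitivity analysis** of the ranking across the subjective-weight
  proportion λ ∈ [0, 1].
- **Temperature selection**: candidate sampling temperatures plotted in
  the recovery × diversity plane are classified into a 3×3 selection
  (McKinsey-style) matrix whose per-axis thresholds are midpoints of the
  three cluster centers from exact, deterministic 1-D k-means.
- **Noise baseline** (random sequences from natural amino-acid
  frequencies) anchoring the indicator floor, a **synthetic benchmark
  generator** with controllable recovery/diversity targets, and
  **continuous-repeat statistics** (maximal runs of identical residues
  with their secondary-structure context).

## Worked example

Rank the eleven methods of the shipped *de novo* benchmark table
(11 methods × 6 indicators, including the Noise baseline):

```python
import protdesign_eval as pe

table = pe.load_denovo_table()
cfg = pe.load_benchmark_config()
result, weights = pe.evaluate(
    table, subjective_weights=cfg["denovo_subjective_weights"])
print(result.frame.round(3))
```

```
                           Ci  Rank
Structured Transformer  0.529     9
ProteinSolver           0.364    10
3D CNN (Energy)         0.568     7
3D CNN (LogP)           0.624     4
ABACUS-R                0.605     5
ESM-IF1                 0.704     3
ProteinMPNN (T=0.1)     0.763     2
ProteinMPNN (T=0.5)     0.787     1
GPD                     0.593     6
PiFold                  0.541     8
Noise                   0.062    11
```

ProteinMPNN at sampling temperature 0.5 wins (Ci 0.787): it trades a
little recovery for much more diversity while keeping RMSD low. The
random-sequence Noise baseline is last by a wide margin, as any sane
evaluation must have it. The three weight rows are available as
`weights["subjective"]`, `weights["objective"]` and `weights["combined"]`
(here CRITIC gives Time the largest objective weight, 0.33, because it
varies enormously and correlates with nothing).

The same works from the shell:

```
protdesign-eval evaluate --table table.csv --config config.json --out report.csv
protdesign-eval sensitivity --table table.csv --config config.json --grid 0:1:0.1 --out sweep.csv
protdesign-eval temp-select --points points.csv --out selection.csv
protdesign-eval noise --lengths 100,200 --count 50 --seed 7 --out noise.fasta
protdesign-eval repeats --designs designs/ --min-run 3 --out repeats.csv
protdesign-eval fixture --config fixture.json --out fixture/
```

## Layout

- `src/protdesign_eval/io.py` — FASTA/PDB/CSV/JSON readers and writers,
  core types (`SequenceRecord`, `StructureModel`, `IndicatorTable`)
- `src/protdesign_eval/indicators.py` — indicator computations and table
  assembly
- `src/protdesign_eval/mcdm.py` — preprocessing, CRITIC, fuzzy AHP,
  TOPSIS, `TopsisEvaluator`, sensitivity sweep
- `src/protdesign_eval/temperature.py` — exact 1-D k-means (`KMeans1D`),
  thresholds, 3×3 classification (`McKinseySelector`)
- `src/protdesign_eval/baselines.py` — noise baseline, synthetic
  benchmark generator
- `src/protdesign_eval/repeats.py` — continuous-repeat statistics
- `src/protdesign_eval/datasets.py` — shipped benchmark tables and
  reference data
- `docs/methods.md` — models, assumptions, numerical choices,
  limitations
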