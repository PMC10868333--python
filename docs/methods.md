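# Methods

This note documents the models and procedures the package implements,
the defaults that matter, and what the synthetic tests do and do not
demonstrate about real design pipelines.

## Indicators

**Recovery** is positional identity between a design and the native
sequence. Fixed-backbone designs share the native's length by
construction, so no alignment is performed and a length mismatch is an
error rather than a cue to align; `X` positions are excluded from the
count. A method's recovery is the mean over designs, and across target
proteins the unweighted mean of per-protein means, so every target
counts equally regardless of its design count.

**Diversity** is 1 − mean pairwise positional identity over all
unordered pairs of a design set, computed on all designs (never only on
the structurally qualified subset — the two agree closely in practice
and restricting would couple a sequence measure to a structure filter).

**Secondary-structure score** compares 3-state (H/E/C) strings
positionally. The package assigns states from Cα geometry alone, in the
spirit of P-SEA: windows on the Cα(i)–Cα(i+2,3,4) distances
(helix ≈ 5.4/5.1/6.2 Å, strand ≈ 6.2–8.0/9.0–12.0 Å) mark the residues
they span; coil is the default. This makes the score self-contained
(the folded model is already in hand), at the cost of ignoring
hydrogen-bond topology; externally produced 3-state strings can be
supplied wherever an SS string is consumed.

**RMSD** is the minimal Cα RMSD after centroid removal and the optimal
proper rotation (Kabsch via SVD, reflections excluded; the rotation
solver is `scipy.spatial.transform.Rotation.align_vectors`, with
residuals re-evaluated explicitly for precision). Fewer than three
residues or collinear coordinates are rejected as degenerate. For
longer single-chain targets the indicator is split into the **qualified
rate** (fraction of designs with RMSD strictly below 2 Å) and the mean
RMSD over qualified designs only; the mean is undefined (reported
missing) when nothing qualifies.

**Nonpolar loss** measures whether hydrophobic residues sit on the
surface more than they do in the native structure. Per-residue relative
solvent accessibility (RSA) comes from a coarse Shrake–Rupley scheme:
each residue is one sphere centred on its Cα, its radius calibrated so
that an isolated residue exposes exactly the maximal reference SASA of
its type (Tien et al. 2013 theoretical values, shipped with the
package); 100 deterministic Fibonacci-lattice sample points per sphere,
probe radius 1.4 Å, RSA clamped to [0, 1]. The score of a model is
S = Σ RSA over the nonpolar set {A, V, L, I, M, F, W, P} (an RSA cutoff
is available but the default is the cutoff-free weighted sum), and
Nonpolar loss = S(design)/S(native); values above 1 mean more exposed
hydrophobic surface than the native. The single-sphere model is
deliberately coarse — it has no side-chain atoms — so absolute RSAs are
approximate; the design/native ratio cancels much of the bias.

## Ranking pipeline

Orientation: Time and Nonpolar loss are linear costs (x → max − x);
RMSD is a reciprocal cost (x → 1/x), which compresses outliers and
spreads the informative sub-2 Å range; Recovery, Diversity, SS score
and Qualified rate are benefits. At most one missing cell per column is
tolerated; the default policy imputes the worst observed raw value of
the column (conservative: a method with an unrecorded time gains no
time benefit), with best-/mean-impute and drop-column available. The
shipped *de novo* table's published closeness column is reproduced to
±0.002 under best-impute — the missing cell belongs to the random
baseline, whose generation cost is genuinely negligible — while the
conservative default still reproduces the top and bottom ranks and the
winner's closeness within 0.01.

Standardization is the column Z-score with sample (n−1) standard
deviation; n−1 is used consistently everywhere a spread is computed.

**CRITIC** objective weights: w_j ∝ σ_j · Σ_k (1 − r_jk), with Pearson
correlations between oriented columns and σ_j the standard deviation of
the min-max normalized column (the classical formulation). Min-max
rather than Z-score spread matters: Z-scoring forces every σ to 1 and
would reduce CRITIC to pure conflict, whereas the min-max spread lets
an indicator that separates methods strongly (Time, in the shipped
benchmark) carry more objective weight. The self term of the conflict
sum contributes exactly zero either way. CRITIC needs at least three
methods and two indicators, and no constant column.

**Fuzzy AHP** subjective weights: a reciprocal matrix of triangular
fuzzy numbers (l, m, u) on the 1–9 scale is aggregated by row-wise
component geometric means, divided by the order-reversing fuzzy sum,
defuzzified by the centroid (l+m+u)/3 and normalized. The consistency
ratio is Saaty's, computed on the middle-value crisp matrix with the
standard random-index table; CR ≥ 0.1 warns but does not fail, since
the weights remain usable and the caller may prefer to rejudge. Any
consistent crisp ratio matrix reproduces its generating weights to
1e-9. A bypass mode accepts an explicit subjective weight row, which is
how the shipped benchmark's published AHP rows are injected.

**Combination**: w = λ·w_subjective + (1−λ)·w_objective with λ = 0.5 by
default, renormalized defensively. The sensitivity sweep re-scores the
standardized matrix over a λ grid (default 0 to 1 in steps of 0.1,
which must contain 0.5); CRITIC is data-determined and computed once.

**TOPSIS**: v = z·w per column, ideal best/worst are column-wise
max/min of v, D± the Euclidean distances, C_i = D⁻/(D⁺+D⁻). Ranks are
dense on descending C_i; ties share the smaller rank and are flagged. A
method identical to both ideals (all columns constant) is degenerate.

## Temperature selection

All candidate settings (possibly from several methods) are pooled;
each axis — recovery, then diversity — is clustered into three groups
by exact 1-D k-means, solved by dynamic programming over the sorted
values (optimal 1-D clusters are contiguous, so the DP is exact and
needs no seed; cost is O(k·n²), trivial at these sizes). The two
thresholds per axis are the midpoints of adjacent cluster centers —
three centers yield exactly two such averages. Points fall into a 3×3
grid; the recommended setting is any point in the (high, high) cell,
ties broken by Euclidean distance to the vertex (max recovery, max
diversity over the pool), with optional per-axis scale factors for
users who weight one axis over the other. If (high, high) is empty the
best occupied cell wins — recovery band ordered before diversity — and
the recommendation is flagged as outside the attractive region.

## Noise baseline and synthetic benchmark

Noise sequences are i.i.d. draws per position from a natural
amino-acid background (Swiss-Prot average composition, shipped and
overridable; normalized to sum to 1 at load). The expected recovery of
noise against a native is analytically the inner product of the
background with the native's composition, ≈ 0.05–0.06 for natural
sequences — the floor the baseline anchors.

The synthetic benchmark emulates a fixed-backbone design study: native
Cα traces are ideal α-helices (rise 1.5 Å, twist 100°, radius 2.3 Å)
with sequences drawn from the background; "folded" design structures
are the native trace plus isotropic Gaussian noise (default 0.2 Å).
Design sequences are built by partitioning positions into three
classes: a fraction g mutated to one shared decoy letter (lowers
recovery, adds no diversity), a fraction h mutated independently per
design to a uniform non-native letter (lowers recovery, adds diversity
h·18/19 in expectation), the rest native. Solving g and h from the
targets gives expected recovery exactly 1−g−h and expected diversity
h·18/19, so a (recovery, diversity) pair is feasible iff
diversity ≤ (1−recovery)·18/19; infeasible pairs raise an error quoting
the bound. Everything is driven by one `numpy` Generator seed, so
fixtures are byte-identical per seed.

What passing on this fixture shows: the indicator computations, the
ranking machinery and their couplings are correct, and measured
indicators match the generator's ground truth within sampling error.
What it does not show: behaviour on real folded structures (no side
chains, no strand topology, no folding failures) or on real design
models' error modes.

## Repeat-run statistics

A repeat run is a maximal stretch of one residue type of length ≥ 3 by
default (doublets are ubiquitous in natural sequences and would swamp
the signal; the threshold is exposed). Runs are found by a linear scan
verified against a regular-expression oracle. When a 3-state SS string
is supplied, each run gets the majority state over its span, ties
resolving to coil (runs can straddle element boundaries). Aggregation
keeps one record per run, so every pivot (per method × residue, per
sequence, residue × SS state) is consistent with the raw counts by
construction.

## Problem sizes and determinism

The shipped benchmark tables are small (11×6 and 6×7) and the pipeline
on them is exact and deterministic. Stochastic tests (noise
frequencies, fixture target recovery) use fixed seeds and 3-standard-
error bands; the synthetic benchmark used in tests has 2–3 proteins of
length 60–200 with 8–100 designs, sizes at which the sampling error of
the targets is well below the asserted tolerances.

## Known limitations

- The Cα-sphere SASA is a stand-in for full-atom accessibility; use the
  ratio (Nonpolar loss), not absolute RSAs, for cross-model claims.
- The geometric SS assigner handles ideal and mildly noisy geometry
  well but is not a DSSP replacement; supply external 3-state strings
  for publication-grade SS scores.
- CRITIC/fuzzy-AHP variants abound; the implemented forms (min-max
  spread CRITIC, geometric-mean/centroid FAHP) are the classical ones,
  and an explicit-weight bypass exists precisely so any externally
  derived weight row can be used instead.
- The evaluation consumes already-folded structures; folding the
  designs is out of scope.
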