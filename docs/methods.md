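# Methods

## Problem and pipeline

The package predicts mesoscale anatomical connectivity between brain
regions from voxel-level gene expression.  The processing chain is:

1. **Grids.**  Expression lives on a coarse grid (200 µm; each voxel holds
   one expression-energy value per gene), projections on a fine grid
   (100 µm; exactly 2× the coarse grid per axis, so one coarse voxel covers
   8 fine voxels).  All grids are flat vectors with an explicit `dims`
   triple; the first axis varies fastest, and every file carries a sidecar
   or header stating dims, resolution and axis order.
2. **Aggregation.**  Per injection experiment and target region: the median
   of the projection values over *all* the target's voxels (zeros included
   — the volume defines a value everywhere; an even count averages the two
   middle values in float64).  Per ordered pair: the maximum of the
   per-experiment medians.  A pair whose source has no experiment is
   absent, not zero.
3. **Labels.**  Multi-class: 0 ↦ class 0, [0.006, 0.1) ↦ class 1,
   ≥ 0.1 ↦ class 2; binary: 0 ↦ 0, > 0.006 ↦ 1.  The boundary value
   c = 0.1 goes to class 2 (the class definitions leave it unassigned; the
   choice is measure-zero and documented here).  Values in the uncovered
   gap (0, 0.006) — and (0, 0.006] for binary — are *excluded* from
   datasets rather than forced into a class.  "Unconnected" means exactly
   zero after aggregation; no detection floor is applied.
4. **Vectors.**  M voxels per region side per pair, sampled uniformly
   without replacement among *eligible* voxels (annotated to the region and
   not all-zero in expression, mirroring the store's zero-row filter);
   smaller regions fall back to sampling with replacement and warn.  The
   default pairing matches i-th source with i-th target voxel (M vectors
   per pair); a full M² cross product is available.  Per-pair draws are
   seeded by (seed, source, target), so the dataset is independent of pair
   iteration order.
5. **Scaling and splits.**  Min-max scaling to [0, 1] fitted on the
   training split only (constant features map to 0; out-of-range values in
   other splits are clipped); a flag allows fitting on the full set for
   strict replication of pipelines that scale before splitting.  Splits are
   stratified by label with exact rounded sizes — test = round(0.20·n),
   validation = round(0.08·n), train = remainder; these default fractions
   reproduce a 10,499/1,167/2,917 partition of n = 14,583.  A pair-disjoint
   split (all vectors of a region pair in one part) exists for
   generalization analyses; see the control below.
6. **Classifier.**  input → dense(64, sigmoid) → dropout → dense(32, ReLU)
   → dropout → dense(32, ReLU) → dropout → head.  Heads: 3-way softmax with
   categorical cross-entropy (200 epochs, batch 6) or single sigmoid with
   binary cross-entropy (100 epochs, batch 32).  Optimizer: Nadam with
   lr = 0.002, β₁ = 0.9, β₂ = 0.999, ε = 1e-7 and learning-rate decay
   lr_t = lr / (1 + 0.004·t) per update.  Glorot-uniform initialization,
   inverted dropout, per-epoch shuffling; every random draw is seeded, and
   training is single-threaded numpy, so runs reproduce bitwise.  The
   validation split is monitored only — no early stopping; the epoch budget
   is fixed.  Decision rule: argmax, or score > 0.5 for binary; the ROC
   sweeps all thresholds and AUC is trapezoidal.

The implementation is pure numpy (forward, backward and the optimizer are
written out explicitly); scikit-learn supplies the scaler and the
evaluation metrics, which double as an independent check on the toy cases
frozen in the tests.

## Synthetic atlas

The generator emulates the structures the real pipeline consumes, with a
planted mechanism implementing "connected regions have similar expression":

* **Ground truth.**  Region embeddings e_r ~ N(0, I_d).  Ordered pair
  (s, t): with probability `frac_unconnected` the connectivity is exactly
  0; otherwise c_st = σ(effect_size · ⟨e_s, e_t⟩ + b_st) with b_st ~ N(0,1)
  independent per pair.  Region mean profiles are
  baseline_g + (e_r · W)_g with W fixed and baselines ~ U(2, 4) per gene —
  a deterministic linear read-out of the embeddings, so profile similarity
  tracks embedding similarity.  `effect_size = 0` makes connectivity
  statistically independent of expression while leaving every marginal
  unchanged — the negative control.  The sigmoid keeps values in (0, 1)
  like projection densities, and with moderate effect sizes populates all
  three label strata.
* **Annotation volumes.**  Regions are contiguous axis-aligned blocks from
  a recursive bisection of the coarse grid (anatomical realism is
  irrelevant to the computation under test); when the grid can spare it, a
  one-voxel slab stays unannotated (background 0), so downstream code must
  handle voxels outside any structure.  The fine volume replicates each
  coarse voxel 2× per axis.
* **Expression.**  Voxel v in region r carries
  max(0, profile_rg + N(0, noise_sd)) — Gaussian noise truncated at zero,
  the simplest non-negative noise model.  Background columns are zero.
* **Injections.**  Each experiment draws one multiplicative attenuation
  scale ∈ (1 − jitter, 1] (peripheral injection sites under-report), then
  fills connected targets' voxels with max(0, c_st·scale + N(0,
  noise_sd·c_st)).  Attenuation never exceeds 1, so the max-over-medians
  rule is a consistent estimator of the planted value, and with all noise
  off it recovers it exactly — the round-trip the tests assert.  Unconnected
  targets stay exactly zero.

What the generator does **not** emulate: realistic anatomy, spatial
autocorrelation within regions (voxel noise is i.i.d.), secondary injection
spillover, gene–gene correlation structure beyond the shared latent space,
and the heavy-tailed intensity distributions of real tracer data.  Passing
tests therefore certify the computational machinery — aggregation,
labeling, dataset construction, training, metrics — not biological claims
about real atlases.

## Reference study conditions

`voxconn.benchmarks` freezes the conditions used by the tests, the
acceptance script and the analysis drivers: 8 regions on a (16, 12, 14)
coarse grid, 50 genes, latent dimension 4, 3 injections per source, 40%
unconnected pairs, and M = 10 voxels per side.  The strong-signal task uses
effect_size = 6 with noise_sd = 0.05 and jitter = 0.2; the zero-signal
control is identical with effect_size = 0.  These sizes keep a full
generate→train→evaluate cycle in single-digit seconds on one CPU core while
every region keeps hundreds of voxels.

Two choices here were genuinely open:

* **Dropout at small scale.**  The published-style rates (0.3 after the
  first hidden layer, 0.2 after the others) remain the `MLPConfig`
  defaults, but the reference tasks train on a few hundred vectors — two
  orders of magnitude less data — where those rates prevent convergence
  within the fixed epoch budget.  The benchmarks use 0.1/0.1/0.1;
  regularization strength has to follow the data regime.
* **Scoring the zero-signal control.**  With a vector-level split, vectors
  of the same region pair land on both sides, and a classifier can recall
  the pair's (arbitrary) label from the region's expression fingerprint —
  above-chance accuracy through memorization, with no
  expression↔connectivity relation at all.  The control therefore uses a
  pair-disjoint test split, scores one majority-vote prediction per
  held-out pair (vectors of one pair are strongly dependent, so the pair is
  the exchangeable unit), and compares against the exact binomial 95% band
  around the training majority rate at n = held-out pairs.

## Storage

The relational store uses the four pipeline tables `voxID2Annotation`,
`voxID2GenExpr`, `injection2regionID`, `injection2target`, with
zero-expression rows omitted from `voxID2GenExpr` and restored as zeros on
load.  A small `meta` table (schema version, dims, resolution, gene-ID
list) makes the file self-describing; loads verify the schema version.
Voxel IDs are 0-based flat indices.  Raw volumes are little-endian float32
(int32 for annotations) with JSON sidecars; projections are raw-encoded
NRRD; the reader trusts header dims and validates payload length, never
hard-coding grid sizes.

## Numerical and degenerate-input choices

* Even-count medians average the two middle values, computed in float64
  regardless of the storage dtype.
* `aggregate_pair([])` is an error: a pair with no experiments is absent,
  not zero-valued.
* A class absent from a test set gets NaN (undefined) recall/F1, never 0.
* Split rounding is half-up; the three parts always sum to n exactly.
* Harmonization maps a voxel to its *nearest* ancestor in the target set,
  is idempotent, and rejects cyclic structure graphs.
* Seeds: every stochastic component derives its generator from an explicit
  integer seed through independent seed sequences, so stages can be rerun
  in isolation without perturbing each other.

## Limitations

The classifier's accuracy on the synthetic tasks says nothing quantitative
about real atlas data — the planted signal is far cleaner than biology.
Region geometry is block-shaped; harmonization is exercised on a three-level
graph, not a full ontology.  The optimizer implements one common Nadam
formulation with momentum bias-correction; other libraries' variants differ
in the third decimal of an update, which fixed seeds absorb but bitwise
cross-library comparisons would not.
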