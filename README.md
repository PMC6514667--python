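# voxconn

Can the gene-expression profile of two brain regions tell you whether they
are anatomically connected?  `voxconn` implements a complete, testable
pipeline for this question in the style of mouse-brain atlas studies: it
takes voxel-level in-situ hybridization expression grids (200 µm) and
viral-tracer projection-density volumes (100 µm), aggregates projections
into a per-pair connectivity value, thresholds that value into categorical
labels, builds concatenated *Source–Target* expression vectors, and trains a
small multilayer perceptron to predict the connectivity label from
expression alone.

Because the real atlas volumes are only available through remote APIs, the
package ships a first-class **synthetic atlas generator** with a planted,
tunable expression↔connectivity coupling: each region carries a latent
embedding *e_r*; the connectivity of an ordered pair (s, t) is (when not
forced to zero) a sigmoid of `effect_size · ⟨e_s, e_t⟩` plus an independent
per-pair offset, and region mean expression profiles are a fixed linear map
of the same embeddings.  Setting `effect_size = 0` severs the link and
yields an exact negative control.  Every downstream stage is therefore
verifiable against known ground truth, offline.

## The method

* **Aggregation (median-then-max).**  For one injection experiment and one
  target region, the projection densities over the target's voxels are
  summarized by their *median* (robust to outliers).  When several
  experiments share a source region, the pair's final connectivity value
  `c` is the *maximum* of the per-experiment medians — the injection with
  the best spatial conditions speaks for the pair.
* **Labels.**  Multi-class: `c = 0` → unconnected (0), `0.006 ≤ c < 0.1` →
  weakly connected (1), `c ≥ 0.1` → strongly connected (2).  Binary:
  `c = 0` → 0, `c > 0.006` → 1.  Values in the uncovered gap are excluded.
* **Vectors.**  Per labeled pair, M voxels are drawn from each region; the
  i-th source voxel's full G-gene profile is concatenated with the i-th
  target voxel's (length 2G, source half first).  Features are min-max
  scaled to [0, 1] with the scaler fitted on the training split only.
* **Classifier.**  A feed-forward network
  `input → 64 (sigmoid) → 32 (ReLU) → 32 (ReLU) → head`, with a dropout
  layer after each hidden layer, trained by the Nadam optimizer
  (lr 0.002, decay 0.004, β₁ 0.9, β₂ 0.999): softmax + categorical
  cross-entropy for 3 classes (200 epochs, batch 6), or sigmoid + binary
  cross-entropy (100 epochs, batch 32).  The implementation is pure numpy
  and fully seeded.

## Worked example

The numbered drivers under `analysis/` run the study end to end at desk
scale (8 regions, 50 genes, 3 injections per source) and write their tables
under `results/`:

```sh
python analysis/01_simulate_atlas.py
python analysis/02_aggregate_labels.py
python analysis/04_train_binary.py
```

prints

```
Simulated atlas written to scratch/atlas_run/data
  8 regions, 50 genes, 24 injection experiments
  coarse grid 2688 voxels (200 um), fine grid 21504 voxels (100 um)
56 ordered region pairs aggregated (median-then-max)
  excluded (value in the (0, 0.006) threshold gap): 7
  class 0 (unconnected): 19 pairs
  class 1 (weakly connected): 9 pairs
  class 2 (strongly connected): 21 pairs
seed 1: accuracy 0.951, AUC 0.996
...
mean accuracy 0.942, mean AUC 0.986
zero-signal control: pair accuracy 0.455 on 11 held-out pairs; chance band
[0.234, 0.833] -> within chance
```

Read: of the 8·7 = 56 ordered region pairs, 49 fall into a labelable class;
with the planted coupling switched on, the MLP separates connected from
unconnected pairs almost perfectly (mean test accuracy 0.942, mean AUC
0.986 over five seeds), while on the control atlas — identical in every way
except that connectivity is statistically independent of expression — its
accuracy on held-out region pairs stays inside the 95% chance band.  The
signal, not the plumbing, carries the performance.

The same workflow is available as a CLI over a single YAML config:

```sh
voxconn run-all --config run.yaml --out myrun --seed 1
```

with subcommands `generate`, `ingest`, `label`, `build-dataset`, `train`,
`evaluate` for stage-wise runs; every stage leaves a manifest (config hash,
input hashes, row counts) so runs are exactly reproducible.

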