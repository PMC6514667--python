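"""Reference experiments on the synthetic atlas.

These functions pin down the study conditions used to validate the
pipeline: a strong-signal binary task the classifier must solve, a
zero-signal control it must not beat chance on, and a three-class task with
well-separated strata.  They are used by the test suite, the acceptance
script and the analysis drivers, so the conditions are defined exactly once.

Scale rationale: 8 regions on a (16, 12, 14) coarse grid with 50 genes keeps
a full generate->train->evaluate cycle in the low seconds on one CPU core
while leaving every region with hundreds of voxels, enough for the M=10
voxel draws to vary across pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import binomtest

from voxconn.datasets import (
    BuildConfig,
    DatasetSplit,
    apply_class_caps,
    build_dataset,
    normalize,
    split_by_pairs,
    split_dataset,
)
from voxconn.labels import LabelScheme, compute_pair_connectivity, label_pairs
from voxconn.mlp import MLP, MLPConfig, evaluate, train
from voxconn.synthetic import SyntheticConfig, generate_dataset

#: The reference tasks train on a few hundred vectors, two orders of
#: magnitude below a full-scale dataset; they use light dropout because the
#: full-scale rates over-regularize that regime.
LIGHT_DROPOUT = (0.1, 0.1, 0.1)

#: Strong planted coupling, low noise: the task the classifier must solve.
STRONG_SIGNAL = SyntheticConfig(
    n_regions=8,
    grid_dims_expr=(16, 12, 14),
    n_genes=50,
    latent_dim=4,
    effect_size=6.0,
    noise_sd=0.05,
    injection_jitter=0.2,
    n_injections_per_source=3,
    frac_unconnected=0.4,
)

#: Identical geometry with the coupling switched off: the negative control.
ZERO_SIGNAL = SyntheticConfig(
    n_regions=8,
    grid_dims_expr=(16, 12, 14),
    n_genes=50,
    latent_dim=4,
    effect_size=0.0,
    noise_sd=0.05,
    injection_jitter=0.2,
    n_injections_per_source=3,
    frac_unconnected=0.4,
)


def build_split(
    synth: SyntheticConfig,
    scheme: LabelScheme,
    build: BuildConfig,
    fractions: tuple[float, float, float] = (0.72, 0.08, 0.20),
    pair_disjoint: bool = False,
) -> DatasetSplit:
    """Generate -> aggregate -> label -> vectorize -> split -> scale."""
    data = generate_dataset(synth)
    pairs = compute_pair_connectivity(
        data["experiments"], data["annotation_fine"], list(synth.region_ids)
    )
    table = label_pairs(pairs, scheme)
    ds = build_dataset(table, data["annotation_coarse"], data["expression"], build)
    ds = apply_class_caps(ds, build.per_class_cap, build.seed)
    splitter = split_by_pairs if pair_disjoint else split_dataset
    split = splitter(ds, fractions, build.seed)
    train_n, (val_n, test_n), _ = normalize(
        split.train, [split.validation, split.test]
    )
    return DatasetSplit(train_n, val_n, test_n, split.split_seed)


@dataclass(frozen=True)
class BinaryResult:
    accuracy: float
    auc: float
    final_train_accuracy: float
    final_val_accuracy: float
    n_test: int


def run_binary_task(seed: int, epochs: int = 100) -> BinaryResult:
    """Strong-signal binary task: M=10 voxel pairs, 100-epoch training."""
    synth = replace(STRONG_SIGNAL, seed=seed)
    scheme = LabelScheme(mode="binary")
    build = BuildConfig(
        M=10, per_class_cap={0: 20000, 1: 17136}, seed=seed + 1
    )
    split = build_split(synth, scheme, build)
    cfg = MLPConfig.binary_default(
        split.train.features.shape[1], seed=seed + 2, epochs=epochs,
        dropout_rates=LIGHT_DROPOUT,
    )
    model = MLP(cfg)
    history = train(model, split, cfg)
    report = evaluate(model, split.test, history)
    return BinaryResult(
        accuracy=report.accuracy,
        auc=float(report.auc),
        final_train_accuracy=float(history["train_accuracy"].iloc[-1]),
        final_val_accuracy=float(history["val_accuracy"].iloc[-1]),
        n_test=len(split.test),
    )


@dataclass(frozen=True)
class ControlResult:
    """Pair-level accuracy of the zero-signal control vs. chance."""

    pair_accuracy: float
    majority_rate: float
    n_test_pairs: int
    ci_low: float
    ci_high: float

    @property
    def within_chance(self) -> bool:
        return self.ci_low <= self.pair_accuracy <= self.ci_high


def run_zero_signal_control(seed: int, epochs: int = 100) -> ControlResult:
    """Train on the no-coupling generator; score pair-disjoint test pairs.

    The test split is pair-disjoint because with vectors of the same region
    pair on both sides of the split a network can recall the pair's
    (arbitrary) label from the region expression fingerprint; that tests
    memorization, not an expression-connectivity relation.  Accuracy is
    scored per held-out pair (majority vote over its vectors) since vectors
    of one pair are strongly dependent; the 95% interval is the binomial
    band around the training majority-class rate at n = held-out pairs.
    """
    synth = replace(ZERO_SIGNAL, seed=seed)
    scheme = LabelScheme(mode="binary")
    build = BuildConfig(M=10, per_class_cap={0: 20000, 1: 17136}, seed=seed + 1)
    split = build_split(synth, scheme, build, pair_disjoint=True)
    cfg = MLPConfig.binary_default(
        split.train.features.shape[1], seed=seed + 2, epochs=epochs,
        dropout_rates=LIGHT_DROPOUT,
    )
    model = MLP(cfg)
    train(model, split, cfg)

    counts = np.bincount(split.train.labels, minlength=2)
    majority = counts.argmax()
    majority_rate = counts.max() / counts.sum()

    keys = split.test.pair_keys()
    pred = model.predict(split.test.features.astype(float))
    correct = 0
    uniq = np.unique(keys)
    for key in uniq:
        mask = keys == key
        vote = np.bincount(pred[mask], minlength=2).argmax()
        correct += int(vote == split.test.labels[mask][0])
    n_pairs = len(uniq)
    ci = binomtest(
        int(round(majority_rate * n_pairs)), n_pairs, majority_rate
    ).proportion_ci(confidence_level=0.95, method="exact")
    return ControlResult(
        pair_accuracy=correct / n_pairs,
        majority_rate=float(majority_rate),
        n_test_pairs=n_pairs,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


@dataclass(frozen=True)
class MulticlassResult:
    accuracy: float
    macro_f1: float
    final_train_accuracy: float
    n_test: int


def run_multiclass_task(seed: int, epochs: int = 200) -> MulticlassResult:
    """Strong-signal three-class task (unconnected / weak / strong)."""
    synth = replace(STRONG_SIGNAL, seed=seed)
    scheme = LabelScheme(mode="multiclass")
    build = BuildConfig(M=10, per_class_cap={0: 5000, 1: 5000, 2: None}, seed=seed + 1)
    split = build_split(synth, scheme, build)
    cfg = MLPConfig.multiclass_default(
        split.train.features.shape[1], seed=seed + 2, epochs=epochs,
        dropout_rates=LIGHT_DROPOUT,
    )
    model = MLP(cfg)
    history = train(model, split, cfg)
    report = evaluate(model, split.test, history)
    valid = ~np.isnan(report.f1)
    return MulticlassResult(
        accuracy=report.accuracy,
        macro_f1=float(np.nanmean(report.f1)) if valid.any() else float("nan"),
        final_train_accuracy=float(history["train_accuracy"].iloc[-1]),
        n_test=len(split.test),
    )
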