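"""Source-Target vector construction, class balancing, scaling, splitting.

A Source-Target vector concatenates the full gene-expression profile of one
voxel of the Source region with that of one voxel of the Target region
(length 2G, source half first) and carries the pair's connectivity label.
Per pair, M voxels are sampled from each side; the default pairing mode
matches the i-th source voxel with the i-th target voxel (M vectors per
pair), with a full M x M cross product available as an option.

Class sizes are balanced by per-class caps, features are min-max scaled to
[0, 1] with the scaler fitted on the training partition only (values of the
other partitions are clipped), and the dataset is split into stratified
train / validation / test parts with exact rounded sizes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from voxconn.errors import ConfigError, EmptyRegionError
from voxconn.grid_io import AnnotationVolume, ExpressionMatrix
from voxconn.labels import EXCLUDED, PairConnectivity


@dataclass(frozen=True)
class BuildConfig:
    """Vector-construction parameters.

    ``M`` voxels are sampled per region side per pair; ``per_class_cap``
    limits how many vectors of each label survive (None = keep all);
    ``pairing_mode`` is ``index_paired`` (M vectors per pair) or
    ``cross_product`` (M^2).
    """

    M: int = 21
    per_class_cap: Mapping[int, int | None] = field(
        default_factory=lambda: {0: 5000, 1: 5000, 2: None}
    )
    pairing_mode: str = "index_paired"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ConfigError("M must be >= 1")
        if self.pairing_mode not in {"index_paired", "cross_product"}:
            raise ConfigError(f"unknown pairing mode {self.pairing_mode!r}")
        if any(c is not None and c < 0 for c in self.per_class_cap.values()):
            raise ConfigError("class caps must be >= 0")


@dataclass(frozen=True)
class SourceTargetDataset:
    """Columnar collection of Source-Target vectors."""

    features: np.ndarray  # (n, 2G) float32
    labels: np.ndarray  # (n,) int
    source_region: np.ndarray
    target_region: np.ndarray
    source_voxel: np.ndarray
    target_voxel: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.features.shape != (n, 2 * self.n_genes):
            raise ConfigError(
                f"features shape {self.features.shape} inconsistent with "
                f"{n} vectors of 2x{self.n_genes} genes"
            )

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "SourceTargetDataset":
        return SourceTargetDataset(
            self.features[idx],
            self.labels[idx],
            self.source_region[idx],
            self.target_region[idx],
            self.source_voxel[idx],
            self.target_voxel[idx],
            self.n_genes,
        )

    def pair_keys(self) -> np.ndarray:
        """One opaque key per (source region, target region) pair."""
        return (
            self.source_region.astype(np.int64) << 32
        ) | self.target_region.astype(np.int64)

    @classmethod
    def concatenate(
        cls, parts: Sequence["SourceTargetDataset"]
    ) -> "SourceTargetDataset":
        if not parts:
            raise ConfigError("nothing to concatenate")
        g = parts[0].n_genes
        return cls(
            np.concatenate([p.features for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.source_region for p in parts]),
            np.concatenate([p.target_region for p in parts]),
            np.concatenate([p.source_voxel for p in parts]),
            np.concatenate([p.target_voxel for p in parts]),
            g,
        )

    def to_csv(self, path: str | Path) -> None:
        meta = pd.DataFrame(
            {
                "source_region": self.source_region,
                "target_region": self.target_region,
                "source_voxel": self.source_voxel,
                "target_voxel": self.target_voxel,
                "label": self.labels,
            }
        )
        feats = pd.DataFrame(
            self.features,
            columns=[f"f{i}" for i in range(self.features.shape[1])],
        )
        pd.concat([meta, feats], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SourceTargetDataset":
        df = pd.read_csv(path)
        meta_cols = [
            "source_region",
            "target_region",
            "source_voxel",
            "target_voxel",
            "label",
        ]
        feats = df.drop(columns=meta_cols).to_numpy(dtype=np.float32)
        return cls(
            feats,
            df["label"].to_numpy(int),
            df["source_region"].to_numpy(int),
            df["target_region"].to_numpy(int),
            df["source_voxel"].to_numpy(int),
            df["target_voxel"].to_numpy(int),
            feats.shape[1] // 2,
        )


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive train / validation / test partition."""

    train: SourceTargetDataset
    validation: SourceTargetDataset
    test: SourceTargetDataset
    split_seed: int


def eligible_voxels(
    region: int, annot: AnnotationVolume, expr: ExpressionMatrix
) -> np.ndarray:
    """Voxels of ``region`` with at least one nonzero expression value."""
    voxels = annot.voxels_of(region)
    if voxels.size == 0:
        return voxels
    keep = np.asarray((expr.values[:, voxels] != 0).any(axis=0))
    return voxels[keep]


def select_region_voxels(
    region: int,
    annot: AnnotationVolume,
    expr: ExpressionMatrix,
    M: int,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Sample M voxel IDs from a region, uniformly and reproducibly.

    Sampling is without replacement when the region has >= M eligible
    voxels; smaller regions are sampled with replacement and a warning is
    emitted.  Voxels whose expression column is all zero are ineligible
    (they carry no signal and are dropped by the store's zero filter).
    """
    pool = eligible_voxels(region, annot, expr)
    if pool.size == 0:
        raise EmptyRegionError(f"region {region} has no eligible voxels")
    rng = np.random.default_rng(seed)
    if pool.size >= M:
        return rng.choice(pool, size=M, replace=False)
    warnings.warn(
        f"region {region}: only {pool.size} eligible voxels for M={M}; "
        "sampling with replacement",
        stacklevel=2,
    )
    return rng.choice(pool, size=M, replace=True)


def build_pair_vectors(
    pair: PairConnectivity,
    src_voxels: np.ndarray,
    tgt_voxels: np.ndarray,
    expr: ExpressionMatrix,
    mode: str = "index_paired",
    label: int | None = None,
) -> SourceTargetDataset:
    """Concatenate source and target voxel profiles into feature vectors.

    ``index_paired`` yields M vectors (i-th source with i-th target voxel);
    ``cross_product`` yields all M^2 combinations.  The first G features are
    the source voxel's profile, the last G the target's.
    """
    if len(src_voxels) != len(tgt_voxels):
        raise ConfigError("source and target voxel lists must have equal length")
    v = expr.voxel_count
    all_vox = np.concatenate([src_voxels, tgt_voxels])
    if all_vox.size and (all_vox.min() < 0 or all_vox.max() >= v):
        raise ConfigError("voxel id outside the expression matrix")
    if mode == "index_paired":
        sv, tv = np.asarray(src_voxels), np.asarray(tgt_voxels)
    elif mode == "cross_product":
        sv = np.repeat(src_voxels, len(tgt_voxels))
        tv = np.tile(tgt_voxels, len(src_voxels))
    else:
        raise ConfigError(f"unknown pairing mode {mode!r}")
    feats = np.concatenate(
        [expr.values[:, sv].T, expr.values[:, tv].T], axis=1
    ).astype(np.float32)
    n = len(sv)
    return SourceTargetDataset(
        feats,
        np.full(n, label if label is not None else 0, dtype=int),
        np.full(n, pair.source_region, dtype=int),
        np.full(n, pair.target_region, dtype=int),
        sv.astype(int),
        tv.astype(int),
        expr.n_genes,
    )


def build_dataset(
    labeled_pairs: pd.DataFrame,
    annot: AnnotationVolume,
    expr: ExpressionMatrix,
    config: BuildConfig,
) -> SourceTargetDataset:
    """Build the full vector dataset from a labeled pair table.

    Pairs labeled EXCLUDED (threshold gap) and self-pairs are skipped.  Each
    pair's voxel draw is seeded from (config.seed, source, target) so the
    result is independent of pair iteration order.
    """
    parts: list[SourceTargetDataset] = []
    kept = labeled_pairs[
        (labeled_pairs["label"] != EXCLUDED)
        & (labeled_pairs["source_region"] != labeled_pairs["target_region"])
    ]
    for row in kept.itertuples(index=False):
        s, t = int(row.source_region), int(row.target_region)
        ss = np.random.SeedSequence([config.seed, s, t, 0])
        ts = np.random.SeedSequence([config.seed, s, t, 1])
        src = select_region_voxels(s, annot, expr, config.M, ss)
        tgt = select_region_voxels(t, annot, expr, config.M, ts)
        pair = PairConnectivity(s, t, float(row.value), int(row.n_experiments))
        parts.append(
            build_pair_vectors(
                pair, src, tgt, expr, config.pairing_mode, int(row.label)
            )
        )
    if not parts:
        raise ConfigError("no pairs survive label exclusion")
    return SourceTargetDataset.concatenate(parts)


def apply_class_caps(
    ds: SourceTargetDataset,
    caps: Mapping[int, int | None],
    seed: int,
) -> SourceTargetDataset:
    """Uniformly subsample each class down to its cap (None = keep all)."""
    present = np.unique(ds.labels)
    missing = [int(c) for c in present if int(c) not in caps]
    if missing:
        raise ConfigError(f"no cap defined for labels {missing}")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for label in present:
        idx = np.flatnonzero(ds.labels == label)
        cap = caps[int(label)]
        if cap is not None and idx.size > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(np.sort(idx))
    return ds.subset(np.concatenate(keep)) if keep else ds


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _stratified_take(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Pick k indices stratified by label (largest-remainder allocation)."""
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    quotas = counts * (k / n)
    take = np.floor(quotas).astype(int)
    remainder = quotas - take
    short = k - take.sum()
    for ci in np.argsort(-remainder)[:short]:
        take[ci] += 1
    chosen: list[np.ndarray] = []
    for c, t in zip(classes, take):
        idx = np.flatnonzero(labels == c)
        if t > idx.size:
            raise ConfigError(f"class {c} too small for requested split")
        chosen.append(rng.choice(idx, size=t, replace=False))
    return np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)


def split_dataset(
    ds: SourceTargetDataset,
    fractions: tuple[float, float, float] = (0.72, 0.08, 0.20),
    seed: int = 0,
) -> DatasetSplit:
    """Stratified train / validation / test split with exact rounded sizes.

    Sizes: test = round(f_test * n), validation = round(f_val * n), train =
    remainder (round half up), so the three parts always sum to n.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("fractions must be positive and sum to 1")
    n = len(ds)
    n_test = _round_half_up(f_test * n)
    n_val = _round_half_up(f_val * n)
    if n_test + n_val >= n:
        raise ConfigError("split leaves no training data")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(n)
    test_idx = _stratified_take(ds.labels, n_test, rng)
    rest = np.setdiff1d(all_idx, test_idx)
    val_local = _stratified_take(ds.labels[rest], n_val, rng)
    val_idx = rest[val_local]
    train_idx = np.setdiff1d(rest, val_idx)
    present = set(np.unique(ds.labels).tolist())
    for name, idx in (("train", train_idx), ("validation", val_idx), ("test", test_idx)):
        if set(np.unique(ds.labels[idx]).tolist()) != present and len(idx) >= len(present):
            raise ConfigError(f"{name} partition lost a class")
    return DatasetSplit(
        ds.subset(train_idx), ds.subset(val_idx), ds.subset(test_idx), seed
    )


def split_by_pairs(
    ds: SourceTargetDataset,
    fractions: tuple[float, float, float] = (0.72, 0.08, 0.20),
    seed: int = 0,
) -> DatasetSplit:
    """Pair-disjoint split: all vectors of a region pair land in one part.

    Used for generalization checks where vector-level splitting would let a
    model answer from memorized pair identity rather than from any
    expression-connectivity relation.  Stratified over pair labels; sizes
    are in pairs, not vectors.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("fractions must be positive and sum to 1")
    keys = ds.pair_keys()
    uniq, first = np.unique(keys, return_index=True)
    pair_labels = ds.labels[first]
    n_pairs = len(uniq)
    n_test = max(1, _round_half_up(f_test * n_pairs))
    n_val = max(1, _round_half_up(f_val * n_pairs))
    if n_test + n_val >= n_pairs:
        raise ConfigError("too few pairs for a pair-disjoint split")
    rng = np.random.default_rng(seed)
    test_p = _stratified_take(pair_labels, n_test, rng)
    rest_p = np.setdiff1d(np.arange(n_pairs), test_p)
    val_local = _stratified_take(pair_labels[rest_p], n_val, rng)
    val_p = rest_p[val_local]
    train_p = np.setdiff1d(rest_p, val_p)
    def part(pidx: np.ndarray) -> SourceTargetDataset:
        mask = np.isin(keys, uniq[pidx])
        return ds.subset(np.flatnonzero(mask))
    return DatasetSplit(part(train_p), part(val_p), part(test_p), seed)


def normalize(
    train: SourceTargetDataset,
    others: Sequence[SourceTargetDataset] = (),
    fit_on_all: bool = False,
) -> tuple[SourceTargetDataset, list[SourceTargetDataset], MinMaxScaler]:
    """Min-max scale features to [0, 1], fitting on the training part only.

    The identical affine map is applied to the other partitions, whose
    out-of-range values are clipped to [0, 1]; a constant training feature
    maps to 0 everywhere.  ``fit_on_all`` fits on the union instead (strict
    replication of pipelines that scale before splitting).
    """
    if len(train) == 0:
        raise ConfigError("cannot fit a scaler on an empty training set")
    scaler = MinMaxScaler(clip=True)
    if fit_on_all:
        scaler.fit(
            np.concatenate([train.features] + [o.features for o in others])
        )
    else:
        scaler.fit(train.features)
    train_n = replace(
        train, features=scaler.transform(train.features).astype(np.float32)
    )
    others_n = [
        replace(o, features=scaler.transform(o.features).astype(np.float32))
        for o in others
    ]
    return train_n, others_n, scaler


def export_split(
    split: DatasetSplit,
    out_dir: str | Path,
    scaler: MinMaxScaler | None = None,
    build_config: BuildConfig | None = None,
) -> None:
    """Write the three partitions as CSV plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, part in (
        ("train", split.train),
        ("validation", split.validation),
        ("test", split.test),
    ):
        part.to_csv(out / f"{name}.csv")
    manifest = {
        "n_genes": split.train.n_genes,
        "sizes": {
            "train": len(split.train),
            "validation": len(split.validation),
            "test": len(split.test),
        },
        "split_seed": split.split_seed,
    }
    if build_config is not None:
        manifest["M"] = build_config.M
        manifest["pairing_mode"] = build_config.pairing_mode
        manifest["per_class_cap"] = {
            str(k): v for k, v in build_config.per_class_cap.items()
        }
        manifest["build_seed"] = build_config.seed
    if scaler is not None:
        manifest["scaler"] = {
            "data_min": scaler.data_min_.tolist(),
            "data_max": scaler.data_max_.tolist(),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
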