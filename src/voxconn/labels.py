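"""Connectivity aggregation and threshold labeling.

The connectivity of an ordered Source-Target region pair is computed in two
stages: within one injection experiment, the projection-density values over
the target's voxels are summarized by their median (robust to outliers);
when several experiments share the same source region, the pair's final
value is the maximum of the per-experiment medians, which favours the
injection with the best spatial conditions and suppresses peripheral
injections that under-report the connection.

The aggregated value c is then mapped to a categorical label by empirical
thresholds: in the multi-class scheme c = 0 is "unconnected" (0),
0.006 <= c < 0.1 is "weakly connected" (1) and c >= 0.1 is "strongly
connected" (2); in the binary scheme c = 0 is 0 and c > 0.006 is 1.  Values
in the uncovered gap (0, 0.006) (and (0, 0.006] for binary) are excluded
from datasets rather than forced into a class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from voxconn.errors import ConfigError, EmptyRegionError
from voxconn.grid_io import AnnotationVolume, InjectionExperiment

#: Sentinel label for pairs whose value falls in the threshold gap.
EXCLUDED = -1


@dataclass(frozen=True)
class LabelScheme:
    """Thresholds turning an aggregated connectivity value into a class."""

    mode: str = "multiclass"  # or "binary"
    t_low: float = 0.006
    t_high: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in {"multiclass", "binary"}:
            raise ConfigError(f"unknown label mode {self.mode!r}")
        if not 0 < self.t_low < self.t_high:
            raise ConfigError("thresholds must satisfy 0 < t_low < t_high")

    @property
    def n_classes(self) -> int:
        return 3 if self.mode == "multiclass" else 2


@dataclass(frozen=True)
class PairConnectivity:
    """One ordered region pair with its aggregated connectivity value."""

    source_region: int
    target_region: int
    value: float
    n_experiments: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ConfigError("connectivity value must be non-negative")
        if self.n_experiments < 1:
            raise ConfigError("a pair needs at least one experiment")


def experiment_target_median(
    exp: InjectionExperiment,
    target_region: int,
    annot_fine: AnnotationVolume,
) -> float:
    """Median projection density of one experiment over one target region.

    The median runs over all voxels annotated to the target (zeros
    included — the projection volume defines a value everywhere); an even
    voxel count uses the mean of the two middle values.
    """
    voxels = annot_fine.voxels_of(target_region)
    if voxels.size == 0:
        raise EmptyRegionError(
            f"region {target_region} has no voxels in the fine annotation"
        )
    # accumulate in float64: the even-count midpoint must not depend on the
    # storage precision of the projection volume
    return float(np.median(exp.projection[voxels].astype(np.float64)))


def aggregate_pair(medians: Sequence[float]) -> float:
    """Final pair value: max of the per-experiment medians."""
    if len(medians) == 0:
        raise ValueError(
            "pair has no contributing experiments; it should be absent, not 0"
        )
    arr = np.asarray(medians, dtype=float)
    if arr.min() < 0:
        raise ValueError("medians must be non-negative")
    return float(arr.max())


def assign_label(c: float, scheme: LabelScheme) -> int:
    """Map an aggregated connectivity value to a class label or EXCLUDED."""
    if c < 0:
        raise ValueError(f"connectivity must be non-negative, got {c}")
    if scheme.mode == "multiclass":
        if c == 0:
            return 0
        if c < scheme.t_low:
            return EXCLUDED
        if c < scheme.t_high:
            return 1
        return 2
    # binary
    if c == 0:
        return 0
    if c > scheme.t_low:
        return 1
    return EXCLUDED


def compute_experiment_medians(
    experiments: Iterable[InjectionExperiment],
    annot_fine: AnnotationVolume,
    regions: Sequence[int] | None = None,
) -> dict[tuple[int, int], float]:
    """Per-(experiment, target) medians — the injection2target table content.

    Self-pairs (target == the experiment's source) are skipped.
    """
    if regions is None:
        regions = [int(r) for r in annot_fine.region_ids()]
    medians: dict[tuple[int, int], float] = {}
    for exp in experiments:
        for t in regions:
            if t == exp.source_region:
                continue
            medians[(exp.experiment_id, t)] = experiment_target_median(
                exp, t, annot_fine
            )
    return medians


def compute_pair_connectivity(
    experiments: Sequence[InjectionExperiment],
    annot_fine: AnnotationVolume,
    regions: Sequence[int] | None = None,
) -> list[PairConnectivity]:
    """Median-then-max aggregation over all ordered region pairs.

    Pairs whose source region has no experiment are absent from the result
    (not reported as zero).
    """
    if regions is None:
        regions = [int(r) for r in annot_fine.region_ids()]
    by_source: dict[int, list[InjectionExperiment]] = {}
    for exp in experiments:
        by_source.setdefault(exp.source_region, []).append(exp)
    pairs: list[PairConnectivity] = []
    for s in regions:
        exps = by_source.get(s, [])
        if not exps:
            continue
        for t in regions:
            if t == s:
                continue
            meds = [experiment_target_median(e, t, annot_fine) for e in exps]
            pairs.append(PairConnectivity(s, t, aggregate_pair(meds), len(meds)))
    return pairs


def pairs_from_medians(
    medians: Mapping[tuple[int, int], float],
    injection_sources: Mapping[int, int],
) -> list[PairConnectivity]:
    """Aggregate stored (injection, target) medians into pair values.

    ``injection_sources`` maps experiment ID to its source region (the
    injection2regionID table).
    """
    grouped: dict[tuple[int, int], list[float]] = {}
    for (inj, target), med in medians.items():
        source = injection_sources[inj]
        grouped.setdefault((source, target), []).append(med)
    return [
        PairConnectivity(s, t, aggregate_pair(meds), len(meds))
        for (s, t), meds in sorted(grouped.items())
    ]


def label_pairs(
    pairs: Sequence[PairConnectivity], scheme: LabelScheme
) -> pd.DataFrame:
    """Tabulate pairs with their labels (EXCLUDED rows kept, flagged)."""
    rows = [
        {
            "source_region": p.source_region,
            "target_region": p.target_region,
            "value": p.value,
            "n_experiments": p.n_experiments,
            "label": assign_label(p.value, scheme),
        }
        for p in pairs
    ]
    df = pd.DataFrame(
        rows,
        columns=["source_region", "target_region", "value", "n_experiments", "label"],
    )
    df["excluded"] = df["label"] == EXCLUDED
    return df
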