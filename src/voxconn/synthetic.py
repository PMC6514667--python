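"""Synthetic Allen-style atlas with a planted expression-connectivity signal.

The generator emulates the three ingredients of the real analysis at
configurable scale: an annotation volume partitioned into contiguous regions
(coarse 200 um grid and a 2x-per-axis fine 100 um grid), per-gene expression
grids whose region-level mean profiles are a linear read-out of latent
region embeddings, and repeated tracer-injection experiments whose
projection volumes are noisy renderings of a planted pair-connectivity
table.

The planted mechanism implements the premise that anatomically connected
regions have similar expression: each region carries a latent embedding
``e_r``; the connectivity of an ordered pair (s, t), when not forced to
zero, is a sigmoid of ``effect_size * <e_s, e_t>`` plus an independent
per-pair offset, and region mean expression profiles are a fixed linear map
of the same embeddings plus per-gene baselines.  ``effect_size = 0``
decouples expression from connectivity entirely, giving a clean negative
control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from voxconn.errors import ConfigError
from voxconn.grid_io import (
    AnnotationVolume,
    Dims,
    ExpressionMatrix,
    InjectionExperiment,
    StructureGraph,
    write_annotation,
    write_expression_volume,
    write_projection_volume,
)

# region IDs: root and two intermediate groups, leaves from _LEAF_BASE
_ROOT_ID = 1
_GROUP_IDS = (2, 3)
_LEAF_BASE = 10


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic atlas.

    ``grid_dims_expr`` is the coarse (expression, 200 um) grid; the fine
    (connectivity, 100 um) grid is exactly 2x per axis, mirroring the
    resolution ratio of the real atlases.  ``effect_size`` scales the
    planted expression-connectivity coupling; ``noise_sd`` is the sd of the
    truncated-Gaussian voxel noise; ``injection_jitter`` is the width of the
    multiplicative per-experiment attenuation in [0, 1), so each experiment
    under-reports the planted value by at most that fraction and the
    max-over-experiments rule is a consistent estimator.
    """

    n_regions: int = 8
    grid_dims_expr: Dims = (16, 12, 14)
    n_genes: int = 50
    latent_dim: int = 4
    effect_size: float = 3.0
    noise_sd: float = 0.1
    injection_jitter: float = 0.3
    n_injections_per_source: int = 3
    frac_unconnected: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ConfigError("n_regions must be positive")
        if len(self.grid_dims_expr) != 3 or any(d < 1 for d in self.grid_dims_expr):
            raise ConfigError("grid_dims_expr must be a triple of positive ints")
        if int(np.prod(self.grid_dims_expr)) < self.n_regions:
            raise ConfigError("grid too small: every region needs >= 1 voxel")
        if self.n_genes < 1 or self.latent_dim < 1:
            raise ConfigError("n_genes and latent_dim must be positive")
        if self.latent_dim > self.n_genes:
            raise ConfigError("latent_dim must not exceed n_genes")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ConfigError("effect_size and noise_sd must be non-negative")
        if not 0 <= self.injection_jitter < 1:
            raise ConfigError("injection_jitter must lie in [0, 1)")
        if self.n_injections_per_source < 1:
            raise ConfigError("n_injections_per_source must be positive")
        if not 0 <= self.frac_unconnected <= 1:
            raise ConfigError("frac_unconnected must lie in [0, 1]")

    @property
    def grid_dims_conn(self) -> Dims:
        """Fine (100 um) grid: 2x the coarse grid per axis."""
        return tuple(2 * d for d in self.grid_dims_expr)

    @property
    def region_ids(self) -> tuple[int, ...]:
        return tuple(_LEAF_BASE + i for i in range(self.n_regions))

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass(frozen=True)
class GroundTruth:
    """The planted quantities every downstream stage is checked against."""

    region_ids: tuple[int, ...]
    region_embeddings: np.ndarray  # (n_regions, latent_dim)
    pair_connectivity: dict[tuple[int, int], float] = field(repr=False)
    region_mean_profiles: np.ndarray = field(repr=False)  # (n_regions, G)

    def embedding_similarity(self, s: int, t: int) -> float:
        """Dot product of the two region embeddings."""
        idx = {r: i for i, r in enumerate(self.region_ids)}
        return float(self.region_embeddings[idx[s]] @ self.region_embeddings[idx[t]])


def generate_ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Draw region embeddings, pair connectivity and region mean profiles.

    Nonzero pair connectivity is ``sigmoid(effect_size * <e_s, e_t> + b_st)``
    with an independent standard-normal per-pair offset ``b_st``; a fraction
    ``frac_unconnected`` of ordered pairs is forced to exactly 0.  Region
    mean profiles are ``baseline_g + (e_r @ W)_g`` with a fixed random map W
    and per-gene baselines, i.e. a deterministic linear function of the
    embeddings.
    """
    rng = config._rng(0)
    n, d, g = config.n_regions, config.latent_dim, config.n_genes
    embeddings = rng.normal(size=(n, d))
    mixing = rng.normal(size=(d, g)) / np.sqrt(d)
    baselines = rng.uniform(2.0, 4.0, size=g)
    profiles = baselines[None, :] + embeddings @ mixing

    region_ids = config.region_ids
    pair_connectivity: dict[tuple[int, int], float] = {}
    for i, s in enumerate(region_ids):
        for j, t in enumerate(region_ids):
            if s == t:
                continue
            unconnected = rng.random() < config.frac_unconnected
            offset = rng.normal()
            if unconnected:
                pair_connectivity[(s, t)] = 0.0
            else:
                sim = float(embeddings[i] @ embeddings[j])
                pair_connectivity[(s, t)] = float(
                    expit(config.effect_size * sim + offset)
                )
    return GroundTruth(region_ids, embeddings, pair_connectivity, profiles)


def _split_box(lo: np.ndarray, hi: np.ndarray, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Recursively bisect an axis-aligned box into k boxes of >= 1 voxel."""
    if k == 1:
        return [(lo.copy(), hi.copy())]
    extent = hi - lo
    axis = int(np.argmax(extent))
    k1 = k // 2
    cut = lo[axis] + max(1, min(extent[axis] - 1, round(extent[axis] * k1 / k)))
    lo_a, hi_a = lo.copy(), hi.copy()
    hi_a[axis] = cut
    lo_b, hi_b = lo.copy(), hi.copy()
    lo_b[axis] = cut
    if np.prod(hi_a - lo_a) < k1 or np.prod(hi_b - lo_b) < k - k1:
        raise ConfigError("grid dims too skewed to host all regions")
    return _split_box(lo_a, hi_a, k1) + _split_box(lo_b, hi_b, k - k1)


def generate_annotation_volume(
    config: SyntheticConfig,
) -> tuple[AnnotationVolume, AnnotationVolume]:
    """Partition the coarse grid into contiguous region blocks; upsample 2x.

    Regions are axis-aligned boxes from a recursive bisection of the volume;
    when the grid is large enough, a one-voxel slab along the longest axis is
    left unannotated (background 0) so downstream code must handle voxels
    outside any structure.  The fine volume replicates every coarse voxel
    into the 8 fine voxels it contains, so both resolutions agree
    region-wise.  The layout is a deterministic function of the config.
    """
    dims = np.array(config.grid_dims_expr, dtype=int)
    grid = np.zeros(dims, dtype=np.int32)
    lo = np.zeros(3, dtype=int)
    hi = dims.copy()
    # reserve a background slab when the grid can spare it
    axis = int(np.argmax(dims))
    interior = dims.copy()
    interior[axis] -= 1
    if dims[axis] > 1 and int(np.prod(interior)) >= config.n_regions:
        hi[axis] -= 1
    boxes = _split_box(lo, hi, config.n_regions)
    for region_id, (blo, bhi) in zip(config.region_ids, boxes):
        grid[blo[0] : bhi[0], blo[1] : bhi[1], blo[2] : bhi[2]] = region_id
    coarse = AnnotationVolume(
        tuple(int(d) for d in dims), 200, grid.ravel(order="F")
    )
    fine_grid = grid.repeat(2, axis=0).repeat(2, axis=1).repeat(2, axis=2)
    fine = AnnotationVolume(
        tuple(int(2 * d) for d in dims), 100, fine_grid.ravel(order="F")
    )
    return coarse, fine


def generate_expression_grids(
    truth: GroundTruth, annot: AnnotationVolume, config: SyntheticConfig
) -> ExpressionMatrix:
    """Render per-gene expression grids from the region mean profiles.

    Voxel v in region r carries ``max(0, profile[r, g] + N(0, noise_sd))``
    for each gene g; background voxels are all-zero columns.  Gene IDs are
    1..G.
    """
    rng = config._rng(2)
    g = config.n_genes
    values = np.zeros((g, annot.n_voxels), dtype=np.float32)
    for i, region in enumerate(truth.region_ids):
        voxels = annot.voxels_of(region)
        if voxels.size == 0:
            continue
        block = np.tile(truth.region_mean_profiles[i][:, None], (1, voxels.size))
        if config.noise_sd > 0:
            block = block + rng.normal(0.0, config.noise_sd, size=block.shape)
        values[:, voxels] = np.maximum(block, 0.0)
    return ExpressionMatrix(tuple(range(1, g + 1)), values)


def generate_injection_experiments(
    truth: GroundTruth, annot_fine: AnnotationVolume, config: SyntheticConfig
) -> list[InjectionExperiment]:
    """Simulate repeated tracer injections per source region.

    Each experiment draws one multiplicative attenuation factor in
    ``(1 - injection_jitter, 1]`` (peripheral injection sites under-report
    the true projection strength), then fills the voxels of every connected
    target t with ``max(0, c_st * scale + N(0, noise_sd * c_st))``.  Voxels
    of unconnected targets, of the source region itself and of the
    background stay exactly 0 (only the projections, not the injection
    site, matter downstream: self-pairs are never formed).
    """
    rng = config._rng(3)
    experiments: list[InjectionExperiment] = []
    exp_id = 0
    target_voxels = {r: annot_fine.voxels_of(r) for r in truth.region_ids}
    for s in truth.region_ids:
        for _ in range(config.n_injections_per_source):
            exp_id += 1
            scale = 1.0 - config.injection_jitter * rng.random()
            proj = np.zeros(annot_fine.n_voxels, dtype=np.float32)
            for t in truth.region_ids:
                if t == s:
                    continue
                c = truth.pair_connectivity[(s, t)]
                if c == 0.0:
                    continue
                vox = target_voxels[t]
                vals = np.full(vox.size, c * scale)
                if config.noise_sd > 0:
                    vals = vals + rng.normal(0.0, config.noise_sd * c, size=vox.size)
                proj[vox] = np.maximum(vals, 0.0)
            experiments.append(
                InjectionExperiment(exp_id, s, annot_fine.dims, proj)
            )
    return experiments


def make_structure_graph(config: SyntheticConfig) -> StructureGraph:
    """Small hierarchy: root -> two group nodes -> region leaves.

    Leaves alternate between the two groups so annotation roll-up has real
    work to do in tests.
    """
    nodes: dict[int, tuple[str, int | None]] = {_ROOT_ID: ("ROOT", None)}
    nodes[_GROUP_IDS[0]] = ("GRPA", _ROOT_ID)
    nodes[_GROUP_IDS[1]] = ("GRPB", _ROOT_ID)
    for i, leaf in enumerate(config.region_ids):
        nodes[leaf] = (f"R{i:03d}", _GROUP_IDS[i % 2])
    return StructureGraph(nodes)


def generate_dataset(config: SyntheticConfig) -> dict:
    """Run the full generator; returns every object keyed by name."""
    truth = generate_ground_truth(config)
    coarse, fine = generate_annotation_volume(config)
    expr = generate_expression_grids(truth, coarse, config)
    experiments = generate_injection_experiments(truth, fine, config)
    graph = make_structure_graph(config)
    return {
        "config": config,
        "truth": truth,
        "annotation_coarse": coarse,
        "annotation_fine": fine,
        "expression": expr,
        "experiments": experiments,
        "graph": graph,
    }


def write_dataset(data: dict, out_dir: str | Path) -> dict[str, str]:
    """Write a generated dataset in the same formats grid_io reads.

    One raw float32 volume per gene, one NRRD per experiment, both
    annotation vectors, the structure graph as JSON.  Returns a manifest of
    relative paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config: SyntheticConfig = data["config"]
    expr: ExpressionMatrix = data["expression"]
    coarse: AnnotationVolume = data["annotation_coarse"]
    fine: AnnotationVolume = data["annotation_fine"]

    (out / "expression").mkdir(exist_ok=True)
    (out / "projections").mkdir(exist_ok=True)
    manifest: dict[str, str] = {}
    for i, gene in enumerate(expr.gene_ids):
        rel = f"expression/gene_{gene:05d}.raw"
        write_expression_volume(out / rel, expr.values[i], coarse.dims, 200)
        manifest[f"gene_{gene}"] = rel
    for exp in data["experiments"]:
        rel = f"projections/experiment_{exp.experiment_id:05d}.nrrd"
        write_projection_volume(out / rel, exp)
        manifest[f"experiment_{exp.experiment_id}"] = rel
    write_annotation(out / "annotation_200um.raw", coarse)
    write_annotation(out / "annotation_100um.raw", fine)
    data["graph"].to_json(out / "structure_graph.json")
    manifest["annotation_coarse"] = "annotation_200um.raw"
    manifest["annotation_fine"] = "annotation_100um.raw"
    manifest["structure_graph"] = "structure_graph.json"
    sources = {
        str(exp.experiment_id): int(exp.source_region)
        for exp in data["experiments"]
    }
    (out / "injection_sources.json").write_text(json.dumps(sources, indent=1))
    manifest["injection_sources"] = "injection_sources.json"
    return manifest
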