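"""Staged pipeline: generate/ingest -> label -> build -> train -> evaluate.

Each stage reads the previous stage's artifacts from the working directory,
writes its own, and records a JSON manifest (config hash, seeds, input
hashes, row counts) so a completed run is reproducible and a rerun with
unchanged inputs yields a byte-identical manifest.

Layout inside the output directory::

    data/            synthetic or ingested volumes (generate)
    db.sqlite        four-table relational store (ingest)
    pairs.csv        aggregated + labeled region pairs (label)
    dataset/         train/validation/test CSVs + manifest (build)
    model.npz        trained classifier + history.csv (train)
    report.json/.txt test-set quality report (evaluate)
    manifests/       one manifest per completed stage
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from voxconn import grid_io, labels as labels_mod, mlp as mlp_mod, synthetic
from voxconn.datasets import (
    BuildConfig,
    DatasetSplit,
    SourceTargetDataset,
    apply_class_caps,
    build_dataset,
    export_split,
    normalize,
    split_dataset,
)
from voxconn.errors import ConfigError, MissingArtifactError
from voxconn.grid_io import read_annotation, read_expression_volume, read_nrrd
from voxconn.labels import LabelScheme, label_pairs, pairs_from_medians
from voxconn.synthetic import SyntheticConfig

log = logging.getLogger("voxconn")

STAGES = ("generate", "ingest", "label", "build", "train", "evaluate")

_UPSTREAM = {
    "ingest": ("generate", "data"),
    "label": ("ingest", "db.sqlite"),
    "build": ("label", "pairs.csv"),
    "train": ("build", "dataset/train.csv"),
    "evaluate": ("train", "model.npz"),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs: sub-configs plus paths."""

    out_dir: Path
    synthetic: SyntheticConfig = SyntheticConfig()
    scheme: LabelScheme = LabelScheme()
    build: BuildConfig = BuildConfig()
    fractions: tuple[float, float, float] = (0.72, 0.08, 0.20)
    fit_scaler_on_all: bool = False
    mlp_overrides: Mapping[str, Any] = field(default_factory=dict)
    data_dir: Path | None = None  # pre-existing input volumes, else generated
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, **overrides)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], **overrides: Any) -> "PipelineConfig":
        try:
            kw: dict[str, Any] = {}
            kw["out_dir"] = Path(raw.get("out_dir", "voxconn_run"))
            if "data_dir" in raw and raw["data_dir"]:
                kw["data_dir"] = Path(raw["data_dir"])
            syn = dict(raw.get("synthetic", {}))
            if "grid_dims_expr" in syn:
                syn["grid_dims_expr"] = tuple(syn["grid_dims_expr"])
            kw["synthetic"] = SyntheticConfig(**syn)
            kw["scheme"] = LabelScheme(**raw.get("labels", {}))
            build_raw = dict(raw.get("build", {}))
            if "per_class_cap" in build_raw:
                build_raw["per_class_cap"] = {
                    int(k): v for k, v in build_raw["per_class_cap"].items()
                }
            kw["build"] = BuildConfig(**build_raw)
            if "fractions" in raw:
                kw["fractions"] = tuple(raw["fractions"])
            kw["fit_scaler_on_all"] = bool(raw.get("fit_scaler_on_all", False))
            kw["mlp_overrides"] = dict(raw.get("mlp", {}))
            kw["log_level"] = str(raw.get("log_level", "INFO"))
            kw.update(overrides)
            return cls(**kw)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config: {exc}") from exc

    def reseeded(self, seed: int) -> "PipelineConfig":
        """Propagate one master seed into every stochastic sub-config."""
        return dataclasses.replace(
            self,
            synthetic=dataclasses.replace(self.synthetic, seed=seed),
            build=dataclasses.replace(self.build, seed=seed + 1),
            mlp_overrides={**self.mlp_overrides, "seed": seed + 2},
        )


def _config_hash(config: PipelineConfig) -> str:
    def default(o: Any) -> Any:
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(
    config: PipelineConfig, stage: str, inputs: list[Path], counts: Mapping[str, Any]
) -> Path:
    mdir = config.out_dir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config_hash": _config_hash(config),
        "inputs": {
            str(p.relative_to(config.out_dir)): _file_hash(p)
            for p in sorted(inputs)
            if p.is_file()
        },
        "counts": dict(counts),
    }
    path = mdir / f"{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _require(config: PipelineConfig, stage: str) -> None:
    prior, artifact = _UPSTREAM[stage]
    if not (config.out_dir / artifact).exists():
        raise MissingArtifactError(
            f"stage '{stage}' needs '{artifact}', produced by stage "
            f"'{prior}'; run that stage first"
        )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_generate(config: PipelineConfig) -> Path:
    data = synthetic.generate_dataset(config.synthetic)
    out = config.out_dir / "data"
    synthetic.write_dataset(data, out)
    truth = data["truth"]
    (out / "ground_truth.json").write_text(
        json.dumps(
            {
                "region_ids": list(truth.region_ids),
                "pair_connectivity": {
                    f"{s},{t}": v for (s, t), v in truth.pair_connectivity.items()
                },
            },
            indent=1,
        )
    )
    counts = {
        "regions": config.synthetic.n_regions,
        "genes": config.synthetic.n_genes,
        "experiments": len(data["experiments"]),
        "coarse_voxels": data["annotation_coarse"].n_voxels,
        "fine_voxels": data["annotation_fine"].n_voxels,
    }
    log.info("generate: %s", counts)
    return _write_manifest(config, "generate", [], counts)


def load_input_volumes(data_dir: Path) -> dict:
    """Read a data directory in the generator's on-disk layout."""
    coarse = read_annotation(data_dir / "annotation_200um.raw")
    fine = read_annotation(data_dir / "annotation_100um.raw")
    graph = grid_io.StructureGraph.from_json(data_dir / "structure_graph.json")
    gene_files = sorted((data_dir / "expression").glob("gene_*.raw"))
    if not gene_files:
        raise MissingArtifactError(f"no expression volumes under {data_dir}")
    gene_ids, rows = [], []
    for f in gene_files:
        gene_ids.append(int(f.stem.split("_")[1]))
        rows.append(read_expression_volume(f, coarse.dims))
    expr = grid_io.ExpressionMatrix(tuple(gene_ids), np.vstack(rows))
    sources = {
        int(k): int(v)
        for k, v in json.loads(
            (data_dir / "injection_sources.json").read_text()
        ).items()
    }
    experiments = []
    for f in sorted((data_dir / "projections").glob("experiment_*.nrrd")):
        exp_id = int(f.stem.split("_")[1])
        dims, proj = read_nrrd(f)
        experiments.append(
            grid_io.InjectionExperiment(exp_id, sources[exp_id], dims, proj)
        )
    return {
        "annotation_coarse": coarse,
        "annotation_fine": fine,
        "graph": graph,
        "expression": expr,
        "experiments": experiments,
    }


def _stage_ingest(config: PipelineConfig) -> Path:
    data_dir = config.data_dir or (config.out_dir / "data")
    if not data_dir.exists():
        raise MissingArtifactError(
            "stage 'ingest' needs a data directory; run 'generate' or point "
            "data_dir at existing volumes"
        )
    data = load_input_volumes(data_dir)
    medians = labels_mod.compute_experiment_medians(
        data["experiments"], data["annotation_fine"]
    )
    db = config.out_dir / "db.sqlite"
    grid_io.store_database(
        db, data["annotation_coarse"], data["expression"], data["experiments"], medians
    )
    counts = {
        "experiments": len(data["experiments"]),
        "median_rows": len(medians),
        "genes": data["expression"].n_genes,
    }
    log.info("ingest: %s", counts)
    inputs = sorted(p for p in data_dir.rglob("*") if p.is_file())
    if config.data_dir is not None:
        inputs = []  # external inputs are outside out_dir; counts still recorded
    return _write_manifest(config, "ingest", inputs, counts)


def _stage_label(config: PipelineConfig) -> Path:
    _require(config, "label")
    db = config.out_dir / "db.sqlite"
    _, _, injections, medians = grid_io.load_database(db)
    med_map = {
        (int(r.injectionID), int(r.targetID)): float(r.median)
        for r in medians.itertuples(index=False)
    }
    sources = {
        int(r.injectionID): int(r.regionID)
        for r in injections.itertuples(index=False)
    }
    pairs = pairs_from_medians(med_map, sources)
    table = label_pairs(pairs, config.scheme)
    table.to_csv(config.out_dir / "pairs.csv", index=False)
    class_sizes = (
        table.loc[~table["excluded"], "label"].value_counts().sort_index()
    )
    counts = {
        "pairs": len(table),
        "excluded": int(table["excluded"].sum()),
        "class_sizes": {int(k): int(v) for k, v in class_sizes.items()},
    }
    log.info("label: %s", counts)
    return _write_manifest(config, "label", [db], counts)


def _stage_build(config: PipelineConfig) -> Path:
    _require(config, "build")
    db = config.out_dir / "db.sqlite"
    pairs_csv = config.out_dir / "pairs.csv"
    annot, expr, _, _ = grid_io.load_database(db)
    table = pd.read_csv(pairs_csv)
    ds = build_dataset(table, annot, expr, config.build)
    ds = apply_class_caps(ds, config.build.per_class_cap, config.build.seed)
    split = split_dataset(ds, config.fractions, config.build.seed)
    train_n, (val_n, test_n), scaler = normalize(
        split.train,
        [split.validation, split.test],
        fit_on_all=config.fit_scaler_on_all,
    )
    split = DatasetSplit(train_n, val_n, test_n, split.split_seed)
    export_split(split, config.out_dir / "dataset", scaler, config.build)
    counts = {
        "vectors": len(ds),
        "feature_length": 2 * ds.n_genes,
        "class_sizes": {
            int(c): int((ds.labels == c).sum()) for c in np.unique(ds.labels)
        },
        "train": len(split.train),
        "validation": len(split.validation),
        "test": len(split.test),
    }
    log.info("build: %s", counts)
    return _write_manifest(config, "build", [db, pairs_csv], counts)


def _load_split(config: PipelineConfig) -> DatasetSplit:
    ddir = config.out_dir / "dataset"
    parts = [
        SourceTargetDataset.from_csv(ddir / f"{name}.csv")
        for name in ("train", "validation", "test")
    ]
    manifest = json.loads((ddir / "manifest.json").read_text())
    return DatasetSplit(*parts, split_seed=int(manifest["split_seed"]))


def _mlp_config(config: PipelineConfig, input_dim: int) -> mlp_mod.MLPConfig:
    over = dict(config.mlp_overrides)
    for key in ("hidden_widths", "hidden_activations", "dropout_rates"):
        if key in over:
            over[key] = tuple(over[key])
    if config.scheme.mode == "multiclass":
        return mlp_mod.MLPConfig.multiclass_default(input_dim, **over)
    return mlp_mod.MLPConfig.binary_default(input_dim, **over)


def _stage_train(config: PipelineConfig) -> Path:
    _require(config, "train")
    split = _load_split(config)
    cfg = _mlp_config(config, split.train.features.shape[1])
    model = mlp_mod.MLP(cfg)
    history = mlp_mod.train(model, split, cfg)
    mlp_mod.save_model(model, config.out_dir / "model.npz")
    history.to_csv(config.out_dir / "history.csv", index=False)
    counts = {
        "parameters": model.n_parameters,
        "epochs": cfg.epochs,
        "final_train_accuracy": (
            float(history["train_accuracy"].iloc[-1]) if len(history) else None
        ),
    }
    log.info("train: %s", counts)
    inputs = [config.out_dir / "dataset" / f"{n}.csv" for n in ("train", "validation")]
    return _write_manifest(config, "train", inputs, counts)


def _stage_evaluate(config: PipelineConfig) -> Path:
    _require(config, "evaluate")
    split = _load_split(config)
    model = mlp_mod.load_model(config.out_dir / "model.npz")
    history_path = config.out_dir / "history.csv"
    history = pd.read_csv(history_path) if history_path.exists() else None
    report = mlp_mod.evaluate(model, split.test, history)
    report.to_json(config.out_dir / "report.json")
    (config.out_dir / "report.txt").write_text(report.format_table() + "\n")
    counts = {"test": len(split.test), "accuracy": round(report.accuracy, 4)}
    if report.auc is not None:
        counts["auc"] = round(report.auc, 4)
    log.info("evaluate: %s", counts)
    inputs = [config.out_dir / "model.npz", config.out_dir / "dataset" / "test.csv"]
    return _write_manifest(config, "evaluate", inputs, counts)


_STAGE_FN = {
    "generate": _stage_generate,
    "ingest": _stage_ingest,
    "label": _stage_label,
    "build": _stage_build,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
}


def run_stage(stage: str, config: PipelineConfig) -> Path:
    """Run one pipeline stage; returns the path of its manifest."""
    if stage not in _STAGE_FN:
        raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    return _STAGE_FN[stage](config)


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage in order; returns stage -> manifest path."""
    return {stage: run_stage(stage, config) for stage in STAGES}
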