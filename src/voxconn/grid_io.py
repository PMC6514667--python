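"""Volumetric grid I/O, annotation harmonization, and the relational store.

All 3D grids are handled as flat vectors with an explicit ``dims`` triple.
The linearization order is fixed: the first axis varies fastest, i.e. the
flat index of voxel (x, y, z) on a grid of dims (nx, ny, nz) is
``x + nx * (y + ny * z)``.  The order is recorded in every sidecar header so
files written here are self-describing.

Three on-disk formats are supported:

* raw little-endian float32 volumes (``energy.raw`` style) with a JSON
  sidecar carrying dims / resolution / axis order — used for per-gene
  expression grids and annotation vectors (int32 for annotations);
* NRRD (raw encoding) — used for per-injection projection-density volumes;
* an SQLite database with the four pipeline tables ``voxID2Annotation``,
  ``voxID2GenExpr`` (zero-expression rows filtered out), ``injection2regionID``
  and ``injection2target``, plus a ``meta`` table that makes reloads
  self-contained.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from voxconn.errors import GridFormatError, SchemaError, StructureGraphError

SCHEMA_VERSION = 1

Dims = tuple[int, int, int]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationVolume:
    """Maps every voxel of a 3D grid to a brain-region identifier.

    ``region_of_voxel`` is a flat int vector of length prod(dims); 0 marks
    background voxels that belong to no annotated structure.
    """

    dims: Dims
    resolution_um: int
    region_of_voxel: np.ndarray

    def __post_init__(self) -> None:
        vec = np.asarray(self.region_of_voxel, dtype=np.int32)
        object.__setattr__(self, "region_of_voxel", vec)
        expected = int(np.prod(self.dims))
        if vec.shape != (expected,):
            raise GridFormatError(
                f"annotation vector has {vec.size} elements, dims "
                f"{self.dims} require {expected}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.region_of_voxel.size)

    def voxels_of(self, region_id: int) -> np.ndarray:
        """Flat voxel indices annotated with ``region_id``."""
        return np.flatnonzero(self.region_of_voxel == region_id)

    def region_ids(self) -> np.ndarray:
        """Sorted nonzero region IDs present in the volume."""
        ids = np.unique(self.region_of_voxel)
        return ids[ids != 0]

    def as_grid(self) -> np.ndarray:
        """3D view with axes (x, y, z), x fastest in the flat layout."""
        return self.region_of_voxel.reshape(self.dims, order="F")


@dataclass(frozen=True)
class StructureGraph:
    """Hierarchy of brain structures: id -> (acronym, parent id or None)."""

    nodes: dict[int, tuple[str, int | None]]

    def __post_init__(self) -> None:
        roots = [i for i, (_, p) in self.nodes.items() if p is None]
        if len(roots) != 1:
            raise StructureGraphError(
                f"structure graph must have exactly one root, found {len(roots)}"
            )
        for node_id, (_, parent) in self.nodes.items():
            if parent is not None and parent not in self.nodes:
                raise StructureGraphError(
                    f"node {node_id} references missing parent {parent}"
                )
        # cycle check: walk every chain to the root
        for start in self.nodes:
            seen = set()
            cur: int | None = start
            while cur is not None:
                if cur in seen:
                    raise StructureGraphError(f"cycle through node {cur}")
                seen.add(cur)
                cur = self.nodes[cur][1]

    @property
    def root(self) -> int:
        return next(i for i, (_, p) in self.nodes.items() if p is None)

    def ancestors(self, node_id: int) -> list[int]:
        """Chain from ``node_id`` (inclusive) up to the root."""
        chain = []
        cur: int | None = node_id
        while cur is not None:
            chain.append(cur)
            cur = self.nodes[cur][1]
        return chain

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"id": i, "acronym": a, "parent": p}
            for i, (a, p) in sorted(self.nodes.items())
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StructureGraph":
        payload = json.loads(Path(path).read_text())
        return cls({int(n["id"]): (n["acronym"], n["parent"]) for n in payload})


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x voxels expression-energy values (non-negative)."""

    gene_ids: tuple[int, ...]
    values: np.ndarray  # shape (G, V)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float32)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "gene_ids", tuple(int(g) for g in self.gene_ids))
        if vals.ndim != 2 or vals.shape[0] != len(self.gene_ids):
            raise GridFormatError(
                f"expression matrix shape {vals.shape} does not match "
                f"{len(self.gene_ids)} gene ids"
            )
        if vals.size and float(vals.min()) < 0:
            raise GridFormatError("expression energies must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def voxel_count(self) -> int:
        return int(self.values.shape[1])

    def column(self, voxel_id: int) -> np.ndarray:
        return self.values[:, voxel_id]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=list(self.gene_ids))
        df.index.name = "gene_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(int(g) for g in df.index), df.to_numpy(dtype=np.float32))


@dataclass(frozen=True)
class InjectionExperiment:
    """One tracer injection: source region plus its projection-density volume."""

    experiment_id: int
    source_region: int
    dims: Dims
    projection: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        proj = np.asarray(self.projection, dtype=np.float32)
        object.__setattr__(self, "projection", proj)
        expected = int(np.prod(self.dims))
        if proj.shape != (expected,):
            raise GridFormatError(
                f"projection has {proj.size} elements, dims {self.dims} "
                f"require {expected}"
            )


# ---------------------------------------------------------------------------
# Raw float32 volumes (energy.raw style)
# ---------------------------------------------------------------------------


def write_expression_volume(
    path: str | Path, values: np.ndarray, dims: Dims, resolution_um: int = 200
) -> None:
    """Write a flat volume as raw little-endian float32 plus a JSON sidecar."""
    values = np.asarray(values, dtype="<f4")
    expected = int(np.prod(dims))
    if values.size != expected:
        raise GridFormatError(
            f"volume has {values.size} elements, dims {dims} require {expected}"
        )
    path = Path(path)
    path.write_bytes(values.tobytes())
    sidecar = {
        "dims": list(dims),
        "resolution_um": resolution_um,
        "dtype": "float32-le",
        "order": "x-fastest",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_expression_volume(path: str | Path, dims: Dims) -> np.ndarray:
    """Read a raw little-endian float32 volume; validates the byte length."""
    raw = Path(path).read_bytes()
    expected = int(np.prod(dims))
    if len(raw) != 4 * expected:
        actual = len(raw) / 4
        raise GridFormatError(
            f"{path}: expected {expected} float32 elements for dims {dims}, "
            f"file holds {actual:g}"
        )
    return np.frombuffer(raw, dtype="<f4").copy()


def write_annotation(path: str | Path, annot: AnnotationVolume) -> None:
    """Write an annotation vector as raw little-endian int32 plus sidecar."""
    path = Path(path)
    path.write_bytes(annot.region_of_voxel.astype("<i4").tobytes())
    sidecar = {
        "dims": list(annot.dims),
        "resolution_um": annot.resolution_um,
        "dtype": "int32-le",
        "order": "x-fastest",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_annotation(path: str | Path) -> AnnotationVolume:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    dims = tuple(sidecar["dims"])
    raw = path.read_bytes()
    expected = int(np.prod(dims))
    if len(raw) != 4 * expected:
        raise GridFormatError(
            f"{path}: expected {expected} int32 elements, file holds {len(raw) / 4:g}"
        )
    vec = np.frombuffer(raw, dtype="<i4").copy()
    return AnnotationVolume(dims, int(sidecar["resolution_um"]), vec)


# ---------------------------------------------------------------------------
# NRRD (raw encoding) for projection volumes
# ---------------------------------------------------------------------------

_NRRD_MAGIC = "NRRD0004"


def write_nrrd(path: str | Path, values: np.ndarray, dims: Dims) -> None:
    """Write a flat float32 volume as a minimal raw-encoded NRRD file."""
    values = np.asarray(values, dtype="<f4")
    expected = int(np.prod(dims))
    if values.size != expected:
        raise GridFormatError(
            f"volume has {values.size} elements, dims {dims} require {expected}"
        )
    header = (
        f"{_NRRD_MAGIC}\n"
        "type: float\n"
        "dimension: 3\n"
        f"sizes: {dims[0]} {dims[1]} {dims[2]}\n"
        "encoding: raw\n"
        "endian: little\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(values.tobytes())


def read_nrrd(path: str | Path) -> tuple[Dims, np.ndarray]:
    """Read a raw-encoded NRRD volume; dims come from the header.

    Only the subset of NRRD this pipeline writes is supported (3D float,
    raw encoding, little endian); the payload length is validated against
    the header sizes.
    """
    blob = Path(path).read_bytes()
    sep = blob.find(b"\n\n")
    if sep < 0 or not blob.startswith(_NRRD_MAGIC.encode()):
        raise GridFormatError(f"{path}: not a supported NRRD file")
    header_lines = blob[:sep].decode("ascii", errors="replace").splitlines()[1:]
    fields: dict[str, str] = {}
    for line in header_lines:
        if line.startswith("#") or ":" not in line:
            continue
        key, val = line.split(":", 1)
        fields[key.strip().lower()] = val.strip()
    if fields.get("encoding") != "raw":
        raise GridFormatError(f"{path}: unsupported encoding {fields.get('encoding')}")
    if fields.get("type") not in {"float", "float32"}:
        raise GridFormatError(f"{path}: unsupported type {fields.get('type')}")
    try:
        sizes = tuple(int(s) for s in fields["sizes"].split())
    except (KeyError, ValueError) as exc:
        raise GridFormatError(f"{path}: bad or missing sizes field") from exc
    if len(sizes) != 3:
        raise GridFormatError(f"{path}: expected 3 sizes, got {sizes}")
    payload = blob[sep + 2 :]
    expected = int(np.prod(sizes))
    if len(payload) != 4 * expected:
        raise GridFormatError(
            f"{path}: header dims {sizes} require {expected} float32 values, "
            f"payload holds {len(payload) / 4:g}"
        )
    return sizes, np.frombuffer(payload, dtype="<f4").copy()


def write_projection_volume(path: str | Path, exp: InjectionExperiment) -> None:
    write_nrrd(path, exp.projection, exp.dims)


def read_projection_volume(path: str | Path) -> tuple[Dims, np.ndarray]:
    return read_nrrd(path)


# ---------------------------------------------------------------------------
# Annotation harmonization
# ---------------------------------------------------------------------------


def harmonize_annotation(
    annot: AnnotationVolume,
    graph: StructureGraph,
    target_regions: Iterable[int],
) -> AnnotationVolume:
    """Roll every voxel label up to its nearest ancestor in ``target_regions``.

    A voxel keeps its label when the label itself is a target region; a voxel
    whose ancestor chain never meets the target set maps to background (0).
    Dims and resolution are unchanged.  Idempotent for a fixed target set.
    """
    targets = set(int(t) for t in target_regions)
    missing = targets - set(graph.nodes)
    if missing:
        raise StructureGraphError(f"target regions not in graph: {sorted(missing)}")
    mapping: dict[int, int] = {0: 0}
    for region in np.unique(annot.region_of_voxel):
        region = int(region)
        if region in mapping:
            continue
        if region not in graph.nodes:
            raise StructureGraphError(f"annotation uses unknown region {region}")
        mapped = 0
        for anc in graph.ancestors(region):
            if anc in targets:
                mapped = anc
                break
        mapping[region] = mapped
    lut = np.vectorize(mapping.__getitem__, otypes=[np.int32])
    return AnnotationVolume(
        annot.dims, annot.resolution_um, lut(annot.region_of_voxel)
    )


# ---------------------------------------------------------------------------
# SQLite store (four pipeline tables + meta)
# ---------------------------------------------------------------------------


def store_database(
    path: str | Path,
    annot: AnnotationVolume,
    expr: ExpressionMatrix,
    experiments: Sequence[InjectionExperiment],
    pair_medians: Mapping[tuple[int, int], float],
) -> None:
    """Persist the harmonized dataset into the four pipeline tables.

    ``pair_medians`` maps (injection/experiment ID, target region ID) to the
    median projection value of that experiment over the target's voxels.
    ``voxID2GenExpr`` omits rows whose expression value is exactly 0; the
    loader restores them as zeros.  Voxel IDs are 0-based flat indices.
    """
    if expr.voxel_count != annot.n_voxels:
        raise GridFormatError(
            f"expression matrix has {expr.voxel_count} voxels, annotation "
            f"has {annot.n_voxels}"
        )
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        cur = con.cursor()
        cur.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT)")
        cur.execute(
            "CREATE TABLE voxID2Annotation (voxID INTEGER PRIMARY KEY, "
            "annotation INTEGER)"
        )
        cur.execute(
            "CREATE TABLE voxID2GenExpr (genExpr REAL, voxID INTEGER, "
            "genID INTEGER)"
        )
        cur.execute(
            "CREATE TABLE injection2regionID (injectionID INTEGER PRIMARY KEY, "
            "regionID INTEGER)"
        )
        cur.execute(
            "CREATE TABLE injection2target (injectionID INTEGER, median REAL, "
            "targetID INTEGER)"
        )
        meta = {
            "schema_version": str(SCHEMA_VERSION),
            "dims": json.dumps(list(annot.dims)),
            "resolution_um": str(annot.resolution_um),
            "gene_ids": json.dumps(list(expr.gene_ids)),
        }
        cur.executemany("INSERT INTO meta VALUES (?, ?)", meta.items())
        cur.executemany(
            "INSERT INTO voxID2Annotation VALUES (?, ?)",
            (
                (int(v), int(r))
                for v, r in enumerate(annot.region_of_voxel)
            ),
        )
        genes, voxels = np.nonzero(expr.values)
        cur.executemany(
            "INSERT INTO voxID2GenExpr VALUES (?, ?, ?)",
            (
                (float(expr.values[g, v]), int(v), int(expr.gene_ids[g]))
                for g, v in zip(genes, voxels)
            ),
        )
        cur.executemany(
            "INSERT INTO injection2regionID VALUES (?, ?)",
            ((int(e.experiment_id), int(e.source_region)) for e in experiments),
        )
        cur.executemany(
            "INSERT INTO injection2target VALUES (?, ?, ?)",
            (
                (int(inj), float(med), int(tgt))
                for (inj, tgt), med in sorted(pair_medians.items())
            ),
        )
        con.commit()
    finally:
        con.close()


def load_database(
    path: str | Path,
) -> tuple[AnnotationVolume, ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Restore the stored dataset.

    Returns the annotation volume, the expression matrix (zero-filtered
    entries restored as 0), the injection->source table and the
    injection/median/target table, exactly as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    con = sqlite3.connect(path)
    try:
        try:
            meta = dict(con.execute("SELECT key, value FROM meta").fetchall())
        except sqlite3.OperationalError as exc:
            raise SchemaError(f"{path}: no meta table; not a voxconn store") from exc
        version = int(meta.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"{path}: schema version {version}, expected {SCHEMA_VERSION}"
            )
        dims = tuple(json.loads(meta["dims"]))
        resolution = int(meta["resolution_um"])
        gene_ids = [int(g) for g in json.loads(meta["gene_ids"])]

        annot_rows = con.execute(
            "SELECT voxID, annotation FROM voxID2Annotation ORDER BY voxID"
        ).fetchall()
        vec = np.zeros(int(np.prod(dims)), dtype=np.int32)
        for v, r in annot_rows:
            vec[v] = r
        annot = AnnotationVolume(dims, resolution, vec)

        gene_index = {g: i for i, g in enumerate(gene_ids)}
        values = np.zeros((len(gene_ids), annot.n_voxels), dtype=np.float32)
        for e, v, g in con.execute(
            "SELECT genExpr, voxID, genID FROM voxID2GenExpr"
        ):
            values[gene_index[g], v] = e
        expr = ExpressionMatrix(tuple(gene_ids), values)

        injections = pd.read_sql_query(
            "SELECT injectionID, regionID FROM injection2regionID "
            "ORDER BY injectionID",
            con,
        )
        medians = pd.read_sql_query(
            "SELECT injectionID, median, targetID FROM injection2target "
            "ORDER BY injectionID, targetID",
            con,
        )
    finally:
        con.close()
    return annot, expr, injections, medians
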