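"""Readers/writers, annotation roll-up, and the relational store."""

import sqlite3

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxconn.errors import GridFormatError, SchemaError, StructureGraphError
from voxconn.grid_io import (
    AnnotationVolume,
    ExpressionMatrix,
    InjectionExperiment,
    StructureGraph,
    harmonize_annotation,
    load_database,
    read_expression_volume,
    read_nrrd,
    store_database,
    write_expression_volume,
    write_nrrd,
)
from voxconn.labels import compute_experiment_medians


class TestRawVolumes:
    def test_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        dims = (5, 4, 3)
        vec = rng.random(60).astype(np.float32)
        path = tmp_path / "v.raw"
        write_expression_volume(path, vec, dims)
        assert np.array_equal(read_expression_volume(path, dims), vec)

    def test_allen_scale_vector_length(self, tmp_path):
        dims = (67, 41, 58)
        vec = np.zeros(159_326, dtype=np.float32)
        path = tmp_path / "energy.raw"
        write_expression_volume(path, vec, dims)
        assert read_expression_volume(path, dims).size == 159_326

    def test_trailing_bytes_raise_format_error(self, tmp_path):
        path = tmp_path / "bad.raw"
        write_expression_volume(path, np.zeros(24, np.float32), (2, 3, 4))
        path.write_bytes(path.read_bytes() + b"0123456789")
        with pytest.raises(GridFormatError, match="24"):
            read_expression_volume(path, (2, 3, 4))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e6, width=32), min_size=1, max_size=30))
    def test_round_trip_arbitrary_payload(self, values):
        import tempfile
        from pathlib import Path

        vec = np.array(values, dtype=np.float32)
        with tempfile.TemporaryDirectory() as d:
            path = Path(d) / "v.raw"
            write_expression_volume(path, vec, (len(vec), 1, 1))
            assert np.array_equal(
                read_expression_volume(path, (len(vec), 1, 1)), vec
            )


class TestNrrd:
    def test_zero_volume(self, tmp_path):
        path = tmp_path / "z.nrrd"
        write_nrrd(path, np.zeros(512, np.float32), (8, 8, 8))
        dims, vec = read_nrrd(path)
        assert dims == (8, 8, 8)
        assert vec.size == 512 and not vec.any()

    def test_round_trip_random_volume(self, tmp_path):
        rng = np.random.default_rng(1)
        vec = rng.random(4 * 5 * 6).astype(np.float32)
        path = tmp_path / "r.nrrd"
        write_nrrd(path, vec, (4, 5, 6))
        dims, out = read_nrrd(path)
        assert dims == (4, 5, 6)
        assert np.array_equal(out, vec)

    def test_header_payload_mismatch_raises(self, tmp_path):
        path = tmp_path / "bad.nrrd"
        write_nrrd(path, np.zeros(24, np.float32), (2, 3, 4))
        blob = path.read_bytes()
        path.write_bytes(blob[:-4])  # drop one float
        with pytest.raises(GridFormatError):
            read_nrrd(path)

    def test_not_nrrd_raises(self, tmp_path):
        path = tmp_path / "junk.nrrd"
        path.write_bytes(b"hello world\n\n1234")
        with pytest.raises(GridFormatError):
            read_nrrd(path)

    def test_synthetic_experiment_round_trips(self, small_data, tmp_path):
        exp = small_data["experiments"][0]
        path = tmp_path / "e.nrrd"
        write_nrrd(path, exp.projection, exp.dims)
        dims, vec = read_nrrd(path)
        assert dims == exp.dims
        assert np.array_equal(vec, exp.projection)


@pytest.fixture()
def chain_graph():
    # root(1) -> A(2) -> leaf(3); plus sibling leaf(4) under root
    return StructureGraph({1: ("ROOT", None), 2: ("A", 1), 3: ("LF", 2), 4: ("LG", 1)})


class TestHarmonize:
    def test_leaf_rolls_up_to_parent_in_target_set(self, chain_graph):
        annot = AnnotationVolume((2, 1, 1), 200, np.array([3, 0]))
        out = harmonize_annotation(annot, chain_graph, {2})
        assert list(out.region_of_voxel) == [2, 0]

    def test_target_label_is_unchanged(self, chain_graph):
        annot = AnnotationVolume((2, 1, 1), 200, np.array([2, 4]))
        out = harmonize_annotation(annot, chain_graph, {2, 4})
        assert list(out.region_of_voxel) == [2, 4]

    def test_three_level_chain_rolls_to_root(self, chain_graph):
        annot = AnnotationVolume((3, 1, 1), 200, np.array([2, 3, 4]))
        out = harmonize_annotation(annot, chain_graph, {1})
        assert list(out.region_of_voxel) == [1, 1, 1]

    def test_no_target_ancestor_maps_to_background(self, chain_graph):
        annot = AnnotationVolume((2, 1, 1), 200, np.array([4, 3]))
        out = harmonize_annotation(annot, chain_graph, {2})
        assert list(out.region_of_voxel) == [0, 2]

    def test_idempotent(self, chain_graph):
        annot = AnnotationVolume((3, 1, 1), 200, np.array([3, 4, 0]))
        once = harmonize_annotation(annot, chain_graph, {2, 4})
        twice = harmonize_annotation(once, chain_graph, {2, 4})
        assert np.array_equal(once.region_of_voxel, twice.region_of_voxel)

    def test_cycle_detected(self):
        with pytest.raises(StructureGraphError, match="cycle"):
            StructureGraph({1: ("ROOT", None), 2: ("A", 3), 3: ("B", 2)})

    def test_roll_up_on_synthetic_graph(self, small_data, small_config):
        annot = small_data["annotation_coarse"]
        graph = small_data["graph"]
        out = harmonize_annotation(annot, graph, {2, 3})
        assert set(np.unique(out.region_of_voxel)) <= {0, 2, 3}
        for i, r in enumerate(small_config.region_ids):
            expected = 2 if i % 2 == 0 else 3
            assert (out.region_of_voxel[annot.voxels_of(r)] == expected).all()


class TestDatabase:
    @pytest.fixture()
    def stored(self, small_data, tmp_path):
        annot = small_data["annotation_coarse"]
        expr = small_data["expression"]
        experiments = small_data["experiments"]
        medians = compute_experiment_medians(
            experiments, small_data["annotation_fine"]
        )
        path = tmp_path / "db.sqlite"
        store_database(path, annot, expr, experiments, medians)
        return path, annot, expr, experiments, medians

    def test_full_round_trip(self, stored):
        path, annot, expr, experiments, medians = stored
        annot2, expr2, injections, medtable = load_database(path)
        assert np.array_equal(annot2.region_of_voxel, annot.region_of_voxel)
        assert annot2.dims == annot.dims
        assert np.array_equal(expr2.values, expr.values)
        assert expr2.gene_ids == expr.gene_ids
        assert len(injections) == len(experiments)
        got = {
            (int(r.injectionID), int(r.targetID)): float(r.median)
            for r in medtable.itertuples(index=False)
        }
        assert got == pytest.approx(medians)

    def test_zero_expression_rows_are_filtered(self, stored):
        path, _, expr, _, _ = stored
        con = sqlite3.connect(path)
        n_rows = con.execute("SELECT COUNT(*) FROM voxID2GenExpr").fetchone()[0]
        con.close()
        assert n_rows == int((expr.values != 0).sum())
        _, expr2, _, _ = load_database(path)
        zero_mask = expr.values == 0
        assert not expr2.values[zero_mask].any()

    def test_empty_experiment_list(self, small_data, tmp_path):
        path = tmp_path / "empty.sqlite"
        store_database(
            path,
            small_data["annotation_coarse"],
            small_data["expression"],
            [],
            {},
        )
        con = sqlite3.connect(path)
        assert con.execute("SELECT COUNT(*) FROM injection2regionID").fetchone()[0] == 0
        assert con.execute("SELECT COUNT(*) FROM injection2target").fetchone()[0] == 0
        con.close()

    def test_fig_table_names_exist(self, stored):
        path = stored[0]
        con = sqlite3.connect(path)
        names = {
            r[0]
            for r in con.execute(
                "SELECT name FROM sqlite_master WHERE type='table'"
            )
        }
        con.close()
        assert {
            "voxID2Annotation",
            "voxID2GenExpr",
            "injection2regionID",
            "injection2target",
        } <= names

    def test_schema_version_guard(self, stored, tmp_path):
        path = stored[0]
        con = sqlite3.connect(path)
        con.execute("UPDATE meta SET value='99' WHERE key='schema_version'")
        con.commit()
        con.close()
        with pytest.raises(SchemaError):
            load_database(path)


def test_expression_matrix_rejects_negative_values():
    with pytest.raises(GridFormatError):
        ExpressionMatrix((1,), np.array([[-1.0]]))


def test_projection_length_must_match_dims():
    with pytest.raises(GridFormatError):
        InjectionExperiment(1, 10, (2, 2, 2), np.zeros(7))


def test_expression_matrix_csv_round_trip(tmp_path, small_data):
    expr = small_data["expression"]
    path = tmp_path / "expr.csv"
    expr.to_csv(path)
    expr2 = ExpressionMatrix.from_csv(path)
    assert expr2.gene_ids == expr.gene_ids
    assert np.allclose(expr2.values, expr.values, atol=1e-6)
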