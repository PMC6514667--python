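"""Source-Target vector construction, caps, scaling, splitting."""

import numpy as np
import pytest

from conftest import make_dataset
from voxconn.datasets import (
    BuildConfig,
    apply_class_caps,
    build_dataset,
    build_pair_vectors,
    normalize,
    select_region_voxels,
    split_by_pairs,
    split_dataset,
)
from voxconn.errors import ConfigError, EmptyRegionError
from voxconn.grid_io import AnnotationVolume, ExpressionMatrix
from voxconn.labels import (
    LabelScheme,
    PairConnectivity,
    compute_pair_connectivity,
    label_pairs,
)


@pytest.fixture()
def tiny_world():
    """Two regions x 4 voxels on a (8,1,1) grid, 3 genes, expression 1..24."""
    annot = AnnotationVolume((8, 1, 1), 200, np.array([5, 5, 5, 5, 6, 6, 6, 6]))
    values = np.arange(1, 25, dtype=np.float32).reshape(3, 8)
    expr = ExpressionMatrix((1, 2, 3), values)
    return annot, expr


class TestVoxelSelection:
    def test_forced_selection_returns_all_voxels(self, tiny_world):
        annot, expr = tiny_world
        got = select_region_voxels(5, annot, expr, M=4, seed=0)
        assert sorted(got) == [0, 1, 2, 3]

    def test_small_region_samples_with_replacement_and_warns(self, tiny_world):
        annot, expr = tiny_world
        with pytest.warns(UserWarning, match="replacement"):
            got = select_region_voxels(5, annot, expr, M=6, seed=0)
        assert len(got) == 6
        assert len(set(got.tolist())) <= 4

    def test_same_seed_same_selection(self, tiny_world):
        annot, expr = tiny_world
        a = select_region_voxels(5, annot, expr, M=3, seed=42)
        b = select_region_voxels(5, annot, expr, M=3, seed=42)
        assert np.array_equal(a, b)

    def test_zero_expression_voxels_are_ineligible(self, tiny_world):
        annot, expr = tiny_world
        vals = expr.values.copy()
        vals[:, 0] = 0.0
        expr2 = ExpressionMatrix(expr.gene_ids, vals)
        got = select_region_voxels(5, annot, expr2, M=3, seed=1)
        assert 0 not in got

    def test_empty_region_raises(self, tiny_world):
        annot, expr = tiny_world
        with pytest.raises(EmptyRegionError):
            select_region_voxels(99, annot, expr, M=2, seed=0)


class TestPairVectors:
    def test_feature_is_source_profile_then_target_profile(self, tiny_world):
        annot, expr = tiny_world
        pair = PairConnectivity(5, 6, 0.2, 1)
        ds = build_pair_vectors(
            pair, np.array([0]), np.array([4]), expr, "index_paired", label=2
        )
        a = expr.values[:, 0]
        b = expr.values[:, 4]
        assert np.array_equal(ds.features[0], np.concatenate([a, b]))
        swapped = build_pair_vectors(
            PairConnectivity(6, 5, 0.2, 1), np.array([4]), np.array([0]), expr
        )
        assert np.array_equal(swapped.features[0], np.concatenate([b, a]))
        assert not np.array_equal(ds.features[0], swapped.features[0])

    def test_index_paired_yields_m_vectors(self, tiny_world):
        annot, expr = tiny_world
        pair = PairConnectivity(5, 6, 0.2, 1)
        ds = build_pair_vectors(
            pair, np.array([0, 1, 2]), np.array([4, 5, 6]), expr, "index_paired"
        )
        assert len(ds) == 3
        assert ds.features.shape == (3, 6)

    def test_cross_product_yields_m_squared(self, tiny_world):
        annot, expr = tiny_world
        pair = PairConnectivity(5, 6, 0.2, 1)
        ds = build_pair_vectors(
            pair, np.array([0, 1]), np.array([4, 5]), expr, "cross_product"
        )
        assert len(ds) == 4
        assert {(int(s), int(t)) for s, t in zip(ds.source_voxel, ds.target_voxel)} == {
            (0, 4),
            (0, 5),
            (1, 4),
            (1, 5),
        }

    def test_unknown_voxel_is_a_consistency_error(self, tiny_world):
        annot, expr = tiny_world
        pair = PairConnectivity(5, 6, 0.2, 1)
        with pytest.raises(ConfigError):
            build_pair_vectors(pair, np.array([0]), np.array([99]), expr)

    def test_full_scale_gene_count_gives_published_feature_length(self):
        g = 3318
        rng = np.random.default_rng(0)
        expr = ExpressionMatrix(
            tuple(range(1, g + 1)),
            rng.random((g, 4)).astype(np.float32),
        )
        pair = PairConnectivity(5, 6, 0.2, 1)
        ds = build_pair_vectors(pair, np.array([0, 1]), np.array([2, 3]), expr)
        assert ds.features.shape[1] == 6636


class TestZeroingHalves:
    def test_zeroing_target_region_zeroes_only_second_half(self, small_data):
        """The two vector halves map one-to-one onto source and target voxels."""
        expr = small_data["expression"]
        annot = small_data["annotation_coarse"]
        regions = list(small_data["truth"].region_ids)
        s, t = regions[0], regions[1]
        pair = PairConnectivity(s, t, 0.5, 1)
        src = select_region_voxels(s, annot, expr, 3, seed=0)
        tgt = select_region_voxels(t, annot, expr, 3, seed=1)
        before = build_pair_vectors(pair, src, tgt, expr)
        zeroed_vals = expr.values.copy()
        zeroed_vals[:, annot.voxels_of(t)] = 0.0
        # target region now all-zero: rebuild with the same voxel ids
        after = build_pair_vectors(
            pair, src, tgt, ExpressionMatrix(expr.gene_ids, zeroed_vals)
        )
        g = expr.n_genes
        assert np.array_equal(after.features[:, :g], before.features[:, :g])
        assert not after.features[:, g:].any()


class TestClassCaps:
    def test_caps_subsample_to_exact_counts(self):
        ds = make_dataset(12_000, labels=np.zeros(12_000, int))
        capped = apply_class_caps(ds, {0: 5000}, seed=0)
        assert len(capped) == 5000

    def test_cap_above_available_keeps_all(self):
        ds = make_dataset(4583, labels=np.full(4583, 2))
        capped = apply_class_caps(ds, {2: 5000}, seed=0)
        assert len(capped) == 4583

    def test_zero_cap_removes_class(self):
        labels = np.array([0] * 50 + [1] * 50)
        ds = make_dataset(100, labels=labels)
        capped = apply_class_caps(ds, {0: 0, 1: None}, seed=0)
        assert set(capped.labels) == {1}
        assert len(capped) == 50

    def test_missing_cap_is_an_error(self):
        ds = make_dataset(10, labels=np.ones(10, int))
        with pytest.raises(ConfigError):
            apply_class_caps(ds, {0: 5}, seed=0)


class TestNormalize:
    def test_midpoint_maps_to_half(self):
        ds = make_dataset(3)
        ds.features[:, 0] = [2.0, 3.0, 4.0]
        out, _, _ = normalize(ds)
        assert out.features[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_feature_maps_to_zero(self):
        ds = make_dataset(4)
        ds.features[:, 1] = 7.0
        out, _, _ = normalize(ds)
        assert not out.features[:, 1].any()

    def test_out_of_range_test_values_are_clipped(self):
        train = make_dataset(2)
        train.features[:, 0] = [2.0, 4.0]
        test = make_dataset(1, seed=1)
        test.features[:, 0] = [5.0]
        _, (test_n,), _ = normalize(train, [test])
        assert test_n.features[0, 0] == pytest.approx(1.0)

    def test_scaler_ignores_non_training_partitions(self):
        train = make_dataset(20, seed=0)
        test_a = make_dataset(5, seed=1)
        test_b = make_dataset(5, seed=1)
        test_b.features[0, 0] = 1e6  # perturb a test vector only
        _, _, scaler_a = normalize(train, [test_a])
        _, _, scaler_b = normalize(train, [test_b])
        assert np.array_equal(scaler_a.data_min_, scaler_b.data_min_)
        assert np.array_equal(scaler_a.data_max_, scaler_b.data_max_)

    def test_train_features_land_in_unit_interval(self):
        ds = make_dataset(50, seed=3)
        out, _, _ = normalize(ds)
        assert out.features.min() >= 0.0 and out.features.max() <= 1.0


class TestSplit:
    def test_published_partition_sizes(self):
        labels = np.array([0] * 5000 + [1] * 5000 + [2] * 4583)
        ds = make_dataset(14_583, labels=labels)
        split = split_dataset(ds, (0.72, 0.08, 0.20), seed=0)
        assert len(split.train) == 10_499
        assert len(split.validation) == 1_167
        assert len(split.test) == 2_917

    def test_exact_division(self):
        ds = make_dataset(100, labels=np.array([0, 1] * 50))
        split = split_dataset(ds, (0.72, 0.08, 0.20), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (72, 8, 20)

    @pytest.mark.parametrize("n", [37, 100, 1001, 14_583])
    def test_split_conservation_and_disjointness(self, n):
        ds = make_dataset(n, seed=n)
        split = split_dataset(ds, (0.6, 0.15, 0.25), seed=1)
        total = len(split.train) + len(split.validation) + len(split.test)
        assert total == n
        ids = np.concatenate(
            [p.source_voxel for p in (split.train, split.validation, split.test)]
        )
        assert len(np.unique(ids)) == n  # source_voxel is unique per row here

    def test_stratification_within_two_items(self):
        labels = np.array([0] * 700 + [1] * 300)
        ds = make_dataset(1000, labels=labels)
        split = split_dataset(ds, (0.72, 0.08, 0.20), seed=2)
        for part, frac in ((split.test, 0.2), (split.validation, 0.08)):
            for c, total in ((0, 700), (1, 300)):
                got = int((part.labels == c).sum())
                assert abs(got - frac * total) <= 2

    def test_same_seed_identical_membership(self):
        ds = make_dataset(200, seed=9)
        a = split_dataset(ds, seed=5)
        b = split_dataset(ds, seed=5)
        assert np.array_equal(a.test.source_voxel, b.test.source_voxel)
        assert np.array_equal(a.train.features, b.train.features)

    def test_pair_disjoint_split_never_shares_a_pair(self):
        rng = np.random.default_rng(0)
        n = 400
        ds = make_dataset(n, seed=4)
        split = split_by_pairs(ds, (0.6, 0.2, 0.2), seed=0)
        parts = [split.train, split.validation, split.test]
        keysets = [set(p.pair_keys().tolist()) for p in parts]
        assert not (keysets[0] & keysets[2])
        assert not (keysets[0] & keysets[1])
        assert not (keysets[1] & keysets[2])
        assert sum(len(p) for p in parts) == n


class TestEndToEndBuild:
    def test_build_is_deterministic_and_excludes_gap_pairs(self, small_data):
        scheme = LabelScheme(mode="multiclass")
        pairs = compute_pair_connectivity(
            small_data["experiments"], small_data["annotation_fine"]
        )
        table = label_pairs(pairs, scheme)
        cfg = BuildConfig(M=5, per_class_cap={0: None, 1: None, 2: None}, seed=11)
        a = build_dataset(
            table, small_data["annotation_coarse"], small_data["expression"], cfg
        )
        b = build_dataset(
            table.sample(frac=1, random_state=0),  # shuffled row order
            small_data["annotation_coarse"],
            small_data["expression"],
            cfg,
        )
        order_a = np.lexsort((a.target_region, a.source_region))
        order_b = np.lexsort((b.target_region, b.source_region))
        assert np.array_equal(a.features[order_a], b.features[order_b])
        n_kept_pairs = int((~table["excluded"]).sum())
        assert len(a) == 5 * n_kept_pairs
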