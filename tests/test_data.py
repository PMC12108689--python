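"""Tests for tabular I/O, stratified splitting, and the synthetic generator."""

import numpy as np
import pytest

from mantafs.data import (
    LabeledDataset,
    SyntheticSpec,
    min_max_scale,
    read_tabular,
    stratified_holdout,
    stratified_kfold,
    stratified_split_indices,
    synthesize_dataset,
    write_tabular,
)
from mantafs.fitness import subset_error


CSV_FIXTURE = "f1,f2,label\n1.0,2.0,A\n3.0,4.0,B\n5.0,6.0,A\n7.0,8.0,B\n"


class TestReadTabular:
    def test_first_appearance_label_encoding(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(CSV_FIXTURE)
        ds = read_tabular(p, label_column="label")
        np.testing.assert_array_equal(ds.y, [0, 1, 0, 1])
        assert ds.label_names == ["A", "B"]
        assert ds.feature_names == ["f1", "f2"]
        np.testing.assert_allclose(ds.X[0], [1.0, 2.0])

    def test_tsv_equals_csv(self, tmp_path):
        c = tmp_path / "d.csv"
        t = tmp_path / "d.tsv"
        c.write_text(CSV_FIXTURE)
        t.write_text(CSV_FIXTURE.replace(",", "\t"))
        a, b = read_tabular(c, "label"), read_tabular(t, "label")
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)

    def test_label_column_by_index(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(CSV_FIXTURE)
        ds = read_tabular(p, label_column=-1)
        np.testing.assert_array_equal(ds.y, [0, 1, 0, 1])

    def test_headerless_file(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("1.0,2.0,0\n3.0,4.0,1\n5.0,6.0,0\n7.0,8.0,1\n")
        ds = read_tabular(p, label_column=-1)
        assert ds.feature_names is None
        assert ds.n_features == 2

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("f1,f2,label\n1.0,NA,A\n3.0,4.0,B\n")
        with pytest.raises(ValueError, match="'NA' at row 0, column 'f2'"):
            read_tabular(p, "label")

    def test_single_class_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("f1,label\n1.0,A\n2.0,A\n")
        with pytest.raises(ValueError):
            read_tabular(p, "label")

    def test_round_trip(self, tmp_path):
        ds = synthesize_dataset(
            SyntheticSpec(n_samples=12, n_classes=2, n_informative=2,
                          n_redundant=2, n_noise=4, seed=0)
        )
        p = tmp_path / "out.csv"
        write_tabular(ds, p, truth_sidecar=tmp_path / "truth.txt")
        back = read_tabular(p, label_column="label")
        np.testing.assert_allclose(back.X, ds.X)
        np.testing.assert_array_equal(back.y, ds.y)
        truth_idx = [int(l) for l in (tmp_path / "truth.txt").read_text().split()]
        np.testing.assert_array_equal(truth_idx, np.flatnonzero(ds.truth_mask))


class TestStratifiedSplits:
    def _balanced(self, n, n_classes=2):
        y = np.arange(n) % n_classes
        X = np.random.default_rng(0).normal(size=(n, 3))
        return LabeledDataset(X, y)

    def test_holdout_per_class_rounding(self, rng):
        train, test = stratified_holdout(self._balanced(10), 0.2, rng)
        assert test.n_samples == 2
        np.testing.assert_array_equal(np.bincount(test.y), [1, 1])
        assert train.n_samples == 8

    def test_holdout_symmetric_split(self, rng):
        train, test = stratified_holdout(self._balanced(4), 0.5, rng)
        assert train.n_samples == test.n_samples == 2
        np.testing.assert_array_equal(np.bincount(test.y), [1, 1])

    def test_holdout_keeps_one_per_class_each_side(self, rng):
        # extreme fraction still leaves one sample of each class on both sides
        tr, te = stratified_split_indices(np.array([0, 0, 1, 1]), 0.9, rng)
        assert len(tr) == len(te) == 2

    def test_holdout_deterministic_given_seed(self):
        ds = self._balanced(20)
        a = stratified_split_indices(ds.y, 0.2, np.random.default_rng(5))
        b = stratified_split_indices(ds.y, 0.2, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_singleton_class_raises(self, rng):
        y = np.array([0, 0, 0, 1])
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="single sample"):
            stratified_holdout(LabeledDataset(X, y), 0.25, rng)

    @pytest.mark.parametrize("frac", [0.0, 1.0])
    def test_fraction_bounds(self, frac, rng):
        with pytest.raises(ValueError):
            stratified_split_indices(np.array([0, 0, 1, 1]), frac, rng)

    def test_kfold_partition_and_balance(self, rng):
        ds = self._balanced(20)
        folds = stratified_kfold(ds, 10, rng)
        assert len(folds) == 10
        sizes = [te.n_samples for _, te in folds]
        assert sizes == [2] * 10
        for _, te in folds:
            np.testing.assert_array_equal(np.bincount(te.y), [1, 1])

    def test_kfold_reduces_with_warning(self, rng):
        ds = self._balanced(8)  # 4 per class < 10 folds
        with pytest.warns(UserWarning, match="reducing n_folds"):
            folds = stratified_kfold(ds, 10, rng)
        assert len(folds) == 4

    def test_kfold_rejects_single_fold(self, rng):
        with pytest.raises(ValueError):
            stratified_kfold(self._balanced(10), 1, rng)


class TestSynthesize:
    def test_bookkeeping(self):
        spec = SyntheticSpec(n_samples=60, n_classes=3, n_informative=10,
                             n_redundant=20, n_noise=470, seed=0)
        ds = synthesize_dataset(spec)
        assert ds.X.shape == (60, 500)
        assert ds.truth_mask.sum() == 10
        assert np.all(ds.truth_mask[:10] == 1) and np.all(ds.truth_mask[10:] == 0)
        np.testing.assert_array_equal(np.bincount(ds.y), [20, 20, 20])

    def test_deterministic_given_seed(self):
        spec = SyntheticSpec(n_samples=20, n_noise=30, seed=11)
        a, b = synthesize_dataset(spec), synthesize_dataset(spec)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)

    def test_redundant_features_correlate_with_parent(self):
        spec = SyntheticSpec(n_samples=200, n_classes=2, n_informative=4,
                             n_redundant=8, n_noise=10, redundancy_noise=0.5, seed=2)
        ds = synthesize_dataset(spec)
        for j in range(8):
            name = ds.feature_names[4 + j]
            parent = int(name.rsplit("_", 1)[1])
            r = np.corrcoef(ds.X[:, 4 + j], ds.X[:, parent])[0, 1]
            assert r >= 0.5

    def test_zero_effect_size_gives_chance_error(self):
        errs = []
        for seed in range(5):
            spec = SyntheticSpec(n_samples=120, n_classes=2, n_informative=5,
                                 n_redundant=5, n_noise=40, effect_size=0.0, seed=seed)
            ds = synthesize_dataset(spec)
            tr, te = stratified_split_indices(ds.y, 0.25, np.random.default_rng(seed))
            errs.append(subset_error(ds.X[tr], ds.y[tr], ds.X[te], ds.y[te],
                                     np.ones(50), k=5))
        assert abs(np.mean(errs) - 0.5) < 0.07

    def test_strong_effect_truth_mask_classifies_well(self):
        errs = []
        for seed in range(10):
            spec = SyntheticSpec(n_samples=60, n_classes=3, n_informative=10,
                                 n_redundant=0, n_noise=0, effect_size=3.0, seed=seed)
            ds = synthesize_dataset(spec)
            rng = np.random.default_rng(seed)
            tr, te = stratified_split_indices(ds.y, 0.2, rng)
            errs.append(subset_error(ds.X[tr], ds.y[tr], ds.X[te], ds.y[te],
                                     ds.truth_mask, k=5))
        assert np.mean(errs) <= 0.05

    def test_too_few_informative_for_distinct_signatures(self):
        with pytest.raises(ValueError):
            synthesize_dataset(SyntheticSpec(n_classes=4, n_informative=1, seed=0))


class TestMinMaxScale:
    def test_train_endpoints_map_to_unit_interval(self):
        tr, _ = min_max_scale(np.array([[2.0], [4.0]]))
        np.testing.assert_allclose(tr.ravel(), [0.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        tr, ap = min_max_scale(np.array([[5.0], [5.0]]), np.array([[7.0]]))
        np.testing.assert_allclose(tr, 0.0)
        np.testing.assert_allclose(ap, 2.0)  # (7-5)/1, unclipped

    def test_apply_values_not_clipped(self):
        _, ap = min_max_scale(np.array([[2.0], [4.0]]), np.array([[6.0]]))
        assert ap[0, 0] == pytest.approx(2.0)
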