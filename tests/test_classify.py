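"""Splitting, tuning, training, metric formulas and the paired experiments."""

import numpy as np
import pytest

from mitespec.classify import (
    ClassifierSpec,
    SplitSpec,
    ablation_drop_band,
    default_spec,
    evaluate,
    metrics_from_counts,
    red_region_experiment,
    reports_to_frame,
    run_pairings,
    split_dataset,
    train_classifier,
    tune_hyperparameters,
)
from mitespec.cube_io import make_grid
from mitespec.selection import SelectionResult, anova_f_scores, select_k_best
from mitespec.signatures import LabeledDataset


def _dataset(X, labels):
    grid = make_grid(502, 502 + 4 * (X.shape[1] - 1), 4)
    return LabeledDataset(np.asarray(X, float), np.asarray(labels, object), grid)


@pytest.fixture
def balanced(rng):
    X = rng.standard_normal((440, 12))
    X[220:, 4] += 3.0
    return _dataset(X, ["healthy"] * 220 + ["infested"] * 220)


class TestSplit:
    def test_stratified_70_30_counts(self, balanced):
        train, test = split_dataset(balanced, SplitSpec(seed=0))
        assert train.class_counts() == {"healthy": 154, "infested": 154}
        assert test.class_counts() == {"healthy": 66, "infested": 66}

    def test_same_seed_identical_partition(self, balanced):
        a = split_dataset(balanced, SplitSpec(seed=9))
        b = split_dataset(balanced, SplitSpec(seed=9))
        assert a[0].sample_ids == b[0].sample_ids

    def test_partition_disjoint_and_complete(self, balanced):
        for seed in range(5):
            train, test = split_dataset(balanced, SplitSpec(seed=seed))
            ids = set(train.sample_ids) | set(test.sample_ids)
            assert not set(train.sample_ids) & set(test.sample_ids)
            assert ids == set(balanced.sample_ids)

    def test_tiny_class_rejected(self, rng):
        ds = _dataset(rng.standard_normal((5, 3)),
                      ["healthy"] * 4 + ["infested"])
        with pytest.raises(ValueError):
            split_dataset(ds, SplitSpec(train_fraction=0.7))


class TestTuning:
    def test_singleton_grid_returned(self, balanced):
        spec = tune_hyperparameters(balanced, "KNN",
                                    [dict(n_neighbors=5, weights="uniform")])
        assert spec.params["n_neighbors"] == 5

    def test_tie_goes_to_first_grid_point(self, balanced):
        grid = [dict(n_neighbors=5, weights="uniform"),
                dict(n_neighbors=5, weights="uniform")]
        spec = tune_hyperparameters(balanced, "KNN", grid)
        assert spec is not None and spec.params == grid[0]

    def test_argmax_over_small_grid(self, rng):
        # separable data: any sensible configuration reaches the maximum,
        # and the chosen one must beat or match every other grid point
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from mitespec.classify import _make_estimator

        X = np.vstack([rng.normal(0, 0.2, (40, 4)), rng.normal(3, 0.2, (40, 4))])
        ds = _dataset(X, ["healthy"] * 40 + ["infested"] * 40)
        grid = [dict(n_neighbors=k, weights="uniform") for k in (1, 5, 9)]
        spec = tune_hyperparameters(ds, "KNN", grid, folds=5, seed=0)
        cv = StratifiedKFold(5, shuffle=True, random_state=0)
        best = cross_val_score(_make_estimator(spec, 0), ds.X, ds.y.astype(str), cv=cv).mean()
        for params in grid:
            other = cross_val_score(_make_estimator(ClassifierSpec("KNN", params), 0),
                                    ds.X, ds.y.astype(str), cv=cv).mean()
            assert best >= other - 1e-12

    def test_fold_exceeding_minority_rejected(self, rng):
        ds = _dataset(rng.standard_normal((12, 3)),
                      ["healthy"] * 9 + ["infested"] * 3)
        with pytest.raises(ValueError):
            tune_hyperparameters(ds, "RF", [dict()], folds=5)


class TestTraining:
    @pytest.mark.parametrize("family", ["RF", "SVM", "KNN"])
    def test_separable_data_reaches_perfect_training_accuracy(self, rng, family):
        X = np.vstack([rng.normal(0, 0.1, (30, 3)), rng.normal(5, 0.1, (30, 3))])
        ds = _dataset(X, ["healthy"] * 30 + ["infested"] * 30)
        model = train_classifier(ds, default_spec(family), seed=0)
        assert np.mean(model.predict(ds.X) == ds.y.astype(str)) == 1.0

    def test_rf_predictions_deterministic_per_seed(self, balanced):
        m1 = train_classifier(balanced, default_spec("RF"), seed=4)
        m2 = train_classifier(balanced, default_spec("RF"), seed=4)
        np.testing.assert_array_equal(m1.predict(balanced.X), m2.predict(balanced.X))

    def test_single_class_training_rejected(self, rng):
        ds = _dataset(rng.standard_normal((10, 3)), ["healthy"] * 10)
        with pytest.raises(ValueError):
            train_classifier(ds, default_spec("RF"))


class _FixedModel:
    def __init__(self, predictions):
        self._p = np.asarray(predictions, dtype=object)

    def predict(self, X):
        return self._p


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        ds = _dataset(rng.standard_normal((10, 3)),
                      ["healthy"] * 5 + ["infested"] * 5)
        rep = evaluate(_FixedModel(ds.y), ds)
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (100, 100, 100, 100)

    def test_closed_form_counts(self):
        m = metrics_from_counts(tp=9, fp=1, fn=2, tn=8)
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["precision"] == pytest.approx(90.0)
        assert m["recall"] == pytest.approx(81.82, abs=0.005)
        assert m["f1"] == pytest.approx(85.71, abs=0.005)

    def test_always_positive_predictor_on_balanced_set(self, rng):
        ds = _dataset(rng.standard_normal((20, 3)),
                      ["healthy"] * 10 + ["infested"] * 10)
        rep = evaluate(_FixedModel(["infested"] * 20), ds)
        assert rep.accuracy == pytest.approx(50.0)
        assert rep.recall == pytest.approx(100.0)
        assert rep.precision == pytest.approx(50.0)
        assert rep.f1 == pytest.approx(66.67, abs=0.005)

    def test_undefined_ratios_flagged_zero(self, rng):
        ds = _dataset(rng.standard_normal((10, 3)),
                      ["healthy"] * 5 + ["infested"] * 5)
        rep = evaluate(_FixedModel(["healthy"] * 10), ds)
        assert rep.precision == 0.0 and "precision" in rep.undefined

    def test_metric_identity_recomputable_from_counts(self, small_dataset):
        records = run_pairings(small_dataset, subset_plan=(5,), seeds=(0,))
        for r in records:
            rep = r["report"]
            m = metrics_from_counts(rep.tp, rep.fp, rep.fn, rep.tn)
            assert rep.accuracy == m["accuracy"]
            assert rep.f1 == m["f1"]
            assert rep.n_test == 24  # 30% of 80, stratified


class TestRunPairings:
    def test_all_subset_uses_every_band(self, small_dataset):
        records = run_pairings(small_dataset, subset_plan=("all",), seeds=(0,))
        assert all(len(r["report"].band_subset) == 113 for r in records)
        assert len(records) == 3

    def test_metrics_bounded(self, small_dataset):
        frame = reports_to_frame(run_pairings(small_dataset, (10, 5), (0, 1)))
        for col in ("accuracy", "precision", "recall", "f1"):
            assert frame[col].between(0, 100).all()

    def test_requires_mnss(self, rng):
        ds = _dataset(rng.standard_normal((20, 5)),
                      ["healthy"] * 10 + ["infested"] * 10)
        ds.kind = "MRSS"
        with pytest.raises(ValueError, match="MNSS"):
            run_pairings(ds)

    def test_label_permutation_is_chance_level(self, small_dataset, rng):
        permuted = LabeledDataset(small_dataset.X, rng.permutation(small_dataset.y),
                                  small_dataset.grid, "MNSS")
        frame = reports_to_frame(run_pairings(permuted, (5,), seeds=(0, 1, 2)))
        # 24-sample test sets: binomial 99% band around 50%
        assert 20 < frame.accuracy.median() < 80


class TestAblation:
    def _selection(self, ds, k=5):
        return select_k_best(anova_f_scores(ds), k, grid=ds.grid)

    def test_round_trip_identical_report(self, small_dataset):
        sel = self._selection(small_dataset)
        pairs = ablation_drop_band(small_dataset, sel, sel.band_indices[0], seeds=(0,))
        before, after = pairs[0]
        re_pairs = ablation_drop_band(small_dataset, sel, sel.band_indices[0], seeds=(0,))
        assert re_pairs[0][0] == before and re_pairs[0][1] == after
        assert set(after.band_subset) == set(before.band_subset) - {sel.band_indices[0]}

    def test_dropping_only_informative_band_collapses_accuracy(self, rng):
        X = rng.standard_normal((200, 6))
        X[100:, 2] += 4.0
        ds = _dataset(X, ["healthy"] * 100 + ["infested"] * 100)
        sel = select_k_best(anova_f_scores(ds), 2, grid=ds.grid)
        assert 2 in sel.band_indices
        pairs = ablation_drop_band(ds, sel, 2, seeds=(0, 1, 2))
        before = np.median([b.accuracy for b, _ in pairs])
        after = np.median([a.accuracy for _, a in pairs])
        assert before > 95
        assert abs(after - 50) < 20

    def test_unselected_band_rejected(self, small_dataset):
        sel = self._selection(small_dataset)
        missing = next(i for i in range(113) if i not in sel.band_indices)
        with pytest.raises(ValueError):
            ablation_drop_band(small_dataset, sel, missing)


class TestRedRegion:
    def test_red_band_count_on_camera_grid(self, small_dataset):
        out = red_region_experiment(small_dataset, seeds=(0,))
        assert out["n_red_bands"] == 22
        assert set(out["band_indices"]) < set(range(113))

    def test_red_only_underperforms_best_five(self, small_dataset):
        seeds = (0, 1, 2)
        red = red_region_experiment(small_dataset, seeds=seeds)
        red_acc = np.median([r.accuracy for r in red["reports"]])
        frame = reports_to_frame(run_pairings(small_dataset, (5,), seeds=seeds))
        best5 = frame[frame.family == "RF"].accuracy.median()
        assert red_acc < best5
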