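import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from swirclass.dl_models import ModelSpec, build_model
from swirclass.preprocess import SplitSpec
from swirclass.spectra_io import SampleMeta, SpectraDataset, Spectrum, WavelengthGrid
from swirclass.train_eval import (
    ConfusionCounts,
    TrainConfig,
    aggregate_metrics,
    compute_metrics,
    confusion_counts,
    evaluate_predictions,
    per_class_metrics,
    predict,
    run_benchmark,
    train_classifier,
)


class TestConfusionCounts:
    def test_hand_counted_example(self):
        y_true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 0, 0, 0, 0, 1]
        c = confusion_counts(np.array(y_true), np.array(y_pred))
        assert (c.TP, c.FN, c.TN, c.FP) == (3, 2, 4, 1)
        assert c.total == 10

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0])
        c = confusion_counts(y, y)
        assert c.FP == 0 and c.FN == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts(np.array([0, 1]), np.array([0]))

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.array([0, 2]), np.array([0, 1]))


class TestMetrics:
    def test_arithmetic_example(self):
        rep = compute_metrics(ConfusionCounts(TP=3, FP=1, TN=4, FN=2))
        assert rep.accuracy == pytest.approx(0.70)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.60)
        assert rep.f1 == pytest.approx(2 / 3, abs=1e-5)

    def test_perfect_confusion_all_ones(self):
        rep = compute_metrics(ConfusionCounts(TP=5, FP=0, TN=5, FN=0))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_undefined_precision_reported_absent(self):
        rep = compute_metrics(ConfusionCounts(TP=0, FP=0, TN=3, FN=2))
        assert rep.precision is None
        assert "precision" in rep.undefined
        assert rep.accuracy == pytest.approx(0.6)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(200):
            c = ConfusionCounts(*(int(v) for v in rng.integers(1, 50, 4)))
            rep = compute_metrics(c)
            assert min(rep.precision, rep.recall) - 1e-12 <= rep.f1
            assert rep.f1 <= max(rep.precision, rep.recall) + 1e-12

    def test_matches_sklearn_on_random_tables(self, rng):
        """Cross-check against an independent implementation, 1000 tables."""
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            if y_true.sum() in (0, n) or y_pred.sum() == 0:
                continue
            rep = compute_metrics(confusion_counts(y_true, y_pred))
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, average="binary", zero_division=np.nan
            )
            assert rep.accuracy == pytest.approx((y_true == y_pred).mean())
            assert rep.precision == pytest.approx(p)
            assert rep.recall == pytest.approx(r)
            if rep.f1 is not None:
                assert rep.f1 == pytest.approx(f)

    def test_macro_average(self):
        c = confusion_counts(
            np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0]),
            np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 1]),
        )
        per = per_class_metrics(c)
        macro = aggregate_metrics(per)
        # class-1: P=3/4, R=3/5; class-0: P=4/6, R=4/5
        assert macro.precision == pytest.approx((0.75 + 4 / 6) / 2)
        assert macro.recall == pytest.approx((0.6 + 0.8) / 2)
        assert macro.accuracy == pytest.approx(0.7)

    def test_macro_symmetric_confusion(self):
        per = per_class_metrics(ConfusionCounts(TP=4, FP=1, TN=4, FN=1))
        macro = aggregate_metrics(per)
        assert macro.precision == per[1].precision == per[0].precision

    def test_label_swap_symmetry(self, rng):
        y_true = rng.integers(0, 2, 30)
        y_pred = rng.integers(0, 2, 30)
        a = evaluate_predictions(y_true, y_pred)
        b = evaluate_predictions(1 - y_true, 1 - y_pred)
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.precision == pytest.approx(b.precision)
        assert a.recall == pytest.approx(b.recall)

    def test_missing_class_rejected(self):
        rep = compute_metrics(ConfusionCounts(3, 1, 4, 2))
        with pytest.raises(ValueError):
            aggregate_metrics({1: rep})


def separable_features(rng, n=100, d=64, gap=6.0):
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, d)) + gap * y[:, None]
    return X, y


class TestTraining:
    def test_default_regime(self):
        cfg = TrainConfig()
        assert cfg.batch_size == 32
        assert cfg.learning_rate == pytest.approx(0.001)
        assert cfg.optimizer == "adam"

    def test_zero_epochs_leaves_model_at_initialization(self, rng):
        X, y = separable_features(rng)
        model = build_model(ModelSpec(kind="cnn"), X.shape[1], seed=0)
        before = [p.copy() for p in model.parameters()]
        log = train_classifier(model, X, y, TrainConfig(epochs=0, seed=0))
        assert log.empty
        for p, b in zip(model.parameters(), before):
            assert np.array_equal(p, b)

    def test_training_reaches_perfect_accuracy_on_separable_data(self, rng):
        X, y = separable_features(rng, n=200)
        model = build_model(ModelSpec(kind="cnn"), X.shape[1], seed=0)
        log = train_classifier(model, X, y, TrainConfig(epochs=15, seed=0))
        assert log.accuracy.iloc[-1] == 1.0
        assert (predict(model, X) == y).all()

    def test_reproducible_given_seed(self, rng):
        X, y = separable_features(rng, n=60)
        preds = []
        for _ in range(2):
            model = build_model(ModelSpec(kind="cnn_lstm"), X.shape[1], seed=3)
            train_classifier(model, X, y, TrainConfig(epochs=2, seed=3))
            preds.append(predict(model, X))
        assert np.array_equal(preds[0], preds[1])

    def test_bad_labels_rejected(self, rng):
        X, _ = separable_features(rng, n=10)
        y = np.array([0, 1, 2] + [0] * 7)
        model = build_model(ModelSpec(kind="cnn"), X.shape[1], seed=0)
        with pytest.raises(ValueError, match="labels"):
            train_classifier(model, X, y)

    def test_predict_row_count_and_determinism(self, rng):
        X, y = separable_features(rng, n=30)
        model = build_model(ModelSpec(kind="cnn"), X.shape[1], seed=0)
        p1, p2 = predict(model, X), predict(model, X)
        assert p1.shape == (30,)
        assert np.array_equal(p1, p2)


def tiny_two_state_dataset(seed=0, n_samples=2, n_reps=10, n_points=64, offset=0.25):
    """Small separable dataset with both physical states for benchmark tests."""
    rng = np.random.default_rng(seed)
    grid = WavelengthGrid(400.0, 400.0 + n_points - 1, 1.0)
    spectra = []
    for cls in (0, 1):
        for si in range(n_samples):
            for state in ("frozen", "thawed"):
                for _ in range(n_reps):
                    r = 0.4 + 0.05 * rng.normal(size=n_points)
                    if cls == 1:
                        r = r + offset
                    spectra.append(
                        Spectrum(SampleMeta(f"C{cls}S{si}", cls, state), np.clip(r, 0, 1))
                    )
    return SpectraDataset(grid, spectra)


class TestBenchmark:
    def test_grid_completeness(self):
        ds = tiny_two_state_dataset()
        grid = run_benchmark(
            ds,
            models=("knn", "nb", "svm"),
            processings=("raw", "standardization", "pca"),
            cfg=TrainConfig(epochs=2, seed=0),
            pca_k=5,
        )
        assert len(grid) == 2 * 3 * 3
        assert set(grid.state) == {"frozen", "thawed"}
        assert set(grid.model) == {"knn", "nb", "svm"}

    def test_deep_model_in_benchmark(self):
        ds = tiny_two_state_dataset(offset=0.3)
        grid = run_benchmark(
            ds, models=("cnn",), processings=("standardization",),
            cfg=TrainConfig(epochs=2, seed=0),
        )
        assert len(grid) == 2
        assert (grid.accuracy >= 0.5).all()

    def test_same_seed_identical_grid(self):
        ds = tiny_two_state_dataset()
        kw = dict(models=("knn", "dt", "svm"), processings=("standardization",),
                  cfg=TrainConfig(epochs=1, seed=4), pca_k=5)
        g1 = run_benchmark(ds, **kw)
        g2 = run_benchmark(ds, **kw)
        assert g1.equals(g2)

    def test_separable_data_classified_well(self):
        ds = tiny_two_state_dataset(offset=0.3)
        grid = run_benchmark(
            ds, models=("nb",), processings=("raw",), cfg=TrainConfig(epochs=0, seed=0)
        )
        assert (grid.accuracy == 1.0).all()

    def test_unknown_model_kind_rejected(self):
        ds = tiny_two_state_dataset()
        with pytest.raises(ValueError, match="unknown model kind"):
            run_benchmark(ds, models=("quantum",), processings=("raw",))

    def test_single_state_dataset_rejected(self, small_grid, rng):
        from conftest import make_dataset

        ds = make_dataset(small_grid, 10, rng, states=("frozen",))
        with pytest.raises(ValueError, match="both physical states"):
            run_benchmark(ds, models=("knn",), processings=("raw",))
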