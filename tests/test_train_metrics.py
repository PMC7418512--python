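"""Losses, metrics, the optimization protocol and cross-validation."""

import itertools

import numpy as np
import pytest

import tcrspec as ts
from tcrspec.dataset import ArrayDataset, build_screen_datasets
from tcrspec.metrics import (
    MetricUndefinedError,
    auc_roc,
    classification_rates,
    multiclass_auc,
)
from tcrspec.pipeline import Part


def concordance_auc(labels, scores):
    """Brute-force pairwise-concordance oracle (ties count 0.5)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestLosses:
    def test_cross_entropy_perfect_prediction_is_zero(self):
        p = np.zeros(9)
        p[4] = 1.0
        assert ts.categorical_cross_entropy(p, 4) == 0.0

    def test_cross_entropy_uniform_nine_classes(self):
        p = np.full(9, 1 / 9)
        np.testing.assert_allclose(ts.categorical_cross_entropy(p, 0), np.log(9))

    def test_invalid_probability_vector_raises(self):
        with pytest.raises(ValueError):
            ts.categorical_cross_entropy(np.array([0.9, 0.5]), 0)

    def test_msle_identity_is_zero(self, rng):
        y = rng.integers(0, 100, size=20).astype(float)
        assert ts.msle(y, y) == 0.0

    def test_msle_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            ts.msle([-1.0], [1.0])


class TestAUC:
    def test_perfect_and_reversed_scores(self):
        y = [0, 0, 1, 1]
        assert auc_roc(y, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert auc_roc(y, [0.9, 0.8, 0.2, 0.1]) == 0.0

    def test_single_class_raises_not_zero(self):
        with pytest.raises(MetricUndefinedError):
            auc_roc([1, 1, 1], [0.5, 0.2, 0.9])

    def test_matches_concordance_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # coarse grid to exercise ties
            assert abs(auc_roc(y, s) - concordance_auc(y, s)) < 1e-9

    def test_multiclass_micro_equals_flattened_binary(self, rng):
        y = rng.integers(0, 3, size=50)
        probs = rng.random((50, 3))
        probs /= probs.sum(axis=1, keepdims=True)
        onehot = np.eye(3)[y]
        res = multiclass_auc(y, probs)
        assert res["micro"] == pytest.approx(
            concordance_auc(onehot.ravel(), probs.ravel()), abs=1e-9
        )
        assert set(res["per_class"]) == {0, 1, 2}


class TestR2Log:
    def test_mean_predictor_scores_zero(self, rng):
        y = rng.integers(0, 50, size=40).astype(float)
        mean_pred = np.full_like(y, np.expm1(np.log1p(y).mean()))
        assert ts.r2_log(y, mean_pred) == pytest.approx(0.0, abs=1e-12)

    def test_train_mean_predictor_nonpositive_on_test(self, rng):
        train = rng.integers(0, 50, size=100).astype(float)
        test = rng.integers(0, 50, size=50).astype(float)
        pred = np.full_like(test, np.expm1(np.log1p(train).mean()))
        assert ts.r2_log(test, pred) <= 0.0

    def test_perfect_prediction_is_one(self, rng):
        y = rng.integers(0, 50, size=30).astype(float)
        assert ts.r2_log(y, y) == 1.0


class TestRates:
    def test_perfect_binary_classifier(self):
        rates = classification_rates([0, 0, 1, 1], [0, 0, 1, 1])
        assert rates == {"f1": 1.0, "fnr": 0.0, "fpr": 0.0}

    def test_multiclass_micro_rates(self):
        rates = classification_rates([0, 1, 2, 2], [0, 1, 2, 1])
        assert rates["f1"] == pytest.approx(0.75)
        assert 0 < rates["fnr"] < 1


class TestCompareModels:
    def test_identical_samples_welch(self):
        assert ts.compare_models([1, 2, 3], [1, 2, 3], "welch") == pytest.approx(1.0)

    def test_wilcoxon_extreme_case_matches_exact_enumeration(self):
        # oracle: enumerate all C(6,3) rank assignments of the pooled sample
        a, b = [1, 2, 3], [10, 11, 12]
        pooled = a + b
        rank_of = {v: r for r, v in enumerate(sorted(pooled), start=1)}
        obs_rank = sum(rank_of[v] for v in a)
        rank_sums = [
            sum(c) for c in itertools.combinations(sorted(rank_of.values()), 3)
        ]
        lo = sum(1 for s in rank_sums if s <= obs_rank) / len(rank_sums)
        hi = sum(1 for s in rank_sums if s >= obs_rank) / len(rank_sums)
        exact_p = min(1.0, 2 * min(lo, hi))
        assert ts.compare_models(a, b, "wilcoxon") == pytest.approx(exact_p)

    def test_welch_degenerate_variances(self):
        assert ts.compare_models([0, 0, 0], [0, 0, 0], "welch") == 1.0
        assert ts.compare_models([0, 0, 0], [1, 1, 1], "welch") == 0.0

    def test_insufficient_samples_raise(self):
        with pytest.raises(ValueError):
            ts.compare_models([1.0], [1.0, 2.0], "welch")
        with pytest.raises(ValueError):
            ts.compare_models([], [1.0], "wilcoxon")


def toy_binary_data(rng, n=80):
    """Linearly separable toy set on 6-position sequences."""
    x = np.zeros((n, 6, 20))
    y = rng.integers(0, 2, size=n)
    for i in range(n):
        x[i, :, y[i]] = 1.0
    cov = np.zeros((n, 0))
    return ArrayDataset(x=x, cov=cov, y=y)


def linear_spec(head="binary", **kw):
    return ts.ModelSpec(
        seq_layer=ts.SequenceLayerSpec(kind="linear"),
        embedding=ts.EmbeddingSpec(mode="onehot"),
        head=head, n_antigens=1, **kw,
    )


class TestTrainingLoop:
    def test_history_bounded_by_max_epochs(self, rng):
        data = toy_binary_data(rng)
        model = ts.Model(linear_spec(), seed=0)
        res = ts.train_model(
            model, data, toy_binary_data(rng, 20),
            ts.TrainConfig(max_epochs=5, window_n=3, seed=0),
        )
        assert len(res.history) <= 5

    def test_decreasing_val_loss_selects_last_epoch(self, rng):
        data = toy_binary_data(rng)
        val = toy_binary_data(rng, 20)
        model = ts.Model(linear_spec(), seed=0)
        res = ts.train_model(
            model, data, val, ts.TrainConfig(max_epochs=6, window_n=3, seed=0)
        )
        vals = [h["val_loss"] for h in res.history]
        if all(b < a for a, b in zip(vals, vals[1:])):
            assert res.selected_epoch == res.history[-1]["epoch"]

    def test_selected_checkpoint_best_in_terminal_window(self, rng):
        data = toy_binary_data(rng)
        val = toy_binary_data(rng, 20)
        model = ts.Model(linear_spec(), seed=1)
        res = ts.train_model(
            model, data, val, ts.TrainConfig(max_epochs=8, window_n=4, seed=1)
        )
        window = res.history[-min(4, len(res.history)):]
        sel = [h for h in res.history if h["epoch"] == res.selected_epoch][0]
        assert all(sel["val_loss"] <= h["val_loss"] for h in window)

    def test_same_seed_identical_history(self, rng):
        histories = []
        for _ in range(2):
            data = toy_binary_data(np.random.default_rng(7))
            val = toy_binary_data(np.random.default_rng(8), 20)
            model = ts.Model(linear_spec(), seed=4)
            res = ts.train_model(
                model, data, val, ts.TrainConfig(max_epochs=4, seed=4)
            )
            histories.append(res.history)
        assert histories[0] == histories[1]

    def test_empty_training_data_raises(self, rng):
        empty = toy_binary_data(rng, 1).subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            ts.train_model(
                ts.Model(linear_spec(), seed=0), empty, toy_binary_data(rng, 5),
                ts.TrainConfig(max_epochs=2),
            )

    def test_plateau_reduces_lr_and_stops_early(self, rng):
        # validation labels are pure noise, so the validation loss plateaus
        # (then worsens) and both schedule and stopping must trigger
        data = toy_binary_data(rng, 40)
        val = toy_binary_data(rng, 16)
        val.y = np.random.default_rng(99).integers(0, 2, size=len(val))
        model = ts.Model(linear_spec(), seed=0)
        config = ts.TrainConfig(
            max_epochs=60, patience=2, window_n=3, lr_reduce_factor=0.5, seed=0
        )
        res = ts.train_model(model, data, val, config)
        assert len(res.history) < config.max_epochs  # early stop fired
        assert len({h["lr"] for h in res.history}) > 1  # schedule fired


class TestCrossValidation:
    def test_threefold_reports_and_shared_folds(self, small_screen):
        cells, _ = ts.filter_doublets(small_screen.cells)
        config = ts.TrainConfig(max_epochs=3, batch_size=64, seed=0)
        reports = {}
        for kind in ("linear", "noseq"):
            spec = ts.ModelSpec(
                chain_mode="trb", head="categorical", n_antigens=3,
                seq_layer=ts.SequenceLayerSpec(kind=kind),
                embedding=ts.EmbeddingSpec(mode="learned"),
                covariate_set=("donor",),
            )
            reports[kind] = ts.run_cross_validation(
                cells, small_screen.panel, spec, config, k=3, base_seed=11
            )
        assert len(reports["linear"]) == 3
        # identical seeded folds across model specs -> identical test sizes
        assert [r.n_test for r in reports["linear"]] == [
            r.n_test for r in reports["noseq"]
        ]
        agg = ts.aggregate_reports(reports["linear"])
        assert agg["n_folds"] == 3 and 0 <= agg["auc_roc_mean"] <= 1

    def test_leave_one_donor_out_gives_one_fold_per_donor(self, small_screen):
        cells, _ = ts.filter_doublets(small_screen.cells)
        spec = ts.ModelSpec(
            chain_mode="trb", head="categorical", n_antigens=3,
            seq_layer=ts.SequenceLayerSpec(kind="linear"),
            embedding=ts.EmbeddingSpec(mode="learned"),
        )
        reports = ts.run_cross_validation(
            cells, small_screen.panel, spec,
            ts.TrainConfig(max_epochs=2, seed=0), scheme="leave_one_donor_out",
        )
        assert len(reports) == len({c.donor for c in cells})

    def test_k_exceeding_clonotypes_raises(self, small_screen):
        cells, _ = ts.filter_doublets(small_screen.cells)
        spec = ts.ModelSpec(
            head="categorical", n_antigens=3,
            seq_layer=ts.SequenceLayerSpec(kind="linear"),
            embedding=ts.EmbeddingSpec(mode="learned"),
        )
        with pytest.raises(ValueError):
            ts.run_cross_validation(
                cells, small_screen.panel, spec, ts.TrainConfig(), k=10_000
            )
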