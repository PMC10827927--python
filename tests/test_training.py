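import numpy as np
import pytest

from ertnet import (EEGNetBaseline, ERTNet, TrainConfig, evaluate, fit,
                    holdout_split, hyperparameter_search, kfold_cv, losocv,
                    sweep, transfer_init)
from ertnet.training import ProtocolError, SearchSpace, TransferError

from .conftest import tiny_model_config


FAST = TrainConfig(epochs=4, batch_size=16, learning_rate=3e-3, seed=0,
                   early_stop_patience=None)


class _StubModel:
    """Deterministic scorer standing in for a trained network."""

    def __init__(self, probs):
        self._probs = np.asarray(probs, dtype=float)

    def predict_proba(self, x, batch_size=64):
        return self._probs


class TestKFold:
    def test_folds_partition_the_data(self, tiny_epochs):
        ep, _ = tiny_epochs
        results, summary = kfold_cv(ep, tiny_model_config(), FAST, k=4)
        assert summary["n_folds"] == 4
        sizes = [int(r.confusion.sum()) for r in results]
        assert sum(sizes) == len(ep)

    def test_learnable_task_reaches_high_accuracy(self, tiny_epochs):
        ep, _ = tiny_epochs
        tc = TrainConfig(epochs=16, batch_size=16, learning_rate=5e-3,
                         seed=1, early_stop_patience=None)
        _, summary = kfold_cv(ep, tiny_model_config(), tc, k=2)
        assert summary["accuracy_mean"] > 85.0

    def test_single_fold_rejected(self, tiny_epochs):
        ep, _ = tiny_epochs
        with pytest.raises(ProtocolError):
            kfold_cv(ep, tiny_model_config(), FAST, k=1)


class TestHoldout:
    def test_stratified_80_20(self, tiny_epochs):
        ep, _ = tiny_epochs
        train, test = holdout_split(ep, 0.8, seed=0)
        assert len(train) == 64 and len(test) == 16
        # per-class proportions preserved
        assert np.bincount(test.labels).tolist() == [8, 8]

    def test_same_seed_reproduces_split(self, tiny_epochs):
        ep, _ = tiny_epochs
        a = holdout_split(ep, 0.8, seed=3)
        b = holdout_split(ep, 0.8, seed=3)
        np.testing.assert_array_equal(a[1].epochs, b[1].epochs)

    def test_degenerate_ratio_rejected(self, tiny_epochs):
        ep, _ = tiny_epochs
        with pytest.raises(ProtocolError):
            holdout_split(ep, 1.0)


class TestLosocv:
    def test_rounds_partition_by_subject(self, tiny_epochs):
        ep, _ = tiny_epochs
        per_subject, summary = losocv(ep, tiny_model_config(), FAST)
        assert set(per_subject) == set(np.unique(ep.subject_ids))
        total = sum(int(r.confusion.sum()) for r in per_subject.values())
        assert total == len(ep)

    def test_single_subject_rejected(self, tiny_epochs):
        ep, _ = tiny_epochs
        solo = ep.subset(np.where(ep.subject_ids == ep.subject_ids[0])[0])
        with pytest.raises(ProtocolError):
            losocv(solo, tiny_model_config(), FAST)


class TestFit:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_epochs):
        ep, _ = tiny_epochs
        model = ERTNet(tiny_model_config(dropout=0.0), seed=0)
        before = {p.name: p.value.copy() for p in model.params}
        fit(model, ep, TrainConfig(epochs=2, batch_size=16, learning_rate=0.0,
                                   seed=0, early_stop_patience=None))
        for p in model.params:
            np.testing.assert_array_equal(p.value, before[p.name])

    def test_seeded_run_is_reproducible(self, tiny_epochs):
        ep, _ = tiny_epochs
        losses = []
        for _ in range(2):
            model = ERTNet(tiny_model_config(), seed=4, dtype=np.float32)
            hist = fit(model, ep, TrainConfig(epochs=3, batch_size=16,
                                              learning_rate=3e-3, seed=4,
                                              early_stop_patience=None))
            losses.append(hist["loss"][-1])
        assert abs(losses[0] - losses[1]) < 1e-6

    def test_loss_decreases_on_learnable_task(self, tiny_epochs):
        ep, _ = tiny_epochs
        model = ERTNet(tiny_model_config(), seed=2, dtype=np.float32)
        hist = fit(model, ep, TrainConfig(epochs=14, batch_size=16,
                                          learning_rate=5e-3, seed=2,
                                          early_stop_patience=None))
        assert hist["loss"][-1] < hist["loss"][0]
        assert hist["accuracy"][-1] > 0.9


class TestEvaluate:
    def test_perfect_scores(self, tiny_epochs):
        ep, _ = tiny_epochs
        probs = np.eye(2)[ep.labels]
        result = evaluate(_StubModel(probs), ep)
        assert result.accuracy == 100.0
        assert result.auc_macro == 1.0

    def test_confusion_matrix_conserves_counts(self, tiny_epochs):
        ep, _ = tiny_epochs
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(2), size=len(ep))
        result = evaluate(_StubModel(probs), ep)
        assert int(result.confusion.sum()) == len(ep)
        acc_direct = 100.0 * np.mean(probs.argmax(1) == ep.labels)
        assert result.accuracy == pytest.approx(acc_direct)

    def test_random_scores_have_chance_auc(self, tiny_epochs):
        ep, _ = tiny_epochs
        big = ep.subset(np.tile(np.arange(len(ep)), 25))  # n = 2000
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(2), size=len(big))
        result = evaluate(_StubModel(probs), big)
        assert abs(result.auc_macro - 0.5) < 0.05

    def test_single_class_auc_is_missing(self, tiny_epochs):
        ep, _ = tiny_epochs
        only = ep.subset(np.where(ep.labels == 0)[0])
        rng = np.random.default_rng(2)
        result = evaluate(_StubModel(rng.dirichlet(np.ones(2),
                                                   size=len(only))), only)
        assert result.auc_macro is None


class TestTransfer:
    def test_extractor_copies_bit_exactly(self, tiny_epochs):
        ep, _ = tiny_epochs
        cfg = tiny_model_config()
        source = EEGNetBaseline(cfg, seed=1, dtype=np.float32)
        fit(source, ep, FAST)
        target = ERTNet(cfg, seed=9, dtype=np.float32)
        transfer_init(target, source)
        for name, p in source.param_dict.items():
            if name.split(".")[0] in ("temporal", "bn1", "spatial", "bn2",
                                      "sep", "bn3"):
                np.testing.assert_array_equal(target.param_dict[name].value,
                                              p.value)

    def test_extraction_forward_matches_after_transfer(self, tiny_epochs):
        ep, _ = tiny_epochs
        cfg = tiny_model_config(dropout=0.0)
        source = EEGNetBaseline(cfg, seed=1, dtype=np.float32)
        fit(source, ep, FAST)
        target = transfer_init(ERTNet(cfg, seed=9, dtype=np.float32), source)
        x = ep.epochs[:4].astype(np.float32)
        n_extract = 13  # layers up to and incl. the second dropout

        def run_stack(model):
            h = x
            for layer in model.net.layers[:n_extract]:
                h = layer.forward(h, False)
            return h

        np.testing.assert_allclose(run_stack(source), run_stack(target),
                                   atol=1e-6)

    def test_mismatched_f1_raises_naming_the_layer(self):
        small = tiny_model_config()
        big = tiny_model_config(f1=4)
        source = EEGNetBaseline(small, seed=0)
        target = ERTNet(big, seed=0)
        with pytest.raises(TransferError, match="temporal"):
            transfer_init(target, source)

    def test_checkpoint_as_transfer_source(self, tmp_path, tiny_epochs):
        cfg = tiny_model_config()
        source = EEGNetBaseline(cfg, seed=5)
        path = source.save(tmp_path / "eegnet.npz")
        target = transfer_init(ERTNet(cfg, seed=0), str(path))
        np.testing.assert_array_equal(
            target.param_dict["temporal.W"].value,
            source.param_dict["temporal.W"].value)


class TestSearchAndSweep:
    def test_budget_one_returns_that_config(self, tiny_epochs):
        ep, _ = tiny_epochs
        space = SearchSpace(f1=(2, 3), kernel_length=(6, 10), depth=(1, 2),
                            n_heads=(2, 3))
        best, log = hyperparameter_search(space, ep, tiny_model_config(),
                                          FAST, budget=1, k=2, seed=0)
        assert len(log) == 1
        assert best.f1 == log.iloc[0]["f1"]

    def test_all_trials_respect_bounds_and_f2_rule(self, tiny_epochs):
        ep, _ = tiny_epochs
        space = SearchSpace(f1=(2, 4), kernel_length=(5, 12), depth=(1, 3),
                            n_heads=(2, 4))
        _, log = hyperparameter_search(space, ep, tiny_model_config(),
                                       FAST, budget=3, k=2, seed=1)
        assert log["f1"].between(2, 4).all()
        assert log["kernel_length"].between(5, 12).all()
        assert log["depth"].between(1, 3).all()
        assert log["n_heads"].between(2, 4).all()
        assert (log["f2"] == log["f1"] * log["depth"]).all()

    def test_sweep_has_one_row_per_value(self, tiny_epochs):
        ep, _ = tiny_epochs
        table = sweep("n_blocks", [0, 1], ep, tiny_model_config(), FAST, k=2)
        assert len(table) == 2
        assert set(table["n_blocks"]) == {0, 1}


class TestDivergence:
    def test_non_finite_loss_raises_with_diagnostics(self, tiny_epochs):
        from ertnet.training import DivergenceError
        ep, _ = tiny_epochs
        bad = ep.subset(np.arange(len(ep)))
        bad.epochs[0, 0, 0] = np.nan
        model = ERTNet(tiny_model_config(), seed=0)
        with pytest.raises(DivergenceError, match="epoch"):
            fit(model, bad, FAST)
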