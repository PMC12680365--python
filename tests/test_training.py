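"""Joint objective, quality targets, scheduler and the training loop."""

import numpy as np
import pytest

from fundusgcn.gcnnet import GraphDRModel
from fundusgcn.phantoms import PhantomSpec, generate_samples
from fundusgcn.training import (
    ReduceLROnPlateau,
    TrainConfig,
    derive_quality_targets,
    quality_loss,
    total_loss,
    train,
)


@pytest.fixture(scope="module")
def tiny_sets():
    spec = PhantomSpec(
        image_size=32, class_counts={g: 8 for g in range(5)}, seed=21
    )
    samples = generate_samples(spec)
    train_s = [s for i, s in enumerate(samples) if i % 4 != 0]
    val_s = [s for i, s in enumerate(samples) if i % 4 == 0]
    return train_s, val_s


class TestQualityLoss:
    def test_half_confidence_wrong_free_is_ln2(self):
        assert quality_loss(np.array([0.5]), np.array([1.0])) == pytest.approx(
            np.log(2), abs=1e-9
        )

    def test_perfect_prediction_limit(self):
        assert quality_loss(np.array([1.0 - 1e-7]), np.array([1.0])) < 1e-6

    def test_confidently_wrong(self):
        assert quality_loss(np.array([0.9]), np.array([0.0])) == pytest.approx(
            -np.log(0.1), abs=1e-9
        )

    def test_mean_over_batch(self):
        q_hat = np.array([0.5, 0.5])
        q = np.array([1.0, 0.0])
        assert quality_loss(q_hat, q) == pytest.approx(np.log(2), abs=1e-12)

    def test_nonbinary_targets_rejected(self):
        with pytest.raises(ValueError):
            quality_loss(np.array([0.5]), np.array([0.3]))


class TestTotalLoss:
    def test_weighted_sum(self):
        assert total_loss(1.0, 0.5, 0.1) == pytest.approx(1.05)

    def test_lambda_zero_reduces_bitwise(self):
        assert total_loss(0.123456789, 7.0, 0.0) == 0.123456789

    def test_zero_quality_term(self):
        assert total_loss(2.0, 0.0, 0.7) == 2.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, -0.1)


class TestQualityTargets:
    def test_argmax_match_and_mismatch(self):
        probs = np.array([[0.1, 0.7, 0.1, 0.05, 0.05]])
        assert derive_quality_targets(probs, np.array([1]))[0] == 1.0
        assert derive_quality_targets(probs, np.array([3]))[0] == 0.0

    def test_tie_breaks_to_lowest_class(self):
        probs = np.array([[0.25, 0.25, 0.25, 0.25, 0.0]])
        assert derive_quality_targets(probs, np.array([0]))[0] == 1.0
        assert derive_quality_targets(probs, np.array([1]))[0] == 0.0


class TestScheduler:
    def test_reduces_only_after_patience_and_floors_at_min_lr(self):
        sched = ReduceLROnPlateau(lr=1e-3, factor=0.1, patience=2, min_lr=1e-6)
        assert sched.step(1.0) == 1e-3
        assert sched.step(1.0) == 1e-3  # bad 1
        assert sched.step(1.0) == 1e-3  # bad 2 == patience, not yet
        assert sched.step(1.0) == pytest.approx(1e-4)  # bad 3 > patience
        for _ in range(20):
            lr = sched.step(1.0)
        assert lr == pytest.approx(1e-6)

    def test_improvement_resets_counter(self):
        sched = ReduceLROnPlateau(lr=1e-3, factor=0.5, patience=1, min_lr=1e-7)
        sched.step(1.0)
        sched.step(2.0)
        assert sched.step(0.5) == 1e-3  # improvement: no reduction ever happened


class TestTrainConfig:
    def test_reference_defaults(self):
        cfg = TrainConfig()
        assert cfg.epochs == 50 and cfg.batch_size == 32
        assert cfg.learning_rate == 5e-5 and cfg.weight_decay == 0.01
        assert cfg.scheduler_patience == 7 and cfg.early_stop_patience == 15
        assert cfg.lam == 0.1 and cfg.mc_passes == 10 and cfg.seed == 42

    def test_early_stop_must_exceed_scheduler_patience(self):
        with pytest.raises(ValueError):
            TrainConfig(scheduler_patience=10, early_stop_patience=5)


class TestTrainLoop:
    def test_epoch_and_batch_bookkeeping(self, tiny_sets):
        train_s, val_s = tiny_sets
        model = GraphDRModel(rng=np.random.default_rng(0))
        cfg = TrainConfig(epochs=1, batch_size=16, seed=1)
        result = train(train_s, val_s, model, cfg)
        assert len(result.log.epochs) == 1
        assert len(result.log.epochs[0]["batch_losses"]) == 2  # ceil(30/16)

    def test_lambda_zero_leaves_quality_head_inert(self, tiny_sets):
        train_s, val_s = tiny_sets
        model = GraphDRModel(rng=np.random.default_rng(0))
        before_qa = model.heads.w_qa.copy()
        cfg = TrainConfig(epochs=1, batch_size=16, lam=0.0, seed=1)
        train(train_s, val_s, model, cfg)
        np.testing.assert_array_equal(model.heads.w_qa, before_qa)
        assert not np.array_equal(
            model.params["heads/w_cls"], np.zeros_like(model.heads.w_cls)
        )

    def test_two_runs_produce_identical_logs(self, tiny_sets):
        train_s, val_s = tiny_sets
        logs = []
        for _ in range(2):
            model = GraphDRModel(rng=np.random.default_rng(0))
            cfg = TrainConfig(epochs=2, batch_size=16, seed=42)
            result = train(train_s, val_s, model, cfg)
            logs.append(result.log.epochs)
        for e1, e2 in zip(*logs):
            assert abs(e1["train_loss"] - e2["train_loss"]) < 1e-6
            assert abs(e1["val_loss"] - e2["val_loss"]) < 1e-6

    def test_training_loss_decreases_on_separable_problem(self, tiny_sets):
        train_s, val_s = tiny_sets
        model = GraphDRModel(rng=np.random.default_rng(0))
        cfg = TrainConfig(epochs=5, batch_size=16, seed=42)
        result = train(train_s, val_s, model, cfg)
        losses = [e["train_loss"] for e in result.log.epochs]
        assert losses[-1] < losses[0]
        assert min(losses[2:]) < losses[0]

    def test_early_stopping_halts(self, tiny_sets):
        train_s, val_s = tiny_sets
        model = GraphDRModel(rng=np.random.default_rng(0))
        # tiny lr so validation never improves measurably after epoch 0
        cfg = TrainConfig(
            epochs=30, batch_size=16, learning_rate=1e-12, seed=1,
            scheduler_patience=2, early_stop_patience=3,
        )
        result = train(train_s, val_s, model, cfg)
        assert result.stopped_epoch < 29
        assert len(result.log.epochs) == result.stopped_epoch + 1

    def test_empty_partition_rejected(self, tiny_sets):
        train_s, _ = tiny_sets
        model = GraphDRModel(rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            train(train_s, [], model, TrainConfig(epochs=1, seed=0))

    def test_log_csv_schema(self, tiny_sets, tmp_path):
        train_s, val_s = tiny_sets
        model = GraphDRModel(rng=np.random.default_rng(0))
        result = train(train_s, val_s, model, TrainConfig(epochs=1, batch_size=16, seed=0))
        path = tmp_path / "log.csv"
        result.log.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "epoch,train_loss,train_cls,train_q,val_loss,lr"
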