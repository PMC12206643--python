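"""Schedule closed forms vs an independent oracle, KL/loss identities,
split properties, and training-loop contracts (zero-lr no-op, determinism,
separable-toy convergence)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegfusion import (FeatureSet, LRSchedule, SplitPlan, TrainConfig,
                       init_params, kl_gaussian, lr_at, make_splits,
                       total_loss, train_model)
from eegfusion.errors import InvalidArgumentError
from eegfusion.fusion_model import ModelOutput
from eegfusion.training import default_schedule


# --------------------------------------------------------------------------
# Independent schedule oracle (deliberately coded differently: a per-epoch
# iterative update rather than closed forms).
# --------------------------------------------------------------------------

def oracle_lr(schedule: LRSchedule, epoch: int) -> float:
    if schedule.kind == "constant":
        return schedule.lr0
    if schedule.kind == "piecewise_exponential":
        lr = schedule.lr0
        for e in range(epoch):
            seg = sum(1 for b in schedule.boundaries if e >= b)
            lr *= schedule.gammas[seg]
        return lr
    if schedule.kind == "cosine_annealing":
        return schedule.lr_min + 0.5 * (schedule.lr0 - schedule.lr_min) * (
            1 + math.cos(math.pi * epoch / schedule.t_max))
    if schedule.kind == "stepped":
        lr = schedule.lr0
        for e in range(1, epoch + 1):
            if e % schedule.step_size == 0:
                lr *= schedule.step_gamma
        return lr
    if schedule.kind == "linear":
        return schedule.lr0 + (schedule.final_lr - schedule.lr0) * (
            epoch / schedule.total_epochs)
    raise AssertionError


SCHEDULES = [
    LRSchedule(kind="constant", lr0=3e-3),
    LRSchedule(kind="piecewise_exponential", lr0=1e-3, boundaries=(10, 40),
               gammas=(1.0, 0.93, 0.85)),
    LRSchedule(kind="cosine_annealing", lr0=1e-3, lr_min=1e-5, t_max=80),
    LRSchedule(kind="stepped", lr0=1e-3, step_size=7, step_gamma=0.5),
    LRSchedule(kind="linear", lr0=1e-3, final_lr=1e-5, total_epochs=80),
]


class TestLRSchedules:
    @pytest.mark.parametrize("schedule", SCHEDULES, ids=lambda s: s.kind)
    def test_matches_iterative_oracle_at_random_epochs(self, schedule, rng):
        for epoch in rng.integers(0, 80, size=100):
            assert lr_at(schedule, int(epoch)) == pytest.approx(
                oracle_lr(schedule, int(epoch)), rel=1e-12)

    @pytest.mark.parametrize("schedule", SCHEDULES, ids=lambda s: s.kind)
    def test_nonincreasing_and_positive(self, schedule):
        values = [lr_at(schedule, e) for e in range(81)]
        assert all(v > 0 for v in values)
        assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    def test_piecewise_worked_example(self):
        """boundary [10], γ=(1.0, 0.5): two decayed epochs by epoch 12."""
        s = LRSchedule(kind="piecewise_exponential", lr0=1e-3,
                       boundaries=(10,), gammas=(1.0, 0.5))
        assert lr_at(s, 12) == pytest.approx(2.5e-4, rel=1e-12)

    def test_piecewise_continuous_at_boundaries(self):
        s = LRSchedule(kind="piecewise_exponential", lr0=1e-3,
                       boundaries=(10, 40), gammas=(0.99, 0.9, 0.8))
        for b in s.boundaries:
            left = lr_at(s, b - 1) * s.gammas[
                sum(1 for x in s.boundaries if b - 1 >= x)]
            assert lr_at(s, b) == pytest.approx(left, rel=1e-12)

    def test_cosine_endpoints(self):
        s = LRSchedule(kind="cosine_annealing", lr0=1e-3, lr_min=0.0, t_max=50)
        assert lr_at(s, 0) == pytest.approx(1e-3)
        assert lr_at(s, 50) == pytest.approx(0.0, abs=1e-18)

    def test_constant_everywhere(self):
        s = LRSchedule(kind="constant", lr0=2e-4)
        assert {lr_at(s, e) for e in range(100)} == {2e-4}

    def test_epoch_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            lr_at(SCHEDULES[0], -1)
        with pytest.raises(InvalidArgumentError):
            lr_at(LRSchedule(kind="linear", total_epochs=10), 11)

    def test_gamma_count_validated(self):
        with pytest.raises(InvalidArgumentError):
            LRSchedule(kind="piecewise_exponential", boundaries=(5,),
                       gammas=(1.0,))


class TestKLDivergence:
    def test_standard_normal_posterior_is_zero(self):
        assert kl_gaussian(np.zeros(4), np.zeros(4)) == 0.0

    def test_unit_mean_shift(self):
        assert kl_gaussian(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_variance_two(self):
        expected = 0.5 * (2 - 1 - math.log(2))
        assert kl_gaussian(np.array([0.0]), np.array([math.log(2)])) == \
            pytest.approx(expected, rel=1e-12)

    def test_nonnegative_and_zero_only_at_origin(self, rng):
        mu = rng.normal(0, 2, size=(10_000, 3))
        lv = rng.normal(0, 1, size=(10_000, 3))
        per = 0.5 * (mu ** 2 + np.exp(lv) - 1 - lv).sum(axis=1)
        assert np.all(per >= 0)
        assert kl_gaussian(mu, lv) > 0

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kl_gaussian(np.array([np.inf]), np.array([0.0]))


class TestTotalLoss:
    def _output(self, probs, mu, logvar, recon):
        return ModelOutput(probs=np.asarray(probs, dtype=float),
                           mu=np.asarray(mu, dtype=float),
                           logvar=np.asarray(logvar, dtype=float),
                           recon=np.asarray(recon, dtype=float))

    def test_one_hot_true_class_has_no_ce(self):
        x = np.zeros((2, 2))
        out = self._output([1.0, 0.0], [0.0], [0.0], x)
        assert total_loss(out, 0, x) <= 1e-6

    def test_zero_weights_reduce_to_cross_entropy(self, rng):
        x = rng.standard_normal((2, 2))
        out = self._output([0.25, 0.75], rng.normal(size=3),
                           rng.normal(size=3), rng.standard_normal((2, 2)))
        assert total_loss(out, 1, x, lambda_vae=0.0, beta=0.0) == \
            pytest.approx(-math.log(0.75), rel=1e-12)

    def test_perfect_reconstruction_and_prior_posterior(self):
        x = np.ones((2, 2))
        out = self._output([0.5, 0.5], [0.0, 0.0], [0.0, 0.0], x)
        assert total_loss(out, 0, x) == pytest.approx(math.log(2), rel=1e-12)

    @given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_loss_decomposes_additively(self, lam, beta):
        rng = np.random.default_rng(17)
        x = rng.standard_normal((3, 3))
        recon = rng.standard_normal((3, 3))
        mu, lv = rng.normal(size=2), rng.normal(size=2)
        out = self._output([0.3, 0.7], mu, lv, recon)
        base = total_loss(out, 1, x, 0.0, 0.0)
        full = total_loss(out, 1, x, lam, beta)
        mse = ((recon - x) ** 2).mean()
        assert full - base == pytest.approx(
            lam * mse + beta * kl_gaussian(mu, lv), rel=1e-9, abs=1e-12)

    def test_label_out_of_range_rejected(self):
        x = np.zeros((2, 2))
        out = self._output([0.5, 0.5], [0.0], [0.0], x)
        with pytest.raises(InvalidArgumentError):
            total_loss(out, 2, x)


def _toy_features(n_subjects=10, per_subject=10, seed=0):
    rng = np.random.default_rng(seed)
    n = n_subjects * per_subject
    labels = np.tile(np.arange(2), n // 2)
    X = rng.standard_normal((n, 6, 8, 9, 4))
    X[labels == 1] += 3.0           # large-margin separation
    subjects = np.repeat([f"S{i}" for i in range(n_subjects)], per_subject)
    return FeatureSet(features=X, labels=labels, subjects=subjects.astype(object),
                      class_names=("a", "b"), band_names=("t", "a", "b", "g"),
                      structural_mask=np.ones((8, 9), dtype=bool))


class TestSplits:
    def test_loso_one_fold_per_subject(self):
        fs = _toy_features()
        folds = make_splits(fs, SplitPlan(protocol="leave_one_subject_out"))
        assert len(folds) == 10
        for (train, test), sid in zip(folds, sorted(set(fs.subjects))):
            assert set(fs.subjects[test]) == {sid}
            assert sid not in set(fs.subjects[train])

    def test_kfold_test_sizes(self):
        fs = _toy_features()
        folds = make_splits(fs, SplitPlan(k=5, seed=1))
        assert sorted(len(te) for _, te in folds) == [20, 20, 20, 20, 20]

    def test_folds_partition_indices(self):
        fs = _toy_features()
        for plan in (SplitPlan(k=5, seed=3),
                     SplitPlan(protocol="leave_one_subject_out")):
            folds = make_splits(fs, plan)
            tests = [set(te.tolist()) for _, te in folds]
            union = set().union(*tests)
            assert union == set(range(len(fs)))
            assert sum(len(t) for t in tests) == len(fs)
            for train, test in folds:
                assert not set(train.tolist()) & set(test.tolist())

    def test_deterministic_under_seed(self):
        fs = _toy_features()
        a = make_splits(fs, SplitPlan(k=5, seed=9))
        b = make_splits(fs, SplitPlan(k=5, seed=9))
        for (tr1, te1), (tr2, te2) in zip(a, b):
            assert np.array_equal(te1, te2)

    def test_loso_needs_two_subjects(self):
        fs = _toy_features(n_subjects=1, per_subject=4)
        with pytest.raises(InvalidArgumentError):
            make_splits(fs, SplitPlan(protocol="leave_one_subject_out"))


class TestTrainModel:
    def test_zero_lr_leaves_params_at_init(self, tiny_model_config):
        fs = _toy_features(n_subjects=2, per_subject=8)
        cfg = TrainConfig(epochs=1, batch_size=8, seed=5,
                          schedule=LRSchedule(kind="constant", lr0=1e-300))
        model, _ = train_model(fs, cfg, None, tiny_model_config)
        ref = init_params(tiny_model_config, seed=cfg.seed, dtype=np.float64)
        for k in ref:
            assert np.allclose(model.params[k], ref[k], atol=1e-290)

    def test_fixed_seed_reproduces_history(self, tiny_model_config):
        fs = _toy_features(n_subjects=2, per_subject=8)
        cfg = TrainConfig(epochs=2, batch_size=8, seed=5,
                          schedule=default_schedule("piecewise_exponential", 2))
        folds = make_splits(fs, SplitPlan(k=2, seed=0))
        _, h1 = train_model(fs, cfg, folds[0], tiny_model_config)
        _, h2 = train_model(fs, cfg, folds[0], tiny_model_config)
        assert h1.as_dict() == h2.as_dict()

    def test_history_lengths_and_lr_values(self, tiny_model_config):
        fs = _toy_features(n_subjects=2, per_subject=8)
        sched = default_schedule("stepped", 3)
        cfg = TrainConfig(epochs=3, batch_size=8, seed=5, schedule=sched)
        _, hist = train_model(fs, cfg, None, tiny_model_config)
        assert len(hist.lr) == len(hist.train_loss) == 3
        assert hist.lr == [lr_at(sched, e) for e in range(3)]

    def test_separable_toy_reaches_high_accuracy(self, tiny_model_config):
        fs = _toy_features(n_subjects=4, per_subject=32)
        cfg = TrainConfig(epochs=30, batch_size=16, seed=2,
                          schedule=default_schedule("piecewise_exponential", 30))
        _, hist = train_model(fs, cfg, None, tiny_model_config,
                              dtype=np.float32)
        assert hist.train_acc[-1] >= 0.99

    def test_empty_split_rejected(self, tiny_model_config):
        fs = _toy_features(n_subjects=2, per_subject=4)
        cfg = TrainConfig(epochs=1, batch_size=4, seed=0)
        with pytest.raises(InvalidArgumentError):
            train_model(fs, cfg, (np.zeros(0, dtype=int), np.arange(4)),
                        tiny_model_config)
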