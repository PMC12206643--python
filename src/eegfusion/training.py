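"""Loss assembly, learning-rate schedules, CV splits and the training loop.

The total objective couples the classifier with the VAE evidence lower bound:

    L = CE(probs, y) + λ_vae · MSE(x′, x) + β · KL(q(z|x) ‖ N(0, I))

with the diagonal-Gaussian KL in closed form,
KL = ½ Σ_j (μ_j² + σ_j² − 1 − ln σ_j²).

Five learning-rate policies are provided in closed form (constant, piecewise
exponential decay, cosine annealing, stepped descent, linear descent); the
piecewise exponential policy applies a per-epoch decay factor per segment and
is continuous at segment boundaries.  None of the policies' hyperparameter
values are canonical — the defaults here are the package's own and are fully
configurable.

Optimization is plain mini-batch Adam, fully reproducible under the config
seed (initialization, batch order, and the VAE reparameterization noise all
derive from it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import EEGFusionError, InvalidArgumentError
from .features4d import FeatureSet
from .fusion_model import FusionModel, ModelConfig, ModelOutput

SCHEDULE_KINDS = ("constant", "piecewise_exponential", "cosine_annealing",
                  "stepped", "linear")


# --------------------------------------------------------------------------
# Learning-rate schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LRSchedule:
    """One of five closed-form learning-rate policies.

    kind-specific fields:

    * ``piecewise_exponential``: ``boundaries`` (epoch list) split training
      into segments; ``gammas`` (one per segment) is the per-epoch decay
      within each segment, applied continuously across boundaries.
    * ``cosine_annealing``: ``lr_min`` floor and half-period ``t_max``.
    * ``stepped``: multiply by ``step_gamma`` every ``step_size`` epochs.
    * ``linear``: straight line from ``lr0`` to ``final_lr`` over
      ``total_epochs``.
    """

    kind: str = "piecewise_exponential"
    lr0: float = 1e-3
    boundaries: tuple[int, ...] = (30, 60)
    gammas: tuple[float, ...] = (1.0, 0.95, 0.90)
    lr_min: float = 1e-5
    t_max: int = 80
    step_size: int = 20
    step_gamma: float = 0.5
    final_lr: float = 1e-5
    total_epochs: int = 80

    def __post_init__(self) -> None:
        if self.kind not in SCHEDULE_KINDS:
            raise InvalidArgumentError(
                f"kind must be one of {SCHEDULE_KINDS}, got {self.kind!r}")
        if self.lr0 <= 0:
            raise InvalidArgumentError("lr0 must be > 0")
        if self.kind == "piecewise_exponential":
            if len(self.gammas) != len(self.boundaries) + 1:
                raise InvalidArgumentError(
                    "need one gamma per segment: len(gammas) == "
                    "len(boundaries) + 1")
            if list(self.boundaries) != sorted(set(self.boundaries)):
                raise InvalidArgumentError("boundaries must be increasing")
            if any(g <= 0 for g in self.gammas):
                raise InvalidArgumentError("gammas must be > 0")


def lr_at(schedule: LRSchedule, epoch: int) -> float:
    """Closed-form learning rate at an (integer) epoch."""
    if epoch < 0:
        raise InvalidArgumentError(f"epoch must be >= 0, got {epoch}")
    k = schedule.kind
    if k == "constant":
        return schedule.lr0
    if k == "piecewise_exponential":
        starts = (0,) + tuple(schedule.boundaries)
        lr_enter = schedule.lr0
        for i, start in enumerate(starts):
            end = starts[i + 1] if i + 1 < len(starts) else None
            if end is None or epoch < end:
                return lr_enter * schedule.gammas[i] ** (epoch - start)
            lr_enter *= schedule.gammas[i] ** (end - start)
        raise AssertionError("unreachable")
    if k == "cosine_annealing":
        if epoch > schedule.t_max:
            raise InvalidArgumentError(
                f"epoch {epoch} beyond cosine half-period t_max={schedule.t_max}")
        return schedule.lr_min + 0.5 * (schedule.lr0 - schedule.lr_min) * (
            1.0 + math.cos(math.pi * epoch / schedule.t_max))
    if k == "stepped":
        return schedule.lr0 * schedule.step_gamma ** (epoch // schedule.step_size)
    if k == "linear":
        if epoch > schedule.total_epochs:
            raise InvalidArgumentError(
                f"epoch {epoch} beyond total_epochs={schedule.total_epochs}")
        frac = epoch / schedule.total_epochs
        return schedule.lr0 + (schedule.final_lr - schedule.lr0) * frac
    raise AssertionError("unreachable")


def default_schedule(kind: str, epochs: int, lr0: float = 1e-3) -> LRSchedule:
    """A schedule of the given kind scaled to an epoch horizon."""
    b1, b2 = max(1, int(0.4 * epochs)), max(2, int(0.75 * epochs))
    return LRSchedule(kind=kind, lr0=lr0,
                      boundaries=(b1, b2), gammas=(1.0, 0.95, 0.90),
                      lr_min=lr0 * 1e-2, t_max=epochs,
                      step_size=max(1, epochs // 4), step_gamma=0.5,
                      final_lr=lr0 * 1e-2, total_epochs=epochs)


# --------------------------------------------------------------------------
# Losses
# --------------------------------------------------------------------------

def kl_gaussian(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL( N(μ, diag e^{logvar}) ‖ N(0, I) ) = ½ Σ (μ² + σ² − 1 − ln σ²).

    1-D inputs give the per-sample sum; 2-D (batch, d) inputs give the batch
    mean of per-sample sums.
    """
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(logvar))):
        raise InvalidArgumentError("mu and logvar must be finite")
    per = 0.5 * (mu ** 2 + np.exp(logvar) - 1.0 - logvar)
    if mu.ndim <= 1:
        return float(per.sum())
    return float(per.sum(axis=-1).mean())


def total_loss(output: ModelOutput, target_label: int, x_input: np.ndarray,
               lambda_vae: float = 1.0, beta: float = 1.0) -> float:
    """CE + λ_vae·MSE(recon, x) + β·KL for a single model output."""
    n_classes = len(output.probs)
    if not (0 <= target_label < n_classes):
        raise InvalidArgumentError(
            f"label {target_label} out of range for {n_classes} classes")
    ce = -math.log(max(float(output.probs[target_label]), 1e-300))
    mse = float(((output.recon - x_input) ** 2).mean())
    return ce + lambda_vae * mse + beta * kl_gaussian(output.mu, output.logvar)


# --------------------------------------------------------------------------
# Splits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Cross-validation protocol: sample-level stratified k-fold
    (subject-dependent) or leave-one-subject-out (subject-independent)."""

    protocol: str = "subject_dependent_kfold"
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in ("subject_dependent_kfold",
                                 "leave_one_subject_out"):
            raise InvalidArgumentError(f"unknown protocol {self.protocol!r}")
        if self.k < 2:
            raise InvalidArgumentError("k must be >= 2")


def make_splits(feature_set: FeatureSet,
                plan: SplitPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic folds; LOSO folds are subject-disjoint by construction."""
    labels = np.asarray(feature_set.labels)
    subjects = np.asarray(feature_set.subjects)
    n = len(labels)
    if n == 0:
        raise InvalidArgumentError("empty feature set")
    if plan.protocol == "subject_dependent_kfold":
        skf = StratifiedKFold(n_splits=plan.k, shuffle=True,
                              random_state=plan.seed)
        return [(tr, te) for tr, te in skf.split(np.zeros(n), labels)]
    unique = sorted(set(subjects))
    if len(unique) < 2:
        raise InvalidArgumentError(
            f"leave-one-subject-out needs >= 2 subjects, got {len(unique)}")
    folds = []
    idx = np.arange(n)
    for sid in unique:
        test = idx[subjects == sid]
        train = idx[subjects != sid]
        folds.append((train, test))
    return folds


# --------------------------------------------------------------------------
# Training loop
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 80
    batch_size: int = 64
    lambda_vae: float = 1.0
    beta: float = 1.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    schedule: LRSchedule = field(default_factory=LRSchedule)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InvalidArgumentError("epochs must be >= 1")
        if self.lambda_vae < 0 or self.beta < 0:
            raise InvalidArgumentError("loss weights must be >= 0")


@dataclass
class TrainHistory:
    """Per-epoch bookkeeping; every list has length ``epochs``."""

    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def as_dict(self) -> dict[str, list[float]]:
        return {"lr": self.lr, "train_loss": self.train_loss,
                "train_acc": self.train_acc, "val_acc": self.val_acc}


def train_model(features: FeatureSet, config: TrainConfig,
                fold: tuple[np.ndarray, np.ndarray] | None = None,
                model_config: ModelConfig | None = None,
                dtype=np.float64) -> tuple[FusionModel, TrainHistory]:
    """Mini-batch Adam on one CV fold; reproducible under ``config.seed``.

    ``fold`` is (train indices, test indices); None trains on everything.
    Aborts with diagnostics on a non-finite loss.
    """
    X = np.asarray(features.features)
    y = np.asarray(features.labels)
    if fold is None:
        train_idx = np.arange(len(X))
        test_idx = np.zeros(0, dtype=int)
    else:
        train_idx, test_idx = np.asarray(fold[0]), np.asarray(fold[1])
    if len(train_idx) == 0:
        raise InvalidArgumentError("empty training split")
    if model_config is None:
        model_config = ModelConfig(
            n_classes=int(y.max()) + 1,
            input_shape=tuple(X.shape[1:]))
    Xtr, ytr = X[train_idx].astype(dtype), y[train_idx]
    Xte, yte = X[test_idx].astype(dtype), y[test_idx]

    model = FusionModel(model_config, seed=config.seed, dtype=dtype)
    adam_m = {k: np.zeros_like(p) for k, p in model.params.items()}
    adam_v = {k: np.zeros_like(p) for k, p in model.params.items()}
    t = 0
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    d = model_config.latent_dim
    history = TrainHistory()

    for epoch in range(config.epochs):
        lr = lr_at(config.schedule, epoch)
        order = rng.permutation(len(Xtr))
        epoch_loss, epoch_hits, seen = 0.0, 0, 0
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            xb, yb = Xtr[batch], ytr[batch]
            eps = rng.standard_normal((len(batch), d)).astype(dtype)
            loss, grads, metrics = model.loss_and_grads(
                xb, yb, lambda_vae=config.lambda_vae, beta=config.beta,
                eps=eps)
            if not math.isfinite(loss):
                raise EEGFusionError(
                    f"non-finite loss at epoch {epoch}, batch offset {start}: "
                    f"{metrics}")
            t += 1
            b1, b2 = config.adam_beta1, config.adam_beta2
            corr1 = 1.0 - b1 ** t
            corr2 = 1.0 - b2 ** t
            for k, g in grads.items():
                adam_m[k] = b1 * adam_m[k] + (1 - b1) * g
                adam_v[k] = b2 * adam_v[k] + (1 - b2) * g * g
                model.params[k] -= lr * (adam_m[k] / corr1) / (
                    np.sqrt(adam_v[k] / corr2) + config.adam_eps)
            epoch_loss += loss * len(batch)
            # running accuracy from the pre-update forward pass
            epoch_hits += metrics["hits"]
            seen += len(batch)
        history.lr.append(float(lr))
        history.train_loss.append(float(epoch_loss / seen))
        history.train_acc.append(float(epoch_hits / seen))
        history.val_acc.append(
            float((model.predict(Xte) == yte).mean()) if len(yte) else math.nan)
    model.trained = True
    return model, history
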