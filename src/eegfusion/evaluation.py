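"""Metrics, experiment orchestration, and report plumbing.

Accuracy is the fraction of correctly classified samples — in the binary case
(TP+TN)/(TP+TN+FP+FN), generalised to trace(CM)/total for multiclass.  The
spread across the N cross-validation folds is the sample standard deviation
with the N−1 denominator.  Accuracies are reported in percent.

``run_experiment`` executes the full chain — simulate → featurize → split →
train → evaluate — from a single nested config dict (YAML-friendly), and is a
pure function of that config: re-running with the same config reproduces the
report and every training history bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import EEGFusionError, InvalidArgumentError
from .features4d import FeatureSet, default_bands, extract_features, grid_for_montage
from .fusion_model import FusionModel, ModelConfig, save_checkpoint
from .synthetic_eeg import (DatasetSpec, deap_like_classes, generate_dataset,
                            seed_like_classes)
from .training import (LRSchedule, SCHEDULE_KINDS, SplitPlan, TrainConfig,
                       default_schedule, make_splits, train_model)


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    """Rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise InvalidArgumentError("confusion matrix must be square")
        if np.any(c < 0):
            raise InvalidArgumentError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(true_labels, predicted_labels, n_classes: int
                     ) -> ConfusionMatrix:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise InvalidArgumentError(
            f"length mismatch: {t.shape} vs {p.shape}")
    if t.size and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise InvalidArgumentError("labels out of range")
    if t.size == 0:
        return ConfusionMatrix(np.zeros((n_classes, n_classes), dtype=int))
    counts = _sk_confusion(t, p, labels=np.arange(n_classes))
    return ConfusionMatrix(counts.astype(int))


def accuracy(cm: ConfusionMatrix) -> float:
    """trace/total; equals (TP+TN)/(TP+TN+FP+FN) for two classes."""
    if cm.total == 0:
        raise InvalidArgumentError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def fold_std(accuracies) -> float:
    """Sample standard deviation across folds, sqrt(Σ(x−x̄)²/(N−1))."""
    x = np.asarray(accuracies, dtype=float)
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 fold accuracies")
    return float(x.std(ddof=1))


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """Diagonal over row totals; empty classes flagged as NaN, not raised."""
    counts = np.asarray(cm.counts, dtype=float)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.diag(counts) / totals
    vals[totals == 0] = np.nan
    return vals


# --------------------------------------------------------------------------
# Experiment configuration
# --------------------------------------------------------------------------

CLASS_PRESETS = {"seed3": seed_like_classes, "deap2": deap_like_classes}


def default_config() -> dict:
    """Bundled study conditions: 8 subjects × 3 classes × 20 trials of 60 s
    at 200 Hz, non-overlapping 6-window fragments, a compact fusion network,
    and a 15-epoch piecewise-exponential training run."""
    return {
        "dataset": {"n_subjects": 8, "trials_per_class": 20,
                    "classes": "seed3", "duration_s": 60.0, "fs": 200.0,
                    "montage": "seed62", "seed": 42},
        "features": {"window_s": 1.0, "T": 6, "stride": 6},
        "model": {"cnn_channels": [16, 32], "bilstm_hidden": 32,
                  "merge_mode": "concat", "dcign_channels": [16, 32, 64],
                  "latent_dim": 32, "fusion_hidden": [64]},
        "train": {"epochs": 8, "batch_size": 64, "lambda_vae": 1.0,
                  "beta": 1.0, "seed": 42, "lr0": 1e-3,
                  "schedule": "piecewise_exponential", "dtype": "float32"},
        "split": {"protocol": "subject_dependent_kfold", "k": 5, "seed": 42},
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) else v
    return out


def load_config(path) -> dict:
    with open(path) as f:
        return _merge(default_config(), yaml.safe_load(f) or {})


def dataset_spec_from_config(cfg: dict) -> DatasetSpec:
    d = cfg["dataset"]
    classes = d["classes"]
    if isinstance(classes, str):
        if classes not in CLASS_PRESETS:
            raise InvalidArgumentError(
                f"unknown class preset {classes!r}; have {sorted(CLASS_PRESETS)}")
        classes = CLASS_PRESETS[classes]()
    return DatasetSpec(n_subjects=int(d["n_subjects"]),
                       trials_per_class=int(d["trials_per_class"]),
                       classes=tuple(classes),
                       duration_s=float(d["duration_s"]), fs=float(d["fs"]),
                       montage=d["montage"], seed=int(d["seed"]))


def schedule_from_config(cfg: dict) -> LRSchedule:
    t = cfg["train"]
    sched = t["schedule"]
    if isinstance(sched, str):
        return default_schedule(sched, int(t["epochs"]), float(t["lr0"]))
    kw = dict(sched)
    for key in ("boundaries", "gammas"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return LRSchedule(**kw)


def model_config_from_config(cfg: dict, n_classes: int,
                             input_shape: tuple) -> ModelConfig:
    m = cfg["model"]
    return ModelConfig(n_classes=n_classes, input_shape=tuple(input_shape),
                       cnn_channels=tuple(m["cnn_channels"]),
                       bilstm_hidden=int(m["bilstm_hidden"]),
                       merge_mode=m["merge_mode"],
                       dcign_channels=tuple(m["dcign_channels"]),
                       latent_dim=int(m["latent_dim"]),
                       fusion_hidden=tuple(m["fusion_hidden"]))


def featurize_config(cfg: dict, recordings) -> FeatureSet:
    f = cfg["features"]
    grid = grid_for_montage(cfg["dataset"]["montage"])
    return extract_features(recordings, bands=default_bands(), grid=grid,
                            window_s=float(f["window_s"]), T=int(f["T"]),
                            stride=int(f["stride"]))


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    """Per-fold and per-subject accuracy bookkeeping (percent)."""

    protocol: str
    class_names: list[str]
    fold_accuracies: list[float]
    mean_acc: float
    std: float
    per_class: dict[str, float]
    per_subject: dict[str, float]
    confusion: list[list[int]]
    histories: list[dict]
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)

    def save(self, run_dir) -> None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "report.json").write_text(self.to_json())
        rows = [{"fold": i, "accuracy_pct": round(a, 2)}
                for i, a in enumerate(self.fold_accuracies)]
        pd.DataFrame(rows).to_csv(run_dir / "report.csv", index=False)


def load_report(path) -> ExperimentReport:
    """Load a report and re-check its internal consistency."""
    path = Path(path)
    if path.is_dir():
        path = path / "report.json"
    rep = ExperimentReport(**json.loads(path.read_text()))
    if abs(rep.mean_acc - float(np.mean(rep.fold_accuracies))) > 1e-6:
        raise EEGFusionError("report mean does not match its fold column")
    return rep


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

def _fold_seed(base: int, fold_idx: int) -> int:
    return int((base * 1009 + fold_idx * 9973 + 1) % (2 ** 31))


def run_experiment(config: dict | None = None, run_dir=None,
                   features: FeatureSet | None = None,
                   save_models: bool = False) -> ExperimentReport:
    """simulate → featurize → split → train → evaluate, from one config.

    ``features`` short-circuits simulation/featurization (used by the
    schedule-comparison harness to share one feature set across runs).
    """
    cfg = _merge(default_config(), config or {})
    if features is None:
        recordings = generate_dataset(dataset_spec_from_config(cfg))
        features = featurize_config(cfg, recordings)
    n_classes = len(features.class_names)
    model_cfg = model_config_from_config(cfg, n_classes,
                                         features.features.shape[1:])
    sched = schedule_from_config(cfg)
    t = cfg["train"]
    dtype = np.float32 if t.get("dtype", "float64") == "float32" else np.float64
    plan = SplitPlan(protocol=cfg["split"]["protocol"],
                     k=int(cfg["split"]["k"]), seed=int(cfg["split"]["seed"]))
    folds = make_splits(features, plan)

    y = np.asarray(features.labels)
    subjects = np.asarray([str(s) for s in features.subjects])
    fold_accs: list[float] = []
    histories: list[dict] = []
    agg = np.zeros((n_classes, n_classes), dtype=int)
    all_true: list[np.ndarray] = []
    all_pred: list[np.ndarray] = []
    all_subj: list[np.ndarray] = []

    for i, (train_idx, test_idx) in enumerate(folds):
        tc = TrainConfig(epochs=int(t["epochs"]),
                         batch_size=int(t["batch_size"]),
                         lambda_vae=float(t["lambda_vae"]),
                         beta=float(t["beta"]),
                         seed=_fold_seed(int(t["seed"]), i), schedule=sched)
        model, hist = train_model(features, tc, (train_idx, test_idx),
                                  model_cfg, dtype=dtype)
        preds = model.predict(features.features[test_idx].astype(dtype))
        cm = confusion_matrix(y[test_idx], preds, n_classes)
        fold_accs.append(100.0 * accuracy(cm))
        agg += cm.counts
        histories.append(hist.as_dict())
        all_true.append(y[test_idx])
        all_pred.append(preds)
        all_subj.append(subjects[test_idx])
        if save_models and run_dir is not None:
            Path(run_dir).mkdir(parents=True, exist_ok=True)
            save_checkpoint(model, Path(run_dir) / f"checkpoint_fold{i}.npz")

    agg_cm = ConfusionMatrix(agg)
    pc = per_class_accuracy(agg_cm)
    per_class = {c: float(round(100.0 * v, 2)) if np.isfinite(v)
                 else float("nan")
                 for c, v in zip(features.class_names, pc)}
    true_all = np.concatenate(all_true)
    pred_all = np.concatenate(all_pred)
    subj_all = np.concatenate(all_subj)
    per_subject = {}
    for sid in sorted(set(subj_all)):
        m = subj_all == sid
        per_subject[str(sid)] = float(
            round(100.0 * float((true_all[m] == pred_all[m]).mean()), 2))

    report = ExperimentReport(
        protocol=plan.protocol,
        class_names=list(features.class_names),
        fold_accuracies=fold_accs,
        mean_acc=float(np.mean(fold_accs)),
        std=fold_std(fold_accs),
        per_class=per_class,
        per_subject=per_subject,
        confusion=agg.tolist(),
        histories=histories,
        config=cfg)
    if run_dir is not None:
        report.save(run_dir)
    return report


def compare_schedules(config: dict | None = None,
                      kinds=SCHEDULE_KINDS,
                      features: FeatureSet | None = None) -> pd.DataFrame:
    """One (Acc, Std) row per learning-rate policy, same data and seeds."""
    cfg = _merge(default_config(), config or {})
    if features is None:
        recordings = generate_dataset(dataset_spec_from_config(cfg))
        features = featurize_config(cfg, recordings)
    rows = []
    for kind in kinds:
        sub = _merge(cfg, {"train": {"schedule": kind}})
        rep = run_experiment(sub, features=features)
        rows.append({"schedule": kind,
                     "mean_acc_pct": round(rep.mean_acc, 2),
                     "std_pct": round(rep.std, 2),
                     "fold_accuracies": [round(a, 2)
                                         for a in rep.fold_accuracies]})
    return pd.DataFrame(rows)


def export_embeddings(model: FusionModel, features: FeatureSet,
                      out_path) -> pd.DataFrame:
    """Penultimate-layer (fused) features + labels to CSV."""
    if not getattr(model, "trained", False):
        raise InvalidArgumentError("model has not been trained")
    X = features.features.astype(model.dtype)
    emb = model.penultimate_features(X)
    df = pd.DataFrame(emb, columns=[f"f{i}" for i in range(emb.shape[1])])
    df["label"] = [features.class_names[i] for i in features.labels]
    df["subject"] = [str(s) for s in features.subjects]
    df.to_csv(out_path, index=False)
    return df
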