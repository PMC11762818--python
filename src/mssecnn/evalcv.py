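"""Five-fold cross-validated training and the standard metric suite.

Training protocol: minibatch Adam (batch 64, initial learning rate 1e-4),
cross-entropy loss, 250 epochs by default, with an exponential learning-rate
decay applied to the multi-scale variants (mscnn, mssecnn) only.  Metrics:
precision, recall, F1, accuracy from the 0.5-thresholded class-1 probability
(ties go to class 0), and AUC by the rank statistic (tied scores get averaged
ranks).  Folds are either segment-level stratified or subject-level grouped;
the subject scheme guarantees no identity leakage between train and
validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

from .nets import ModelConfig, ModelHandle, build_model

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "MetricsRecord",
    "FoldResult",
    "CVReport",
    "kfold_split",
    "train_model",
    "compute_metrics",
    "crossvalidate",
]


@dataclass
class TrainConfig:
    batch_size: int = 64
    epochs: int = 250
    lr: float = 1e-4
    lr_schedule: str = "none"       # "none" or "exponential"
    lr_gamma: float = 0.99          # per-epoch decay factor when exponential
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("need lr > 0, epochs >= 1, batch_size >= 1")
        if self.lr_schedule not in ("none", "exponential"):
            raise ValueError("lr_schedule must be 'none' or 'exponential'")

    def lr_at(self, epoch: int) -> float:
        """Effective learning rate at a 0-based epoch index."""
        if self.lr_schedule == "exponential":
            return self.lr * self.lr_gamma**epoch
        return self.lr


@dataclass
class MetricsRecord:
    precision: float
    recall: float
    f1: float
    accuracy: float
    auc: float | None
    confusion: dict[str, int]  # tp, fp, fn, tn


@dataclass
class FoldResult:
    fold: int
    train_acc: list[float]
    train_loss: list[float]
    val_acc: list[float]
    val_loss: list[float]
    metrics: MetricsRecord


@dataclass
class CVReport:
    variant: str
    scheme: str
    folds: list[FoldResult]
    mean: dict[str, float]
    std: dict[str, float]
    model_cfg: ModelConfig | None = None
    train_cfg: TrainConfig | None = None

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "scheme": self.scheme,
            "mean": self.mean,
            "std": self.std,
            "folds": [asdict(f) for f in self.folds],
        }
        if self.model_cfg is not None:
            d["model_cfg"] = asdict(self.model_cfg)
        if self.train_cfg is not None:
            d["train_cfg"] = asdict(self.train_cfg)
        return d


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def kfold_split(
    y: np.ndarray,
    k: int = 5,
    scheme: str = "segment",
    seed: int = 0,
    subjects: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Disjoint (train_idx, val_idx) folds covering the dataset.

    scheme "segment": label-stratified shuffled folds over samples.
    scheme "subject": all samples of one subject land in the same fold
    (grouped); requires >= k distinct subjects.
    """
    from sklearn.model_selection import GroupKFold, StratifiedKFold

    y = np.asarray(y)
    if scheme == "segment":
        counts = np.bincount(y)
        if np.any(counts[counts > 0] < k):
            raise ValueError(f"need >= {k} samples per class for stratified folds")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, va) for tr, va in skf.split(np.zeros_like(y), y)]
    if scheme == "subject":
        if subjects is None:
            raise ValueError("subject scheme requires subject ids")
        subjects = np.asarray(subjects)
        if len(np.unique(subjects)) < k:
            raise ValueError(f"need >= {k} distinct subjects for subject folds")
        # shuffle group order deterministically so folds depend on the seed
        rng = np.random.default_rng(seed)
        uniq = rng.permutation(np.unique(subjects))
        remap = {s: i for i, s in enumerate(uniq)}
        groups = np.array([remap[s] for s in subjects])
        gkf = GroupKFold(n_splits=k)
        return [(tr, va) for tr, va in gkf.split(np.zeros_like(y), y, groups=groups)]
    raise ValueError("scheme must be 'segment' or 'subject'")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann–Whitney rank statistic; ties receive averaged ranks."""
    pos = y_true == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5
) -> MetricsRecord:
    """Precision/recall/F1/accuracy at the threshold, plus rank AUC.

    y_prob is the class-1 probability.  Predictions are class 1 iff
    y_prob > threshold (a tied probability of exactly 0.5 predicts class 0).
    AUC is reported as None when only one class is present.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must have equal length")
    y_pred = (y_prob > threshold).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / len(y_true)
    auc = None
    if len(np.unique(y_true)) == 2:
        auc = _rank_auc(y_true, y_prob)
    return MetricsRecord(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        auc=auc,
        confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _xent(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))))


def train_model(
    handle: ModelHandle,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None,
    y_val: np.ndarray | None,
    cfg: TrainConfig,
) -> dict[str, list[float]]:
    """Minibatch Adam training; returns per-epoch train/val accuracy and loss.

    Aborts if the loss becomes non-finite (divergence).
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(y_train)
    opt = _Adam(handle.parameters(), cfg.lr)
    curves: dict[str, list[float]] = {
        "train_acc": [], "train_loss": [], "val_acc": [], "val_loss": []
    }
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        # epoch-level training metrics are running averages over minibatches
        loss_sum = 0.0
        hit_sum = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs = handle.forward(X_train[idx])
            loss = _xent(probs, y_train[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss {loss})"
                )
            loss_sum += loss * len(idx)
            hit_sum += int(np.sum(probs.argmax(1) == y_train[idx]))
            handle.train_step_backward(probs, y_train[idx])
            opt.step(handle.gradients())
        curves["train_loss"].append(loss_sum / n)
        curves["train_acc"].append(hit_sum / n)
        if X_val is not None and len(X_val):
            p_va = handle.forward(X_val)
            curves["val_loss"].append(_xent(p_va, y_val))
            curves["val_acc"].append(float(np.mean(p_va.argmax(1) == y_val)))
    return curves


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

_METRICS = ("precision", "recall", "f1", "accuracy", "auc")


def crossvalidate(
    X: np.ndarray,
    y: np.ndarray,
    variant: str = "mssecnn",
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    k: int = 5,
    scheme: str = "segment",
    subjects: np.ndarray | None = None,
    seed: int = 0,
    normalize: bool = False,
) -> CVReport:
    """k-fold CV of one classifier variant on stacked feature tensors (N,H,W,C).

    The exponential learning-rate schedule is enabled automatically for the
    multi-scale variants when train_cfg does not request a schedule
    explicitly.  normalize=True applies a per-tensor z-score before training
    (speeds convergence of Adam at the default learning rate; off by default —
    the SE block provides adaptive scaling).
    """
    X = np.asarray(X, dtype=np.float64)
    if normalize:
        mu = X.mean(axis=(1, 2, 3), keepdims=True)
        sd = X.std(axis=(1, 2, 3), keepdims=True)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
    y = np.asarray(y, dtype=int)
    if model_cfg is None:
        model_cfg = ModelConfig(
            variant=variant, input_hw=X.shape[1:3], in_channels=X.shape[3]
        )
    if train_cfg is None:
        train_cfg = TrainConfig()
        if variant in ("mscnn", "mssecnn"):
            train_cfg.lr_schedule = "exponential"
    folds = kfold_split(y, k=k, scheme=scheme, seed=seed, subjects=subjects)
    results: list[FoldResult] = []
    for fi, (tr, va) in enumerate(folds):
        if scheme == "subject":
            assert subjects is not None
            assert not set(np.asarray(subjects)[tr]) & set(np.asarray(subjects)[va]), (
                "subject leakage between train and validation"
            )
        handle = build_model(model_cfg, seed=seed * 1000 + fi)
        fold_train_cfg = TrainConfig(**{**asdict(train_cfg), "seed": seed * 1000 + fi})
        curves = train_model(handle, X[tr], y[tr], X[va], y[va], fold_train_cfg)
        probs = handle.forward(X[va])[:, 1]
        rec = compute_metrics(y[va], probs)
        results.append(
            FoldResult(
                fold=fi,
                train_acc=curves["train_acc"],
                train_loss=curves["train_loss"],
                val_acc=curves["val_acc"],
                val_loss=curves["val_loss"],
                metrics=rec,
            )
        )
        logger.info(
            "%s fold %d: acc=%.3f auc=%s", variant, fi, rec.accuracy, rec.auc
        )
    mean, std = {}, {}
    for m in _METRICS:
        vals = [getattr(f.metrics, m) for f in results]
        vals = [v for v in vals if v is not None]
        mean[m] = float(np.mean(vals)) if vals else float("nan")
        std[m] = float(np.std(vals)) if vals else float("nan")
    return CVReport(
        variant=variant,
        scheme=scheme,
        folds=results,
        mean=mean,
        std=std,
        model_cfg=model_cfg,
        train_cfg=train_cfg,
    )


def mean_curves(report: CVReport) -> dict[str, np.ndarray]:
    """Across-fold average of the per-epoch accuracy/loss curves."""
    out = {}
    for key in ("train_acc", "train_loss", "val_acc", "val_loss"):
        arrs = [np.asarray(getattr(f, key)) for f in report.folds]
        out[key] = np.mean(arrs, axis=0)
    return out
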