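"""Time-reversal self-supervised pretraining.

The pretext task doubles the corpus — every subject appears once in original
temporal order (y = 0) and once reversed (y = 1) — and trains the model to
classify direction.  Both copies of a subject always land on the same side of
any cross-validation split, since folds are assigned by subject.

The training loop (Adam, batch size 32, learning rate 7e-4, early stopping on
validation loss with patience 50 and minimum delta 1e-4 by default) is shared
with downstream fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from ._autodiff import Adam, Tensor
from .core_io import CohortDataset, TimeCourse, prepare_model_inputs
from .model import HierarchicalAttentionNet, ModelConfig, save_checkpoint

__all__ = [
    "TRSample",
    "TrainSpec",
    "EarlyStopper",
    "reverse_time",
    "tr_augment",
    "tr_loss",
    "softmax_probs",
    "fit_model",
    "run_pretraining",
    "FoldResult",
]

_CLAMP = 1e-7


@dataclass
class TRSample:
    """One pretext-task sample: a series and its direction label (1 = reversed)."""

    series: TimeCourse
    y: int


@dataclass
class TrainSpec:
    """Optimization settings; defaults follow the reference training recipe."""

    batch_size: int = 32
    learning_rate: float = 7e-4
    patience: int = 50
    min_delta: float = 1e-4
    max_epochs: int = 200
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self):
        if min(self.batch_size, self.patience, self.max_epochs) < 1:
            raise ValueError("batch_size, patience and max_epochs must be >= 1")
        if self.learning_rate <= 0 or self.min_delta < 0:
            raise ValueError("learning_rate must be > 0 and min_delta >= 0")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")


class EarlyStopper:
    """Stop when no validation improvement of at least min_delta for `patience` epochs.

    An improvement means the monitored loss undercuts the best seen value by
    min_delta or more; training halts at the first epoch ending a full
    patience-length stretch without one.
    """

    def __init__(self, patience: int, min_delta: float):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.stale = 0

    def update(self, loss: float) -> bool:
        """Record an epoch's validation loss; return True if training should stop."""
        if self.best - loss >= self.min_delta:
            self.best = loss
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def reverse_time(tc: TimeCourse) -> TimeCourse:
    """Reverse the temporal order of a time course; components untouched."""
    return TimeCourse(values=tc.values[::-1].copy(), subject_id=tc.subject_id)


def tr_augment(ds: CohortDataset, seed: int) -> list[TRSample]:
    """Original (y=0) plus reversed (y=1) copy of every subject, shuffled by seed."""
    samples = [TRSample(tc, 0) for tc in ds.subjects]
    samples += [TRSample(reverse_time(tc), 1) for tc in ds.subjects]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    return [samples[i] for i in order]


def tr_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of predicted reversal probabilities.

    `probs` is the model's probability that each input is time-reversed;
    probabilities are clamped to (1e-7, 1 - 1e-7) before the log.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if np.setdiff1d(np.unique(labels), [0, 1]).size:
        raise ValueError("labels must be binary (0/1)")
    p = np.clip(probs, _CLAMP, 1.0 - _CLAMP)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1.0 - p)))


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Class probabilities from logits; column 1 is the positive class."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _xent(logits_t: Tensor, y: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy against integer labels (graph op)."""
    n = logits_t.shape[0]
    m = Tensor(logits_t.data.max(axis=1, keepdims=True))
    z = logits_t - m
    lse = z.exp().sum(axis=1, keepdims=True).log()
    logp = z - lse
    return -logp[np.arange(n), np.asarray(y)].mean()


@dataclass
class FitResult:
    best_epoch: int
    best_val_loss: float
    val_auc: float
    history: list[dict] = field(default_factory=list)


def _evaluate(model: HierarchicalAttentionNet, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> tuple[float, np.ndarray]:
    probs = []
    for i in range(0, len(x), batch_size):
        out = model.forward(x[i: i + batch_size])
        probs.append(softmax_probs(out.logits)[:, 1])
    p = np.concatenate(probs)
    return tr_loss(p, y), p


def fit_model(model: HierarchicalAttentionNet, x_train: np.ndarray, y_train: np.ndarray,
              x_val: np.ndarray, y_val: np.ndarray, spec: TrainSpec,
              freeze_prefixes: tuple[str, ...] = ()) -> FitResult:
    """Train with Adam + early stopping on validation loss; restores the best state.

    Parameters whose names start with any of ``freeze_prefixes`` (e.g.
    ``("enc.", "attn_win.")`` to freeze the encoder stage) are excluded from
    optimization.
    """
    from .finetune import auc  # local import to avoid a cycle

    trainable = [p for k, p in model.params.items()
                 if not any(k.startswith(f) for f in freeze_prefixes)]
    opt = Adam(trainable, lr=spec.learning_rate)
    stopper = EarlyStopper(spec.patience, spec.min_delta)
    rng = np.random.default_rng(spec.seed)
    best_state = model.state_dict()
    best_loss = np.inf
    best_epoch = -1
    history: list[dict] = []
    n = len(x_train)
    for epoch in range(spec.max_epochs):
        order = rng.permutation(n)
        train_loss = 0.0
        for i in range(0, n, spec.batch_size):
            idx = order[i: i + spec.batch_size]
            out = model.forward(x_train[idx])
            loss = _xent(out.logits_t, y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_loss += float(loss.data) * len(idx)
        val_loss, _ = _evaluate(model, x_val, y_val, spec.batch_size)
        history.append({"epoch": epoch, "train_loss": train_loss / n, "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
        if stopper.update(val_loss):
            break
    model.load_state_dict(best_state)
    _, p = _evaluate(model, x_val, y_val, spec.batch_size)
    val_auc = auc(p, y_val) if len(np.unique(y_val)) == 2 else float("nan")
    return FitResult(best_epoch=best_epoch, best_val_loss=best_loss,
                     val_auc=val_auc, history=history)


def _augmented_arrays(ds: CohortDataset, idx: np.ndarray, seed: int,
                      scaler: tuple[np.ndarray, np.ndarray] | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Standardized (2n, T, C) array of original+reversed copies with labels.

    Standardization is cohort-level per-component z-scoring; reversal leaves
    the pooled moments unchanged, so augmenting and standardizing commute.
    A scaler fit on the training side should be passed for validation data.
    """
    from .core_io import cohort_scaler

    sub = ds.subset(idx)
    samples = tr_augment(sub, seed)
    x = np.stack([s.series.values for s in samples])
    if scaler is None:
        scaler = cohort_scaler(x)
    mu, sd = scaler
    x = (x - mu) / sd
    y = np.array([s.y for s in samples], dtype=np.int64)
    return x, y, scaler


@dataclass
class FoldResult:
    fold: int
    best_epoch: int
    val_loss: float
    val_auc: float
    model: HierarchicalAttentionNet


def run_pretraining(corpus: CohortDataset, cfg: ModelConfig, spec: TrainSpec,
                    n_folds: int = 5, out_dir: str | Path | None = None) -> list[FoldResult]:
    """Five-fold pretraining: each fold trains on 4/5 of the subjects and early
    stops on the held-out fifth, yielding one checkpoint per fold.

    Fold assignment is by subject, so a subject's original and reversed copies
    never straddle a split.
    """
    if len(corpus) < n_folds:
        raise ValueError(f"corpus of {len(corpus)} subjects cannot form {n_folds} folds")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    results: list[FoldResult] = []
    for fold, (tr_idx, va_idx) in enumerate(kf.split(np.arange(len(corpus)))):
        x_tr, y_tr, scaler = _augmented_arrays(corpus, tr_idx, seed=spec.seed + fold)
        x_va, y_va, _ = _augmented_arrays(corpus, va_idx, seed=spec.seed + fold + 1000,
                                          scaler=scaler)
        model = HierarchicalAttentionNet(cfg, seed=spec.seed + fold)
        fit = fit_model(model, x_tr, y_tr, x_va, y_va, spec)
        results.append(FoldResult(fold, fit.best_epoch, fit.best_val_loss, fit.val_auc, model))
        if out_dir is not None:
            save_checkpoint(model, Path(out_dir) / f"pretrain_fold{fold}.ckpt")
    if out_dir is not None:
        pd.DataFrame(
            [
                {"fold": r.fold, "best_epoch": r.best_epoch,
                 "val_loss": r.val_loss, "val_auc": r.val_auc}
                for r in results
            ]
        ).to_csv(Path(out_dir) / "pretrain_metrics.csv", index=False)
    return results
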