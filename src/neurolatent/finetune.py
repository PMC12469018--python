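"""Transfer to case/control classification and the evaluation grid.

Pretrained encoder/attention/recurrence weights are copied into a fresh model
whose decoder is re-initialized for the diagnostic task; a scratch mode skips
the copy entirely (the non-pretrained baseline arm).  The full evaluation
protocol crosses pretraining checkpoints x stratified downstream folds x
random seeds (5 x 5 x 4 = 100 cells at reference scale); each cell fine-tunes
on the training side, records the held-out AUC, and exports held-out latents
with their attention records for probing.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .core_io import CohortDataset, cohort_scaler, prepare_model_inputs
from .model import AttentionRecord, HierarchicalAttentionNet, ModelConfig
from .pretrain import FoldResult, TrainSpec, fit_model, softmax_probs

__all__ = [
    "ExperimentGrid",
    "LatentMatrix",
    "CellResult",
    "OOFResult",
    "enumerate_grid",
    "transfer_weights",
    "auc",
    "run_cell",
    "run_oof_cell",
    "run_grid",
]


@dataclass
class ExperimentGrid:
    """The checkpoint x fold x seed Cartesian product, in lexicographic order."""

    n_checkpoints: int = 5
    n_folds: int = 5
    n_seeds: int = 4
    cells: list[tuple[int, int, int]] = field(init=False)

    def __post_init__(self):
        if min(self.n_checkpoints, self.n_folds, self.n_seeds) < 1:
            raise ValueError("grid dimensions must be positive")
        self.cells = list(
            product(range(self.n_checkpoints), range(self.n_folds), range(self.n_seeds))
        )

    def __len__(self) -> int:
        return len(self.cells)


def enumerate_grid(n_ckpt: int, n_folds: int, n_seeds: int) -> ExperimentGrid:
    return ExperimentGrid(n_ckpt, n_folds, n_seeds)


@dataclass
class LatentMatrix:
    """Subject latents (rows) with labels and provenance; columns = D_main."""

    values: np.ndarray               # (n_subjects, D_main)
    labels: np.ndarray
    provenance: dict
    attention: list[AttentionRecord] = field(default_factory=list)

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite latent values")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("latent/label row mismatch")


def transfer_weights(checkpoint_model: HierarchicalAttentionNet | None,
                     cfg: ModelConfig, seed: int,
                     scratch: bool = False) -> HierarchicalAttentionNet:
    """Build the downstream model: pretrained weights minus the decoder.

    With ``scratch=True`` (or no checkpoint) the model is a fresh seeded
    initialization — the non-pretrained baseline.
    """
    model = HierarchicalAttentionNet(cfg, seed=seed)
    if scratch or checkpoint_model is None:
        return model
    if checkpoint_model.cfg != cfg:
        raise ValueError(
            f"checkpoint config {checkpoint_model.cfg} does not match target {cfg}"
        )
    model.load_state_dict(checkpoint_model.state_dict(), skip=("dec.",))
    model.reinit_decoder(seed)
    return model


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation.

    The probability that a uniformly chosen positive outranks a uniformly
    chosen negative, counting score ties as one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    r = rankdata(scores)
    u = r[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class CellResult:
    checkpoint_id: int
    fold_id: int
    seed: int
    test_auc: float
    best_epoch: int
    latents: LatentMatrix
    model: "HierarchicalAttentionNet | None" = None


def _latents_for(model: HierarchicalAttentionNet, x: np.ndarray, labels: np.ndarray,
                 provenance: dict, batch_size: int = 32) -> LatentMatrix:
    vals, recs = [], []
    for i in range(0, len(x), batch_size):
        out = model.forward(x[i: i + batch_size])
        vals.append(out.latent)
        recs.extend(out.attention)
    return LatentMatrix(np.concatenate(vals), np.asarray(labels), provenance, recs)


def run_cell(ds: CohortDataset, cfg: ModelConfig, spec: TrainSpec,
             checkpoint: HierarchicalAttentionNet | None,
             checkpoint_id: int, fold_id: int, seed: int,
             n_folds: int = 5, scratch: bool = False) -> CellResult:
    """One grid cell: stratified split, fine-tune, held-out AUC + latents."""
    raw = prepare_model_inputs(ds, standardize=None)
    y = np.asarray(ds.labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=spec.seed)
    splits = list(skf.split(raw, y))
    tr_idx, te_idx = splits[fold_id]
    mu, sd = cohort_scaler(raw[tr_idx])  # scaling statistics from training subjects only
    x = (raw - mu) / sd
    # inner early-stopping split carved out of the training side
    tr_in, va_in = train_test_split(
        tr_idx, test_size=spec.val_fraction, stratify=y[tr_idx], random_state=seed
    )
    cell_spec = TrainSpec(**{**spec.__dict__, "seed": seed})
    model = transfer_weights(checkpoint, cfg, seed=seed + 7919 * (checkpoint_id + 1),
                             scratch=scratch)
    fit = fit_model(model, x[tr_in], y[tr_in], x[va_in], y[va_in], cell_spec)
    probs = []
    for i in range(0, len(te_idx), spec.batch_size):
        out = model.forward(x[te_idx][i: i + spec.batch_size])
        probs.append(softmax_probs(out.logits)[:, 1])
    p_test = np.concatenate(probs)
    provenance = {
        "checkpoint_id": checkpoint_id, "fold_id": fold_id,
        "seed": seed, "split": "held-out", "scratch": scratch,
        "cohort_id": ds.cohort_id,
    }
    latents = _latents_for(model, x[te_idx], y[te_idx], provenance, spec.batch_size)
    return CellResult(checkpoint_id, fold_id, seed, auc(p_test, y[te_idx]),
                      fit.best_epoch, latents, model)


@dataclass
class OOFResult:
    """Out-of-fold evaluation: pooled held-out latents covering the cohort.

    Every subject's latent comes from the fold model that did not train on
    it, so the pooled matrix is leakage-free and spans the whole cohort —
    large enough for a meaningful probe even at desk scale.
    """

    latents: LatentMatrix                  # pooled, in original subject order
    fold_models: list[HierarchicalAttentionNet]
    fold_of: np.ndarray                    # (n_subjects,) fold index per subject
    fold_aucs: list[float]

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def run_oof_cell(ds: CohortDataset, cfg: ModelConfig, spec: TrainSpec,
                 checkpoint: HierarchicalAttentionNet | None, seed: int,
                 n_folds: int = 2, scratch: bool = False,
                 provenance: dict | None = None) -> OOFResult:
    """Cross-fitting for probing: fine-tune per fold, collect each fold's
    held-out latents/attention, and pool them over the cohort."""
    raw = prepare_model_inputs(ds, standardize=None)
    y = np.asarray(ds.labels)
    n = len(y)
    latents = np.empty((n, cfg.D_main))
    attention: list[AttentionRecord | None] = [None] * n
    fold_of = np.empty(n, dtype=int)
    models, aucs = [], []
    # runs on different cohorts are independent experiments: weight
    # initialization must not be shared across cohorts (only the pretrained
    # checkpoint, when present, is a deliberate shared anchor)
    cohort_salt = zlib.crc32(ds.cohort_id.encode()) % 100003
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for fold, (tr_idx, te_idx) in enumerate(skf.split(raw, y)):
        mu, sd = cohort_scaler(raw[tr_idx])
        x = (raw - mu) / sd
        tr_in, va_in = train_test_split(
            tr_idx, test_size=spec.val_fraction, stratify=y[tr_idx],
            random_state=seed + fold,
        )
        model = transfer_weights(checkpoint, cfg,
                                 seed=seed + 101 * (fold + 1) + cohort_salt,
                                 scratch=scratch)
        fold_spec = TrainSpec(**{**spec.__dict__, "seed": seed + fold})
        fit_model(model, x[tr_in], y[tr_in], x[va_in], y[va_in], fold_spec)
        probs = []
        for i in range(0, len(te_idx), spec.batch_size):
            out = model.forward(x[te_idx][i: i + spec.batch_size])
            latents[te_idx[i: i + spec.batch_size]] = out.latent
            for j, rec in enumerate(out.attention):
                attention[te_idx[i + j]] = rec
            probs.append(softmax_probs(out.logits)[:, 1])
        aucs.append(auc(np.concatenate(probs), y[te_idx]))
        fold_of[te_idx] = fold
        models.append(model)
    prov = {"seed": seed, "split": "out-of-fold", "scratch": scratch,
            "cohort_id": ds.cohort_id, **(provenance or {})}
    lm = LatentMatrix(latents, y, prov, attention)  # type: ignore[arg-type]
    return OOFResult(lm, models, fold_of, aucs)


def run_grid(ds: CohortDataset, grid: ExperimentGrid, cfg: ModelConfig, spec: TrainSpec,
             checkpoints: list[HierarchicalAttentionNet] | None,
             scratch: bool = False) -> list[CellResult]:
    """Run every grid cell.  `checkpoints` indexes checkpoint_id; latents come
    exclusively from held-out subjects of each fold (no leakage into probing)."""
    if not scratch:
        if checkpoints is None or len(checkpoints) < grid.n_checkpoints:
            raise ValueError("need one pretrained checkpoint per grid row")
    results = []
    for ck, fold, seed in grid.cells:
        checkpoint = None if scratch else checkpoints[ck]
        results.append(
            run_cell(ds, cfg, spec, checkpoint, ck, fold, seed,
                     n_folds=grid.n_folds, scratch=scratch)
        )
    return results
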