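"""Probing and attribution: from latent features back to brain networks.

The chain has three links:

1. a linear logistic-regression probe on the frozen latents quantifies each
   feature's class association;
2. the attention-weighted component-to-latent mapping M (D_main x C)
   propagates those coefficients from latent features to input components,
   scaling the main-LSTM weight view by global attention and the encoder
   weight view by window-level attention and accumulating over windows and
   time steps;
3. the component->network assignment averages component scores into the seven
   functional networks.

Sign convention: the probe's positive class is the *patient* group, so a
positive coefficient marks a pathology-associated feature.  A network whose
activity is suppressed in patients therefore receives a negative importance
score (its tracking features are weaker in patients), and an enhanced network
a positive one.  The opposite ("control-positive") coding is available via
``positive_class``; it negates every coefficient and score.

When both attention arrays are probability vectors — which the model
guarantees — the double accumulation collapses algebraically to
M = W_main @ W_enc, because sum_k alpha_global[k] * sum_t alpha_win[k,t] = 1.
Subject-level attention then carries no information into M; the
``"score"`` mapping variant uses the raw (pre-softmax) attention scores
instead, preserving attention dependence as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .core_io import NETWORK_NAMES, NetworkMap
from .finetune import LatentMatrix, auc
from .model import AttentionRecord, HierarchicalAttentionNet, extract_weight_views

__all__ = [
    "ProbeResult",
    "MappingMatrix",
    "NetworkImportance",
    "fit_probe",
    "component_to_latent_mapping",
    "subject_mapping",
    "network_importance",
    "cell_network_importance",
    "oof_network_importance",
    "aggregate_importance",
    "cross_cohort_consistency",
]


@dataclass
class ProbeResult:
    beta: np.ndarray          # (D_main,) mean over probe folds
    intercept: float
    fold_betas: np.ndarray    # (n_folds, D_main)
    probe_auc: float
    positive_class: str


@dataclass
class MappingMatrix:
    M: np.ndarray             # (D_main, C)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.M)):
            raise ValueError("non-finite mapping matrix")


@dataclass
class NetworkImportance:
    scores: pd.Series         # per-network weighted mean coefficient
    dispersion: pd.Series     # per-network sd (across probe folds or grid cells)
    per_component: np.ndarray # (C,)


def fit_probe(latents: LatentMatrix, n_folds: int = 5, C_reg: float = 1.0,
              positive_class: str = "patient", seed: int = 0,
              feature_mask: np.ndarray | None = None) -> ProbeResult:
    """L2 logistic regression on z-scored latents with internal stratified CV.

    Coefficients are averaged over the folds; the probe AUC pools held-out
    decision scores.  ``positive_class`` chooses which group the positive
    coefficients point to.  ``feature_mask`` (boolean, per latent dimension)
    optionally restricts the probe to e.g. statistically significant features;
    masked-out dimensions receive zero coefficients.  The default probes all
    dimensions.
    """
    if positive_class not in ("patient", "control"):
        raise ValueError("positive_class must be 'patient' or 'control'")
    labels = np.asarray(latents.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("probe requires both classes")
    y = (labels == 0).astype(int) if positive_class == "patient" else (labels == 1).astype(int)
    x = latents.values
    n_all = x.shape[1]
    if feature_mask is not None:
        feature_mask = np.asarray(feature_mask, dtype=bool)
        if feature_mask.shape != (n_all,):
            raise ValueError("feature_mask length must equal the latent dimension")
        if not feature_mask.any():
            raise ValueError("feature_mask excludes every feature")
        x = x[:, feature_mask]
    mu, sd = x.mean(axis=0), x.std(axis=0)
    xz = (x - mu) / np.where(sd > 0, sd, 1.0)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    betas, intercepts = [], []
    scores = np.empty(len(y))
    for tr, te in skf.split(xz, y):
        clf = LogisticRegression(C=C_reg, max_iter=2000)
        clf.fit(xz[tr], y[tr])
        betas.append(clf.coef_[0])
        intercepts.append(clf.intercept_[0])
        scores[te] = clf.decision_function(xz[te])
    fold_betas = np.stack(betas)
    if feature_mask is not None:
        full = np.zeros((fold_betas.shape[0], n_all))
        full[:, feature_mask] = fold_betas
        fold_betas = full
    return ProbeResult(
        beta=fold_betas.mean(axis=0),
        intercept=float(np.mean(intercepts)),
        fold_betas=fold_betas,
        probe_auc=auc(scores, y),
        positive_class=positive_class,
    )


def component_to_latent_mapping(W_enc: np.ndarray, W_main: np.ndarray,
                                alpha_win: np.ndarray,
                                alpha_global: np.ndarray) -> MappingMatrix:
    """Attention-weighted accumulation M = sum_k sum_t
    (alpha_global[k] * W_main) @ (alpha_win[k,t] * W_enc).

    Since every term is the same matrix product scaled by a scalar, the double
    sum equals (sum_k alpha_global[k] * sum_t alpha_win[k,t]) * W_main @ W_enc;
    the vectorized form computes exactly that.
    """
    W_enc = np.asarray(W_enc, dtype=np.float64)
    W_main = np.asarray(W_main, dtype=np.float64)
    alpha_win = np.atleast_2d(np.asarray(alpha_win, dtype=np.float64))
    alpha_global = np.asarray(alpha_global, dtype=np.float64).ravel()
    d_main, d_enc = W_main.shape
    if W_enc.shape[0] != d_enc:
        raise ValueError(f"W_main {W_main.shape} and W_enc {W_enc.shape} are not conformable")
    if alpha_win.shape[0] != alpha_global.shape[0]:
        raise ValueError(
            f"alpha_win has {alpha_win.shape[0]} windows, alpha_global {alpha_global.shape[0]}"
        )
    scale = float(alpha_global @ alpha_win.sum(axis=1))
    return MappingMatrix(M=scale * (W_main @ W_enc))


def subject_mapping(model: HierarchicalAttentionNet,
                    attention: list[AttentionRecord],
                    mapping: str = "normalized",
                    reduction: str = "cell-gate") -> MappingMatrix:
    """Element-wise mean of per-subject mapping matrices over a subject set.

    ``mapping="normalized"`` uses the softmax attention weights (the faithful
    default, which collapses to W_main @ W_enc); ``"score"`` uses the raw
    attention scores, retaining per-subject attention dependence.
    """
    if not attention:
        raise ValueError("empty subject set")
    if mapping not in ("normalized", "score"):
        raise ValueError("mapping must be 'normalized' or 'score'")
    w_enc, w_main = extract_weight_views(model, reduction=reduction)
    mats = []
    for rec in attention:
        if mapping == "normalized":
            aw, ag = rec.alpha_win, rec.alpha_global
        else:
            aw, ag = rec.score_win, rec.score_global
        mats.append(component_to_latent_mapping(w_enc, w_main, aw, ag).M)
    return MappingMatrix(
        M=np.mean(mats, axis=0),
        provenance={"n_subjects": len(attention), "mapping": mapping, "reduction": reduction},
    )


def network_importance(probe: ProbeResult, mapping: MappingMatrix,
                       net_map: NetworkMap) -> NetworkImportance:
    """Propagate probe coefficients through M and average within networks.

    per_component[c] = sum_f beta[f] * M[f, c]; a network's score is the mean
    of its components' scores, and the dispersion is the sd of that score
    recomputed per probe fold.
    """
    d_main, c = mapping.M.shape
    if net_map.n_components != c:
        raise ValueError(
            f"network map covers {net_map.n_components} components, mapping has {c}"
        )
    if probe.beta.shape[0] != d_main:
        raise ValueError("probe coefficient length does not match mapping rows")
    per_component = probe.beta @ mapping.M
    per_fold = probe.fold_betas @ mapping.M  # (n_folds, C)
    networks = net_map.networks
    scores, disp = {}, {}
    for net in networks:
        comps = net_map.components_of(net)
        scores[net] = float(per_component[comps].mean())
        disp[net] = float(per_fold[:, comps].mean(axis=1).std())
    return NetworkImportance(
        scores=pd.Series(scores, index=list(networks)),
        dispersion=pd.Series(disp, index=list(networks)),
        per_component=per_component,
    )


def cell_network_importance(model: HierarchicalAttentionNet, latents: LatentMatrix,
                            net_map: NetworkMap, mapping: str = "normalized",
                            positive_class: str = "patient",
                            seed: int = 0) -> NetworkImportance:
    """Probe one grid cell's latents and attribute the coefficients to networks."""
    probe = fit_probe(latents, positive_class=positive_class, seed=seed)
    m = subject_mapping(model, latents.attention, mapping=mapping)
    return network_importance(probe, m, net_map)


def oof_network_importance(oof, net_map: NetworkMap, mapping: str = "normalized",
                           reduction: str = "cell-gate",
                           positive_class: str = "patient",
                           seed: int = 0) -> NetworkImportance:
    """Probe pooled out-of-fold latents and attribute through the fold models.

    The probe sees every subject exactly once (scored by the model that did
    not train on it); the mapping matrix is the subject-count-weighted mean of
    each fold model's subject-aggregated mapping.
    """
    probe = fit_probe(oof.latents, positive_class=positive_class, seed=seed)
    mats, weights = [], []
    recs = oof.latents.attention
    for fold, model in enumerate(oof.fold_models):
        fold_recs = [r for r, f in zip(recs, oof.fold_of) if f == fold]
        if not fold_recs:
            continue
        mats.append(subject_mapping(model, fold_recs, mapping=mapping,
                                    reduction=reduction).M)
        weights.append(len(fold_recs))
    m = MappingMatrix(
        M=np.average(mats, axis=0, weights=weights),
        provenance={"mapping": mapping, "reduction": reduction,
                    "n_folds": len(oof.fold_models)},
    )
    return network_importance(probe, m, net_map)


def aggregate_importance(importances: list[NetworkImportance]) -> pd.DataFrame:
    """Mean and sd of network scores across grid cells."""
    if not importances:
        raise ValueError("nothing to aggregate")
    frame = pd.DataFrame([imp.scores for imp in importances])
    return pd.DataFrame(
        {
            "network": frame.columns,
            "mean": frame.mean(axis=0).to_numpy(),
            "sd": frame.std(axis=0, ddof=1).to_numpy() if len(frame) > 1 else 0.0,
            "n_cells": len(frame),
        }
    )


def cross_cohort_consistency(imp_a: NetworkImportance | pd.Series,
                             imp_b: NetworkImportance | pd.Series) -> float:
    """Pearson correlation of two cohorts' network-score vectors."""
    a = imp_a.scores if isinstance(imp_a, NetworkImportance) else imp_a
    b = imp_b.scores if isinstance(imp_b, NetworkImportance) else imp_b
    if list(a.index) != list(b.index):
        raise ValueError("network sets/orders differ between cohorts")
    av, bv = a.to_numpy(), b.to_numpy()
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("Pearson correlation undefined for zero-variance scores")
    return float(pearsonr(av, bv).statistic)
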