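"""Mahalanobis-distance cohort balancing.

Severely imbalanced case/control cohorts are balanced by keeping only the k
healthy controls whose functional profiles most resemble the patient group.
Each subject is embedded as the time average of its component time courses (a
C-vector of mean activity); the patient group defines a distribution via its
embedding mean and (ridge-regularized) covariance, and every control is scored
by its Mahalanobis distance to that distribution.  Patients always pass
through unchanged; the k nearest controls are kept and the combined cohort is
re-shuffled with a seed.

Shipped retention presets mirror the reference clinical settings: 100 controls
for the 433/66 profile, 261 for the 651/172 profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CohortDataset, TimeCourse

__all__ = [
    "SubjectEmbedding",
    "BalancingResult",
    "RETENTION_PRESETS",
    "embed_subject",
    "mahalanobis",
    "patient_distribution",
    "balance_cohort",
]

#: Retained-control counts for the two reference imbalance profiles.
RETENTION_PRESETS = {"adni": 100, "oasis": 261}

_RIDGE_SCALE = 1e-3  # lambda = scale * trace(cov) / C added to the diagonal


@dataclass
class SubjectEmbedding:
    """Time-averaged component activity (C-vector)."""

    vector: np.ndarray
    subject_id: str


@dataclass
class BalancingResult:
    kept_hc_ids: list[str]      # ascending distance order
    distances: pd.DataFrame     # columns subject_id, distance for every HC
    k: int


def embed_subject(tc: TimeCourse) -> SubjectEmbedding:
    """Average the time series across time points -> one value per component."""
    return SubjectEmbedding(vector=tc.values.mean(axis=0), subject_id=tc.subject_id)


def _regularized_cov(x: np.ndarray) -> np.ndarray:
    cov = np.cov(x, rowvar=False)
    c = cov.shape[0]
    lam = _RIDGE_SCALE * np.trace(cov) / c
    return cov + lam * np.eye(c)


def patient_distribution(ds: CohortDataset,
                         diagonal: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Mean and ridge-regularized covariance of the patient embeddings.

    ``diagonal=True`` keeps only the per-component variances — more stable
    when patients are few relative to the number of components.
    """
    pat = [embed_subject(tc).vector for tc, y in zip(ds.subjects, ds.labels) if y == 0]
    if len(pat) < 2:
        raise ValueError("need at least 2 patients to define a covariance")
    x = np.stack(pat)
    cov = _regularized_cov(x)
    if diagonal:
        cov = np.diag(np.diag(cov))
    return x.mean(axis=0), cov


def mahalanobis(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """sqrt((x-mu)^T cov^-1 (x-mu)); cov must be symmetric positive definite."""
    x = np.asarray(x, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance not positive definite after regularization") from exc
    d = np.linalg.solve(chol, x - mu)
    return float(np.sqrt(d @ d))


def balance_cohort(ds: CohortDataset, k: int, seed: int = 0,
                   diagonal: bool = False) -> tuple[BalancingResult, CohortDataset]:
    """Keep the k controls nearest (Mahalanobis) to the patient distribution.

    Ties in distance break by subject id; output subject order is a seeded
    shuffle of all patients plus the kept controls.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels = np.asarray(ds.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("cohort must contain both classes")
    mu, cov = patient_distribution(ds, diagonal=diagonal)
    hc_idx = np.flatnonzero(labels == 1)
    dist = np.array([mahalanobis(embed_subject(ds.subjects[i]).vector, mu, cov) for i in hc_idx])
    ids = [ds.subjects[i].subject_id for i in hc_idx]
    order = sorted(range(len(hc_idx)), key=lambda j: (dist[j], ids[j]))
    keep = order[: min(k, len(hc_idx))]
    kept_ids = [ids[j] for j in keep]

    pat_idx = np.flatnonzero(labels == 0)
    selected = np.concatenate([pat_idx, hc_idx[keep]])
    rng = np.random.default_rng(seed)
    selected = selected[rng.permutation(len(selected))]
    balanced = ds.subset(selected)
    result = BalancingResult(
        kept_hc_ids=kept_ids,
        distances=pd.DataFrame({"subject_id": ids, "distance": dist}),
        k=min(k, len(hc_idx)),
    )
    return result, balanced
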