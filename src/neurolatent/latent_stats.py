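"""Statistical validation of latent features.

Per-feature one-sample t-tests (does the feature deviate from zero at all?)
and two-sample Welch t-tests (does it separate patients from controls?), each
followed by Benjamini-Hochberg FDR adjustment and a count of features
significant at q < 0.05.  The Welch variant is used because the planted
effects (and real pathology) produce variance heterogeneity between groups;
Benjamini-Yekutieli is available for dependence-robust adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .finetune import LatentMatrix

__all__ = [
    "StatReport",
    "one_sample_test",
    "two_sample_test",
    "fdr_adjust",
    "count_significant",
    "latent_stat_report",
]


@dataclass
class StatReport:
    n_features: int
    p_one: np.ndarray
    p_two: np.ndarray
    q_one: np.ndarray
    q_two: np.ndarray
    n_sig_one: int
    n_sig_two: int
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": np.arange(self.n_features),
                "p_one_sample": self.p_one,
                "q_one_sample": self.q_one,
                "p_two_sample": self.p_two,
                "q_two_sample": self.q_two,
            }
        )

    def summary_row(self) -> dict:
        """Mirrors the significance-count table: total / one-sample / two-sample."""
        return {
            "total_features": self.n_features,
            "one_sample_significant": self.n_sig_one,
            "two_sample_significant": self.n_sig_two,
        }


def one_sample_test(latents: LatentMatrix) -> np.ndarray:
    """Two-sided one-sample t-test of each latent feature against zero.

    Zero-variance columns are degenerate: p is set to 1 when the column mean
    is 0 (no evidence either way) and to 0 when a constant nonzero value is
    the infinitely strong signal limit.
    """
    x = latents.values
    if x.shape[0] < 2:
        raise ValueError("one-sample test needs at least 2 subjects")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_1samp(x, popmean=0.0, axis=0)
    var = x.var(axis=0)
    degenerate = var == 0
    if degenerate.any():
        means = x.mean(axis=0)
        p = np.where(degenerate, np.where(means == 0, 1.0, 0.0), p)
    return np.asarray(p, dtype=np.float64)


def two_sample_test(latents: LatentMatrix) -> np.ndarray:
    """Two-sided Welch t-test (patients vs controls) per latent feature."""
    y = np.asarray(latents.labels)
    a = latents.values[y == 1]  # controls
    b = latents.values[y == 0]  # patients
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two-sample test needs >= 2 subjects per class")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # both groups constant and equal
    return np.asarray(p, dtype=np.float64)


def fdr_adjust(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Step-up FDR-adjusted p-values (Benjamini-Hochberg, or "by" for
    Benjamini-Yekutieli), monotone in the sorted order and capped at 1."""
    p = np.asarray(p, dtype=np.float64)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown FDR method {method!r}")
    if p.size == 0:
        return p.copy()
    _, q, _, _ = multipletests(p, alpha=0.05, method=sm_method)
    return q


def count_significant(q_one: np.ndarray, q_two: np.ndarray,
                      alpha: float = 0.05) -> tuple[int, int]:
    return int(np.sum(np.asarray(q_one) < alpha)), int(np.sum(np.asarray(q_two) < alpha))


def latent_stat_report(latents: LatentMatrix, alpha: float = 0.05,
                       method: str = "bh") -> StatReport:
    """Full per-cell validation: both tests, FDR adjustment, significance counts."""
    p_one = one_sample_test(latents)
    p_two = two_sample_test(latents)
    q_one = fdr_adjust(p_one, method)
    q_two = fdr_adjust(p_two, method)
    n_one, n_two = count_significant(q_one, q_two, alpha)
    return StatReport(
        n_features=latents.values.shape[1],
        p_one=p_one, p_two=p_two, q_one=q_one, q_two=q_two,
        n_sig_one=n_one, n_sig_two=n_two, alpha=alpha,
    )
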