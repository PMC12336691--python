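"""Prediction of prior treatment exposure from pattern breadth/depth.

The discovered sequence patterns are HLA-restricted, so exposure
prediction is evaluated within the pattern's own HLA stratum: among
carriers of the restricting allele, a sample's clonal breadth (or
depth) against the pattern is the score and prior exposure is the
label. Discrimination is summarized by the AUC computed as the midrank
Mann-Whitney statistic (identical to trapezoidal integration of the
ROC with tied scores pooled), with a 95% CI from the DeLong
covariance estimator; a stratified bootstrap CI is available as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ROCResult", "roc_auc", "predict_exposure"]


@dataclass(frozen=True)
class ROCResult:
    """ROC summary for one scorer within one stratum."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    ci95: tuple[float, float]
    scorer: str = "breadth"
    n_pos: int = 0
    n_neg: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivities,
                "specificity": self.specificities,
            }
        )


def _auc_midrank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized midrank sum of the positive scores."""
    r = rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    return float((r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_var(scores: np.ndarray, labels: np.ndarray, auc: float) -> float:
    """DeLong variance of the AUC via placement values."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    # v10[i] = P(pos_i > neg) + 0.5 P(=); v01[j] analogous
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    scores,
    labels,
    scorer: str = "breadth",
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """ROC curve and AUC with 95% CI for one score vector.

    ``labels`` are booleans (True = exposed). The AUC equals the
    probability a random exposed sample outscores a random unexposed
    one, ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(scores) != len(labels):
        raise ValueError("scores and labels length mismatch")
    if labels.all() or not labels.any():
        raise ValueError("both exposed and unexposed samples are required")

    auc = _auc_midrank(scores, labels)
    if ci_method == "delong":
        se = np.sqrt(_delong_var(scores, labels, auc))
        lo, hi = auc - 1.96 * se, auc + 1.96 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(labels)
        neg_idx = np.flatnonzero(~labels)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate(
                [rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
            )
            boots[b] = _auc_midrank(scores[idx], labels[idx])
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    # ROC staircase over unique thresholds (descending)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    sens = np.array([(scores[labels] >= t).sum() / n1 for t in thresholds])
    spec = np.array([(scores[~labels] < t).sum() / n0 for t in thresholds])
    return ROCResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        ci95=(float(max(0.0, lo)), float(min(1.0, hi))),
        scorer=scorer,
        n_pos=n1,
        n_neg=n0,
    )


def predict_exposure(
    scores: pd.DataFrame,
    exposed: pd.Series,
    carrier: pd.Series | None = None,
    ci_method: str = "delong",
) -> dict[str, ROCResult]:
    """Within-stratum exposure prediction from breadth and depth.

    ``scores`` is a samples-indexed frame with ``breadth`` and
    ``depth`` columns (e.g. the output of
    :meth:`EnhancedSequenceDiscovery.transform`); ``exposed`` the
    exposure labels; ``carrier`` the HLA stratum mask (None = all
    samples). Returns one :class:`ROCResult` per scorer.
    """
    exposed = exposed.reindex(scores.index)
    if exposed.isna().any():
        raise ValueError("exposure label missing for some scored samples")
    mask = (
        carrier.reindex(scores.index).fillna(False).astype(bool)
        if carrier is not None
        else pd.Series(True, index=scores.index)
    )
    if not mask.any():
        raise ValueError("empty HLA stratum")
    sub = scores[mask]
    lab = exposed[mask].astype(bool)
    if lab.all() or not lab.any():
        raise ValueError("stratum lacks exposed or unexposed samples")
    return {
        col: roc_auc(sub[col].to_numpy(), lab.to_numpy(), scorer=col, ci_method=ci_method)
        for col in ("breadth", "depth")
        if col in sub.columns
    }
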