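"""ROC/AUC evaluation, DeLong AUC comparison, and type-I calibration.

Significance scores are ``1 - p``: the AUC is then exactly the probability
that a stimulus-containing ROI yields a smaller p-value than a null ROI
(Mann-Whitney pairing, ties counted half).  Two analysis methods scored on
the same simulated instances are compared with DeLong's nonparametric
estimator of the variance of the (correlated) AUC difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ROCResult",
    "AUCComparison",
    "roc_from_pvalues",
    "delong_compare",
    "fpr_calibration",
]


@dataclass(frozen=True)
class ROCResult:
    """ROC curve over the (1 - p) threshold sweep, with Mann-Whitney AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class AUCComparison:
    """DeLong z-test of the difference between two AUCs."""

    auc1: float
    auc2: float
    se_diff: float
    z: float
    p: float


def _placements(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """Per-observation placement values (DeLong's structural components).

    V10[i] = P(score_i > neg) + P(= )/2 over nulls; V01[j] analogous over
    positives.  mean(V10) = mean(V01) = AUC.
    """
    pos = pos_scores[:, None]
    neg = neg_scores[None, :]
    wins = (pos > neg).astype(float) + 0.5 * (pos == neg)
    return wins.mean(axis=1), 1.0 - wins.mean(axis=0)  # V10, V01 (as P(pos>neg))


def roc_from_pvalues(
    active_pvals: np.ndarray, null_pvals: np.ndarray
) -> ROCResult:
    """ROC of discriminating active from null ROIs by p-value.

    The score is ``1 - p``; the AUC equals the probability that an active
    ROI is more significant (smaller p) than a null ROI, ties counted half.
    """
    active = np.asarray(active_pvals, float)
    null = np.asarray(null_pvals, float)
    if active.size == 0 or null.size == 0:
        raise ValueError("both p-value lists must be nonempty")
    # rank on -p rather than 1 - p: the same ordering, but immune to the
    # floating-point collapse of 1 - p for very small p-values
    v10, _ = _placements(-active, -null)
    auc = float(v10.mean())
    pos, neg = 1.0 - active, 1.0 - null

    # threshold sweep over all observed scores (plus sentinels)
    grid = np.unique(np.concatenate([pos, neg]))
    thresholds = np.concatenate([[np.inf], grid[::-1], [-np.inf]])
    fpr = np.array([(neg >= th).mean() for th in thresholds])
    tpr = np.array([(pos >= th).mean() for th in thresholds])
    return ROCResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        n_positive=active.size,
        n_negative=null.size,
    )


def delong_compare(
    active_p_a: np.ndarray,
    null_p_a: np.ndarray,
    active_p_b: np.ndarray,
    null_p_b: np.ndarray,
    paired: bool = True,
) -> AUCComparison:
    """DeLong z-test for AUC(A) vs AUC(B).

    In paired mode (default) the two methods must have scored the same
    simulation instances in the same order; the covariance between the two
    AUCs is then estimated from the paired placement values.  In unpaired
    mode the AUC variances are estimated independently.
    """
    sa_pos, sa_neg = -np.asarray(active_p_a, float), -np.asarray(null_p_a, float)
    sb_pos, sb_neg = -np.asarray(active_p_b, float), -np.asarray(null_p_b, float)
    v10_a, v01_a = _placements(sa_pos, sa_neg)
    v10_b, v01_b = _placements(sb_pos, sb_neg)
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())
    m, n = len(v10_a), len(v01_a)

    def _var(v, auc):
        return float(np.sum((v - auc) ** 2)) / max(len(v) - 1, 1)

    if paired:
        if len(v10_a) != len(v10_b) or len(v01_a) != len(v01_b):
            raise ValueError("paired comparison requires equal instance counts")
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
        var = (
            (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
        )
    else:
        var = (
            _var(v10_a, auc_a) / m
            + _var(v01_a, auc_a) / n
            + _var(v10_b, auc_b) / len(v10_b)
            + _var(v01_b, auc_b) / len(v01_b)
        )
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:  # identical scores: no difference to test
            return AUCComparison(auc_a, auc_b, 0.0, 0.0, 1.0)
        raise ValueError("degenerate variance: all placement values tied")
    se = float(np.sqrt(var))
    z = abs(diff) / se
    p = float(2.0 * stats.norm.sf(z))
    return AUCComparison(auc1=auc_a, auc2=auc_b, se_diff=se, z=float(z), p=p)


def fpr_calibration(
    null_pvals: np.ndarray, alpha_grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical false-positive rate at each nominal level.

    Returns ``(alpha_grid, empirical_fpr)`` where the empirical FPR at
    alpha is the fraction of null p-values <= alpha; ideally the curve is
    the diagonal.  The default grid is 512 evenly spaced levels plus the
    conventional 0.05.
    """
    null = np.asarray(null_pvals, float)
    if null.size == 0:
        raise ValueError("null p-values must be nonempty")
    if alpha_grid is None:
        alpha_grid = np.union1d(np.linspace(0.0, 1.0, 512), [0.05])
    alpha_grid = np.asarray(alpha_grid, float)
    fpr = np.array([(null <= a).mean() for a in alpha_grid])
    return alpha_grid, fpr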