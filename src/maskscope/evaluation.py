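"""ROC analyses for the masking-risk validation.

Binary AUC by the Mann-Whitney pair-count estimator (ties credited 0.5),
percentile-bootstrap confidence intervals (B = 1000 by default), a paired
predictor comparison on the same cases via leave-one-case-out jackknife
pseudo-values (single-reader multi-case design), an independent-samples
Z-test against a literature AUC, the three-category cumulative ROC (two
nested binary splits of the ordered categories), and a chi-square
comparison of two proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import MaskScopeError, ParameterError

__all__ = [
    "ROCSummary",
    "CumulativeROCResult",
    "auc_mann_whitney",
    "roc_curve_points",
    "bootstrap_auc_ci",
    "paired_auc_test",
    "independent_auc_ztest",
    "ci_to_se",
    "cumulative_roc",
    "compare_proportions",
    "roc_summary",
]


@dataclass
class ROCSummary:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    curve: np.ndarray            # (k, 2) array of (FPR, TPR)
    bootstrap_B: int = 0
    seed: int | None = None


@dataclass
class CumulativeROCResult:
    """Two nested binary tasks over ordered categories low < mid < high."""

    auc_low_vs_rest: float | None
    ci_low_vs_rest: tuple | None
    auc_rest_vs_high: float | None
    ci_rest_vs_high: tuple | None
    counts: dict = field(default_factory=dict)


def _check_binary(labels: np.ndarray) -> tuple[int, int]:
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes must be present")
    if n_pos + n_neg != labels.size:
        raise ParameterError("labels must be binary 0/1")
    return n_pos, n_neg


def auc_mann_whitney(scores, labels) -> float:
    """Pair-counting AUC with ties credited 0.5.

    Computed from midranks: AUC = (R_pos - n_pos (n_pos+1)/2) / (n_pos n_neg),
    which equals the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos, n_neg = _check_binary(labels)
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_curve_points(scores, labels) -> np.ndarray:
    """Empirical ROC curve (FPR, TPR), from (0,0) to (1,1), tie-aware."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos, n_neg = _check_binary(labels)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # collapse tied thresholds
    distinct = np.r_[True, np.diff(s) != 0]
    tp = np.cumsum(y == 1)
    fp = np.cumsum(y == 0)
    idx = np.r_[np.nonzero(distinct)[0][1:] - 1, len(s) - 1]
    tpr = tp[idx] / n_pos
    fpr = fp[idx] / n_neg
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])


def bootstrap_auc_ci(
    scores,
    labels,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the AUC under case resampling.

    Whole cases are resampled with replacement; a resample that loses one
    class entirely is redrawn (the redraw count is tracked on the
    function attribute ``last_redraws``).
    """
    if B < 100:
        raise ParameterError("B must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_binary(labels)
    n = scores.size
    rng = rng if rng is not None else np.random.default_rng(seed)
    aucs = np.empty(B)
    redraws = 0
    filled = 0
    while filled < B:
        take = min(B - filled, 256)
        idx = rng.integers(0, n, size=(take, n))
        lab = labels[idx]
        npos = (lab == 1).sum(axis=1)
        ok = (npos > 0) & (npos < n)
        redraws += int((~ok).sum())
        if not ok.any():
            continue
        sc = scores[idx[ok]]
        lab = lab[ok]
        ranks = stats.rankdata(sc, axis=1)
        npos_ok = npos[ok]
        nneg_ok = n - npos_ok
        r_pos = np.where(lab == 1, ranks, 0.0).sum(axis=1)
        vals = (r_pos - npos_ok * (npos_ok + 1) / 2.0) / (npos_ok * nneg_ok)
        m = min(vals.size, B - filled)
        aucs[filled : filled + m] = vals[:m]
        filled += m
    bootstrap_auc_ci.last_redraws = redraws
    lo, hi = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _jackknife_pseudovalues(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Leave-one-case-out pseudo-values of the Mann-Whitney AUC.

    Uses the per-case marginals of the pair-score matrix so each LOO AUC
    is O(1) after an O(n_pos * n_neg) precomputation.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n_pos, n_neg = pos.size, neg.size
    n = n_pos + n_neg
    wins = (pos[:, None] > neg[None, :]).astype(float)
    wins += 0.5 * (pos[:, None] == neg[None, :])
    total = wins.sum()
    theta = total / (n_pos * n_neg)
    pseudo = np.empty(n)
    loo = np.empty(n)
    if n_pos > 1:
        loo_pos = (total - wins.sum(axis=1)) / ((n_pos - 1) * n_neg)
    else:
        loo_pos = np.full(n_pos, theta)
    if n_neg > 1:
        loo_neg = (total - wins.sum(axis=0)) / (n_pos * (n_neg - 1))
    else:
        loo_neg = np.full(n_neg, theta)
    loo[labels == 1] = loo_pos
    loo[labels == 0] = loo_neg
    pseudo = n * theta - (n - 1) * loo
    return pseudo


def paired_auc_test(scores_a, scores_b, labels):
    """Paired AUC comparison on common cases via jackknife pseudo-values.

    Returns (auc_a, auc_b, diff, se_diff, p).  The variance of the AUC
    difference is the sample variance of the per-case pseudo-value
    differences over n, which carries the covariance between the two
    predictors evaluated on the same cases; p is two-sided normal-theory.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ParameterError("paired comparison requires equal-length arrays")
    _check_binary(labels)
    n = labels.size
    if n < 10:
        import warnings

        warnings.warn("n < 10: jackknife variance is unreliable", stacklevel=2)
    auc_a = auc_mann_whitney(scores_a, labels)
    auc_b = auc_mann_whitney(scores_b, labels)
    pa = _jackknife_pseudovalues(scores_a, labels)
    pb = _jackknife_pseudovalues(scores_b, labels)
    d = pa - pb
    se = float(np.sqrt(d.var(ddof=1) / n))
    diff = auc_a - auc_b
    if se == 0.0:
        return auc_a, auc_b, diff, 0.0, 1.0 if diff == 0 else 0.0
    z = diff / se
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, diff, se, float(p)


def ci_to_se(ci_low: float, ci_high: float) -> float:
    """Standard error implied by a printed 95% confidence interval."""
    return (ci_high - ci_low) / (2.0 * stats.norm.ppf(0.975))


def independent_auc_ztest(auc1: float, se1: float, auc2: float, se2: float):
    """Two-sided Z-test of two AUCs from independent samples."""
    if se1 < 0 or se2 < 0:
        raise ParameterError("standard errors must be non-negative")
    se = float(np.hypot(se1, se2))
    if se == 0.0:
        return (0.0, 1.0) if auc1 == auc2 else (float(np.inf), 0.0)
    z = (auc1 - auc2) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def cumulative_roc(
    scores,
    categories,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> CumulativeROCResult:
    """Three-category cumulative ROC: two nested binary discrimination tasks.

    With ordered categories low < intermediate < high, reports AUC(low vs
    intermediate+high) and AUC(low+intermediate vs high), each with a
    percentile-bootstrap CI.  A split with an empty side is left None.
    """
    scores = np.asarray(scores, dtype=float)
    cats = np.asarray(categories)
    levels = np.unique(cats)
    if levels.size < 2:
        raise ParameterError("need at least two categories present")
    order = np.sort(levels)
    low = order[0]
    high = order[-1]
    counts = {str(v): int((cats == v).sum()) for v in order}
    rng = np.random.default_rng(seed)

    def split_auc(labels):
        if labels.min() == labels.max():
            return None, None
        a = auc_mann_whitney(scores, labels)
        ci = bootstrap_auc_ci(scores, labels, B=B, alpha=alpha, rng=rng)
        return a, ci

    auc1, ci1 = split_auc((cats != low).astype(int))
    auc2, ci2 = split_auc((cats == high).astype(int))
    return CumulativeROCResult(
        auc_low_vs_rest=auc1,
        ci_low_vs_rest=ci1,
        auc_rest_vs_high=auc2,
        ci_rest_vs_high=ci2,
        counts=counts,
    )


def compare_proportions(k1: int, n1: int, k2: int, n2: int):
    """Compare two binomial proportions; Pearson chi-square, two-sided.

    Returns (p1_percent, p2_percent, chi2, p).  Proportions are rounded to
    whole percent (reporting convention).  Falls back to Fisher's exact
    test when any table margin is zero.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ParameterError("require 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    p1 = round(100.0 * k1 / n1)
    p2 = round(100.0 * k2 / n2)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        _, p = stats.fisher_exact(table)
        return p1, p2, float("nan"), float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return p1, p2, float(chi2), float(p)


def roc_summary(
    scores, labels, B: int = 1000, alpha: float = 0.05, seed: int | None = None
) -> ROCSummary:
    """Point AUC, bootstrap CI and curve points in one summary object."""
    labels = np.asarray(labels)
    n_pos, n_neg = _check_binary(labels)
    auc = auc_mann_whitney(scores, labels)
    lo, hi = bootstrap_auc_ci(scores, labels, B=B, alpha=alpha, seed=seed)
    return ROCSummary(
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        n_pos=n_pos,
        n_neg=n_neg,
        curve=roc_curve_points(scores, labels),
        bootstrap_B=B,
        seed=seed,
    )
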