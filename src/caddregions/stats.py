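"""Self-contained statistics for the threshold analysis.

Implements the Mann-Whitney U test (mid-ranks, tie-corrected normal
approximation with continuity correction, and exact enumeration at small
sample sizes), Benjamini-Hochberg FDR adjustment, ROC curves with
trapezoidal AUC, and the Youden-J / F1 / weighted optimal-cutpoint rules.

Conventions shared by everything downstream:

* the classification rule is ``score >= threshold => predicted pathogenic``;
* candidate cutpoints are the distinct observed score values;
* cutpoint ties break toward the *higher* threshold (fewer false positives).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "RocCurve",
    "CutpointResult",
    "mann_whitney_u",
    "bh_fdr",
    "roc_curve",
    "youden_cutpoint",
    "f1_cutpoint",
    "weighted_cutpoint",
    "significance_label",
]

#: total sample size at or below which the exact MWU null is enumerated
EXACT_ENUMERATION_LIMIT = 10


@dataclass
class RocCurve:
    """ROC curve for scores under ``score >= threshold`` classification.

    ``thresholds`` descend from an ``inf`` sentinel (the (0,0) corner) down
    to the minimum observed score (the (1,1) corner); ``auc`` is the
    trapezoidal area, which equals the tie-corrected rank statistic
    ``U / (n_pos * n_neg)``.  ``tp``/``fp`` hold the integer counts behind
    ``tpr``/``fpr`` so cutpoint comparisons can be made in exact rational
    arithmetic (float rounding must not decide a tie-break).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    tp: np.ndarray = None
    fp: np.ndarray = None


@dataclass
class CutpointResult:
    """An optimal cutpoint with both criteria evaluated there."""

    threshold: float
    j: float
    f1: float
    objective: float
    strategy: str


def _check_group(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"empty group: {name}")
    return a


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of ``x`` vs ``y``.

    Returns ``(U, p)`` where ``U`` is the mid-rank U statistic of the first
    sample.  For total sample size <= 10 (and ``method="auto"``) the exact
    two-sided p-value is obtained by enumerating all label assignments and
    counting those whose U deviates from the null mean at least as much as
    observed; otherwise a normal approximation with tie-corrected variance
    and 0.5 continuity correction is used.
    """
    x = _check_group(x, "x")
    y = _check_group(y, "y")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    # doubled mid-ranks are exact integers, so tie comparisons are exact
    ranks2 = np.rint(2.0 * rankdata(pooled)).astype(np.int64)
    u2_obs = int(ranks2[:n1].sum()) - n1 * (n1 + 1)
    u = u2_obs / 2.0

    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    exact = method == "exact" or (method == "auto" and n <= EXACT_ENUMERATION_LIMIT)

    if exact:
        mu2 = n1 * n2  # = 2 * n1*n2/2
        dev = abs(u2_obs - mu2)
        hits = 0
        for idx in combinations(range(n), n1):
            u2 = int(sum(ranks2[i] for i in idx)) - n1 * (n1 + 1)
            if abs(u2 - mu2) >= dev:
                hits += 1
        return u, hits / comb(n, n1)

    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(np.float64) ** 3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u, 1.0
    d = u - mu
    if d == 0:
        return u, 1.0
    z = (abs(d) - 0.5) / sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(z)))
    # the normal tail underflows for |z| > ~38; keep p strictly positive
    return u, max(p, 5e-324)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adj
    return out


def roc_curve(pos, neg) -> RocCurve:
    """ROC curve of pathogenic (``pos``) vs benign (``neg``) scores.

    Candidate thresholds are the distinct observed scores, descending,
    preceded by an ``inf`` sentinel so the curve starts at (0, 0) and ends
    at (1, 1).
    """
    pos = np.sort(_check_group(pos, "pos"))
    neg = np.sort(_check_group(neg, "neg"))
    n1, n2 = pos.size, neg.size
    observed = np.unique(np.concatenate([pos, neg]))[::-1]
    thresholds = np.concatenate([[np.inf], observed])
    # count of scores >= t via searchsorted on the ascending arrays
    tp = n1 - np.searchsorted(pos, thresholds, side="left")
    fp = n2 - np.searchsorted(neg, thresholds, side="left")
    tpr = tp / n1
    fpr = fp / n2
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc, n_pos=n1, n_neg=n2, tp=tp, fp=fp
    )


def _counts(curve: RocCurve) -> tuple[np.ndarray, np.ndarray]:
    if curve.tp is not None and curve.fp is not None:
        return curve.tp, curve.fp
    tp = np.rint(curve.tpr * curve.n_pos).astype(np.int64)
    fp = np.rint(curve.fpr * curve.n_neg).astype(np.int64)
    return tp, fp


def _f1_values(tp: np.ndarray, fp: np.ndarray, n_pos: int) -> np.ndarray:
    fn = n_pos - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2.0 * tp / np.where(denom > 0, denom, 1), 0.0)
    # no predicted positives => undefined precision => F1 = 0
    return np.where(tp + fp == 0, 0.0, f1)


def _result(curve: RocCurve, i: int, objective: float, strategy: str) -> CutpointResult:
    tp, fp = _counts(curve)
    j = float(tp[i]) / curve.n_pos - float(fp[i]) / curve.n_neg
    f1 = float(_f1_values(tp[i : i + 1], fp[i : i + 1], curve.n_pos)[0])
    return CutpointResult(
        threshold=float(curve.thresholds[i]),
        j=j,
        f1=f1,
        objective=float(objective),
        strategy=strategy,
    )


def _argmax_first(values) -> int:
    """First index of the maximum (thresholds descend, so the first maximum
    is the highest threshold: the conservative tie-break)."""
    best, best_i = None, 0
    for i, v in enumerate(values):
        if best is None or v > best:
            best, best_i = v, i
    return best_i


def youden_cutpoint(curve: RocCurve) -> CutpointResult:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are compared on the exact integer key ``tp*n_neg - fp*n_pos``
    (J times ``n_pos*n_neg``), so equal J values tie exactly and resolve to
    the higher threshold.
    """
    tp, fp = _counts(curve)
    key = tp.astype(np.int64) * curve.n_neg - fp.astype(np.int64) * curve.n_pos
    i = int(np.argmax(key[1:])) + 1  # skip the inf sentinel
    return _result(curve, i, key[i] / (curve.n_pos * curve.n_neg), "youden")


def f1_cutpoint(pos, neg) -> CutpointResult:
    """Threshold maximizing F1 with pathogenic as the positive class.

    Candidates are compared as exact fractions ``2tp / (2tp + fp + fn)`` by
    cross-multiplication; ties resolve to the higher threshold.
    """
    curve = roc_curve(pos, neg)
    tp, fp = _counts(curve)
    fracs = [
        Fraction(int(2 * t), int(2 * t + f + (curve.n_pos - t))) if (t + f) > 0 else Fraction(0)
        for t, f in zip(tp[1:], fp[1:])
    ]
    i = _argmax_first(fracs) + 1
    return _result(curve, i, float(fracs[i - 1]), "f1")


def weighted_cutpoint(pos, neg, w_youden: float = 0.4) -> CutpointResult:
    """Threshold maximizing ``w*J + (1-w)*F1`` on the shared threshold grid.

    ``w_youden = 1`` recovers the Youden rule and ``w_youden = 0`` the F1
    rule exactly (same candidate grid and tie-break).
    """
    if not (0.0 <= w_youden <= 1.0):
        raise ValueError("w_youden must lie in [0, 1]")
    curve = roc_curve(pos, neg)
    if w_youden == 1.0:
        cut = youden_cutpoint(curve)
        return CutpointResult(cut.threshold, cut.j, cut.f1, cut.objective, "weighted")
    if w_youden == 0.0:
        cut = f1_cutpoint(pos, neg)
        return CutpointResult(cut.threshold, cut.j, cut.f1, cut.objective, "weighted")
    tp, fp = _counts(curve)
    j = tp / curve.n_pos - fp / curve.n_neg
    f1 = _f1_values(tp, fp, curve.n_pos)
    objective = w_youden * j + (1.0 - w_youden) * f1
    i = _argmax_first(objective[1:]) + 1
    return _result(curve, i, objective[i], "weighted")


def significance_label(p_adj: float) -> str:
    """Star notation: ``***`` < 0.001, ``**`` < 0.01, ``*`` < 0.05, else ``ns``."""
    if not (0.0 < p_adj <= 1.0):
        raise ValueError("adjusted p-value must lie in (0, 1]")
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"
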