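"""Unit and property tests for the statistics core."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata

from caddregions.stats import (
    bh_fdr,
    f1_cutpoint,
    mann_whitney_u,
    roc_curve,
    significance_label,
    weighted_cutpoint,
    youden_cutpoint,
)


def enumeration_mwu_p(x, y):
    """Independent exact oracle: enumerate every label assignment."""
    x, y = list(x), list(y)
    pooled = np.array(x + y, dtype=float)
    n1, n = len(x), len(pooled)
    r2 = np.rint(2 * rankdata(pooled)).astype(int)
    u2_obs = int(r2[:n1].sum()) - n1 * (n1 + 1)
    mu2 = n1 * len(y)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        u2 = sum(int(r2[i]) for i in idx) - n1 * (n1 + 1)
        if abs(u2 - mu2) >= abs(u2_obs - mu2):
            hits += 1
    return hits / total


def scan_cutpoint(pos, neg, kind, w=0.4):
    """Independent exhaustive-scan oracle over all observed thresholds."""
    n1, n2 = len(pos), len(neg)
    best = None
    for t in sorted(set(pos) | set(neg), reverse=True):
        tp = sum(p >= t for p in pos)
        fp = sum(q >= t for q in neg)
        fn = n1 - tp
        j = Fraction(tp, n1) - Fraction(fp, n2)
        f1 = Fraction(2 * tp, 2 * tp + fp + fn) if tp + fp > 0 else Fraction(0)
        if kind == "youden":
            obj = j
        elif kind == "f1":
            obj = f1
        else:  # same float expression as the implementation
            obj = w * (tp / n1 - fp / n2) + (1.0 - w) * (
                2 * tp / (2 * tp + fp + fn) if tp + fp > 0 else 0.0
            )
        if best is None or obj > best[0]:
            best = (obj, t)
    return best[1]


class TestMannWhitney:
    @pytest.mark.parametrize(
        "x,y,u_exp,p_exp",
        [
            ([1, 2, 3], [4, 5, 6], 0.0, 0.1),
            ([5], [5], 0.5, 1.0),
            ([4, 5, 6], [1, 2, 3], 9.0, 0.1),
        ],
    )
    def test_exact_examples(self, x, y, u_exp, p_exp):
        u, p = mann_whitney_u(x, y)
        assert u == u_exp
        assert p == pytest.approx(p_exp, abs=1e-15)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            mann_whitney_u([], [1.0])

    def test_exact_matches_enumeration_with_ties(self, rng):
        for _ in range(60):
            n1, n2 = rng.integers(1, 8, size=2)
            while n1 + n2 > 10:
                n1, n2 = rng.integers(1, 8, size=2)
            x = rng.integers(0, 6, size=n1).astype(float)
            y = rng.integers(0, 6, size=n2).astype(float)
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(enumeration_mwu_p(x, y), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(40):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, p = mann_whitney_u(x, y)
            p_sp = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert p == pytest.approx(p_sp, abs=1e-12)

    def test_asymptotic_matches_scipy(self, rng):
        for _ in range(40):
            n1, n2 = int(rng.integers(8, 30)), int(rng.integers(8, 30))
            x = rng.integers(0, 15, size=n1).astype(float)
            y = rng.integers(0, 15, size=n2).astype(float) + rng.integers(0, 3)
            _, p = mann_whitney_u(x, y, method="asymptotic")
            p_sp = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert p == pytest.approx(min(1.0, p_sp), abs=1e-9)

    def test_normal_approximation_close_to_exact(self, rng):
        """At n=8..12 without heavy ties the approximation is within 0.02."""
        for _ in range(25):
            n1 = int(rng.integers(4, 7))
            n2 = int(rng.integers(4, 7))
            x = rng.normal(size=n1)
            y = rng.normal(loc=rng.uniform(0, 1.5), size=n2)
            _, p_exact = mann_whitney_u(x, y, method="exact")
            _, p_approx = mann_whitney_u(x, y, method="asymptotic")
            assert abs(p_exact - p_approx) <= 0.02


class TestBhFdr:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_step_up_examples(self, raw, expected):
        assert bh_fdr(raw) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [1.2], [-0.1]])
    def test_domain_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 25)))
            adj = bh_fdr(p)
            _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(adj, adj_sm, atol=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    def test_monotone_and_order_preserving(self, pvals):
        adj = bh_fdr(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestRoc:
    @pytest.mark.parametrize(
        "pos,neg,auc",
        [
            ([10, 20], [1, 2], 1.0),
            ([3, 1, 4], [3, 1, 4], 0.5),
            ([3, 5], [4, 1], 0.75),
        ],
    )
    def test_auc_examples(self, pos, neg, auc):
        assert roc_curve(pos, neg).auc == pytest.approx(auc, abs=1e-12)

    def test_curve_shape(self, rng):
        curve = roc_curve(rng.normal(2, 1, 20), rng.normal(0, 1, 30))
        assert curve.tpr[0] == 0.0 and curve.fpr[0] == 0.0
        assert curve.tpr[-1] == 1.0 and curve.fpr[-1] == 1.0
        assert np.all(np.diff(curve.tpr) >= 0) and np.all(np.diff(curve.fpr) >= 0)

    def test_auc_equals_rank_statistic(self, rng):
        for _ in range(50):
            pos = rng.integers(0, 8, size=int(rng.integers(1, 25))).astype(float)
            neg = rng.integers(0, 8, size=int(rng.integers(1, 25))).astype(float)
            u, _ = mann_whitney_u(pos, neg)
            assert roc_curve(pos, neg).auc == pytest.approx(
                u / (len(pos) * len(neg)), abs=1e-9
            )

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            pos = rng.integers(0, 10, size=15).astype(float)
            neg = rng.integers(0, 10, size=12).astype(float)
            y = np.r_[np.ones(15), np.zeros(12)]
            assert roc_curve(pos, neg).auc == pytest.approx(
                roc_auc_score(y, np.r_[pos, neg]), abs=1e-12
            )

    def test_label_swap_flips_auc(self, rng):
        for _ in range(30):
            pos = rng.integers(0, 6, size=10).astype(float)
            neg = rng.integers(0, 6, size=8).astype(float)
            assert roc_curve(pos, neg).auc + roc_curve(neg, pos).auc == pytest.approx(
                1.0, abs=1e-12
            )


class TestCutpoints:
    def test_youden_examples(self):
        cut = youden_cutpoint(roc_curve([10, 20], [1, 2]))
        assert (cut.threshold, cut.j) == (10.0, 1.0)
        assert youden_cutpoint(roc_curve([3, 1], [3, 1])).j == 0.0
        cut = youden_cutpoint(roc_curve([3, 5, 6], [1, 4, 2]))
        assert cut.threshold == 5.0  # tie with t=3 resolves to the higher cut
        assert cut.j == pytest.approx(2 / 3)

    def test_f1_examples(self):
        cut = f1_cutpoint([10, 20], [1, 2])
        assert (cut.threshold, cut.f1) == (10.0, 1.0)
        cut = f1_cutpoint([5], [5])
        assert cut.threshold == 5.0
        assert cut.f1 == pytest.approx(2 / 3)

    def test_cutpoints_match_exhaustive_scan(self, rng):
        for _ in range(150):
            pos = rng.integers(0, 10, size=int(rng.integers(1, 15))).astype(float)
            neg = rng.integers(0, 10, size=int(rng.integers(1, 15))).astype(float)
            assert youden_cutpoint(roc_curve(pos, neg)).threshold == scan_cutpoint(
                pos, neg, "youden"
            )
            assert f1_cutpoint(pos, neg).threshold == scan_cutpoint(pos, neg, "f1")
            w = float(rng.uniform(0.1, 0.9))
            assert weighted_cutpoint(pos, neg, w).threshold == scan_cutpoint(
                pos, neg, "weighted", w
            )

    def test_degenerate_weights_recover_named_criteria(self, rng):
        for _ in range(50):
            pos = rng.integers(0, 8, size=int(rng.integers(1, 12))).astype(float)
            neg = rng.integers(0, 8, size=int(rng.integers(1, 12))).astype(float)
            assert (
                weighted_cutpoint(pos, neg, 1.0).threshold
                == youden_cutpoint(roc_curve(pos, neg)).threshold
            )
            assert (
                weighted_cutpoint(pos, neg, 0.0).threshold
                == f1_cutpoint(pos, neg).threshold
            )

    def test_weight_domain(self):
        with pytest.raises(ValueError):
            weighted_cutpoint([1.0], [2.0], 1.5)


class TestSignificanceLabel:
    @pytest.mark.parametrize(
        "p,label",
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.05, "ns"), (0.2, "ns"), (1.0, "ns")],
    )
    def test_star_mapping(self, p, label):
        assert significance_label(p) == label

    @pytest.mark.parametrize("bad", [0.0, -1.0, 1.5])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            significance_label(bad)
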