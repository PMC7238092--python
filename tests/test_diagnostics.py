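"""Diagnostic-statistics unit tests with independent oracles.

Implementation-vs-oracle pairs: metric ratios vs exact rational
arithmetic; McNemar vs brute-force binomial mass summation and
statsmodels; kappa vs hand-computed fractions and scikit-learn; ROC AUC
vs brute-force pairwise counting and scikit-learn; Youden vs exhaustive
threshold search; Fisher fallback vs hypergeometric enumeration.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from cadfusion.diagnostics import (
    ContingencyTable2x2,
    PairedAgreementTable,
    cohen_kappa,
    compare_auc_paired,
    compare_proportions,
    empirical_roc,
    estimate_paired_auc_correlation,
    hanley_mcneil_se,
    mcnemar_test,
    metrics_from_table,
    percent_string,
    youden_optimal,
)


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def brute_force_auc(pos_scores, neg_scores) -> Fraction:
    """Tie-corrected pairwise comparison over all positive-negative pairs."""
    num = Fraction(0)
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                num += 1
            elif p == n:
                num += Fraction(1, 2)
    return num / (len(pos_scores) * len(neg_scores))


def brute_force_mcnemar_exact(b: int, c: int) -> Fraction:
    """Two-sided tail of Binomial(b + c, 1/2) by direct mass summation."""
    n = b + c
    k = min(b, c)
    tail = sum(Fraction(math.comb(n, i), 2**n) for i in range(k + 1))
    return min(Fraction(1), 2 * tail)


def brute_force_youden(scores, truth):
    """Exhaustive search of sens + spec - 1 over all midpoint thresholds."""
    values = sorted(set(scores))
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    best = None
    for lo, hi in zip(values, values[1:]):
        cut = (lo + hi) / 2
        sens = sum(s > cut for s in pos) / len(pos)
        spec = sum(s < cut for s in neg) / len(neg)
        j = sens + spec - 1
        if best is None or j > best[1] + 1e-12 or (
            abs(j - best[1]) <= 1e-12 and sens > best[2]
        ):
            best = (cut, j, sens)
    return best[0], best[1]


# --------------------------------------------------------------------------
# 2x2 metrics
# --------------------------------------------------------------------------

class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics_from_table(ContingencyTable2x2(10, 0, 0, 10))
        assert set(m.as_percent_strings().values()) == {"100.0"}

    def test_exact_ratio_identity(self):
        t = ContingencyTable2x2(tp=175, fp=58, fn=25, tn=254)
        m = metrics_from_table(t)
        assert m.sensitivity * (t.tp + t.fn) == t.tp
        assert m.specificity * (t.tn + t.fp) == t.tn
        assert m.accuracy * t.total == t.tp + t.tn

    def test_zero_denominator_flags_metric_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = metrics_from_table(ContingencyTable2x2(tp=0, fp=0, fn=5, tn=5))
        assert m.ppv is None
        assert m.sensitivity == 0
        assert m.npv == Fraction(1, 2)

    def test_percent_rounding_half_away_from_zero(self):
        assert percent_string(Fraction(432, 512)) == "84.4"  # 84.375
        assert percent_string(Fraction(1, 3)) == "33.3"
        assert percent_string(Fraction(1, 1)) == "100.0"

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 1)


# --------------------------------------------------------------------------
# McNemar
# --------------------------------------------------------------------------

class TestMcNemar:
    def test_no_discordant_pairs(self):
        res = mcnemar_test(0, 0)
        assert res.p_value == 1.0
        assert res.statistic is None

    def test_symmetric_discordants(self):
        assert mcnemar_test(5, 5, mode="exact").p_value == pytest.approx(1.0)

    def test_exact_two_sided_tail(self):
        res = mcnemar_test(15, 5, mode="exact")
        assert res.p_value == pytest.approx(0.0414, abs=5e-5)

    def test_exact_equals_binomial_mass_summation(self):
        for n in range(1, 31):
            for b in range(n + 1):
                c = n - b
                expected = float(brute_force_mcnemar_exact(b, c))
                got = mcnemar_test(b, c, mode="exact").p_value
                assert got == pytest.approx(expected, rel=1e-12), (b, c)

    def test_matches_statsmodels(self):
        for b, c in [(15, 5), (3, 9), (40, 25), (0, 7)]:
            exact = sm_mcnemar([[0, b], [c, 0]], exact=True)
            assert mcnemar_test(b, c, mode="exact").p_value == pytest.approx(
                float(exact.pvalue)
            )
            if b + c > 0:
                asym = sm_mcnemar([[0, b], [c, 0]], exact=False, correction=True)
                res = mcnemar_test(b, c, mode="asymptotic")
                assert res.p_value == pytest.approx(float(asym.pvalue))
                assert res.statistic == pytest.approx(float(asym.statistic))

    def test_auto_switches_at_25_discordants(self):
        assert mcnemar_test(10, 14).method == "exact"
        assert mcnemar_test(10, 15).method == "continuity-corrected"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test(-1, 3)


# --------------------------------------------------------------------------
# Cohen's kappa
# --------------------------------------------------------------------------

class TestKappa:
    def test_combined_mode_pairing_is_good(self):
        res = cohen_kappa(PairedAgreementTable(pp=141, pn=33, np=55, nn=283))
        assert res.kappa_rounded == 0.63
        assert res.band == "good"

    def test_without_mode_pairing_exact_value(self):
        res = cohen_kappa(PairedAgreementTable(pp=121, pn=53, np=46, nn=292))
        assert res.kappa_exact == Fraction(65788, 116476)
        assert res.kappa == pytest.approx(0.5648, abs=5e-5)
        assert Fraction(res.observed_agreement) == Fraction(413, 512)
        assert res.band == "moderate"

    def test_perfect_agreement(self):
        res = cohen_kappa(PairedAgreementTable(pp=50, pn=0, np=0, nn=50))
        assert res.kappa == 1.0
        assert res.band == "perfect"

    def test_kappa_one_iff_no_off_diagonal(self):
        assert cohen_kappa(PairedAgreementTable(3, 0, 0, 7)).kappa == 1.0
        assert cohen_kappa(PairedAgreementTable(3, 1, 0, 7)).kappa < 1.0

    def test_undefined_when_chance_agreement_is_one(self):
        with pytest.raises(ZeroDivisionError):
            cohen_kappa(PairedAgreementTable(pp=10, pn=0, np=0, nn=0))

    @given(
        st.tuples(
            st.integers(0, 30), st.integers(0, 30),
            st.integers(0, 30), st.integers(0, 30),
        ).filter(lambda t: sum(t) > 0 and not (t[1] + t[2] == 0 and (t[0] == 0 or t[3] == 0)))
    )
    def test_transposition_with_rater_relabel_invariance(self, cells):
        pp, pn, np_, nn = cells
        a = cohen_kappa(PairedAgreementTable(pp, pn, np_, nn))
        b = cohen_kappa(PairedAgreementTable(pp, np_, pn, nn))
        assert a.kappa_exact == b.kappa_exact

    def test_matches_sklearn(self, rng):
        r1 = rng.integers(0, 2, 200).astype(bool)
        r2 = r1 ^ (rng.random(200) < 0.25)
        table = PairedAgreementTable.from_verdicts(r1, r2)
        assert cohen_kappa(table).kappa == pytest.approx(
            cohen_kappa_score(r1, r2), rel=1e-12
        )


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------

class TestROC:
    def test_perfect_separation(self):
        roc = empirical_roc([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        assert roc.auc == pytest.approx(1.0)
        assert roc.se_auc == 0.0

    def test_constant_scores_give_chance_auc(self):
        roc = empirical_roc([2, 2, 2, 2], [1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.5)
        assert roc.optimal_cutoff is None

    def test_tie_corrected_pairwise_example(self):
        # pos=[3,2,2], neg=[1,2,0]: 7 concordant pairs + 2 ties -> 8/9
        scores = [3, 2, 2, 1, 2, 0]
        truth = [1, 1, 1, 0, 0, 0]
        oracle = brute_force_auc([3, 2, 2], [1, 2, 0])
        assert oracle == Fraction(8, 9)
        assert empirical_roc(scores, truth).auc == pytest.approx(float(oracle))

    def test_operating_points_monotone_from_origin_to_one(self, rng):
        scores = rng.integers(0, 5, 60)
        truth = rng.random(60) < 0.4
        truth[0], truth[1] = True, False
        roc = empirical_roc(scores, truth)
        fpr = [p[0] for p in roc.operating_points]
        tpr = [p[1] for p in roc.operating_points]
        assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    def test_auc_equals_brute_force_and_sklearn(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = rng.integers(0, 6, n)
            truth = rng.random(n) < 0.5
            if truth.all() or not truth.any():
                continue
            roc = empirical_roc(scores, truth)
            oracle = brute_force_auc(scores[truth], scores[~truth])
            assert roc.auc == pytest.approx(float(oracle), abs=1e-12)
            assert roc.auc == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            empirical_roc([1, 2], [1, 1])


class TestHanleyMcNeil:
    def test_minimal_chance_case(self):
        assert hanley_mcneil_se(0.5, 1, 1) == pytest.approx(0.5)

    def test_perfect_discrimination_has_zero_se(self):
        assert hanley_mcneil_se(1.0, 17, 23) == 0.0

    def test_direct_substitution(self):
        a, n_pos, n_neg = 0.84, 200, 312
        q1 = a / (2 - a)
        q2 = 2 * a * a / (1 + a)
        var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
            n_pos * n_neg
        )
        assert hanley_mcneil_se(a, n_pos, n_neg) == pytest.approx(math.sqrt(var))
        assert hanley_mcneil_se(a, n_pos, n_neg) == pytest.approx(0.019159, abs=5e-6)

    def test_decreasing_in_sample_sizes(self):
        base = hanley_mcneil_se(0.8, 50, 80)
        assert hanley_mcneil_se(0.8, 100, 80) < base
        assert hanley_mcneil_se(0.8, 50, 160) < base

    def test_out_of_range_auc_rejected(self):
        with pytest.raises(ValueError):
            hanley_mcneil_se(1.2, 10, 10)


class TestCompareAUC:
    def test_equal_aucs(self):
        res = compare_auc_paired(0.8, 0.8, 0.02, 0.03, r=0.4)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_r_zero_reduces_to_unpaired(self):
        res = compare_auc_paired(0.84, 0.76, 0.019, 0.023, r=0.0)
        z = (0.84 - 0.76) / math.sqrt(0.019**2 + 0.023**2)
        assert res.statistic == pytest.approx(z)
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_correlation_strictly_tightens_the_test(self):
        zs = [
            abs(compare_auc_paired(0.84, 0.80, 0.02, 0.02, r=r).statistic)
            for r in [0.0, 0.2, 0.4, 0.6, 0.8]
        ]
        assert all(a < b for a, b in zip(zs, zs[1:]))

    def test_degenerate_denominator_signalled(self):
        res = compare_auc_paired(0.8, 0.7, 0.0, 0.0)
        assert res.statistic is None
        assert res.method == "degenerate"


class TestPairedCorrelationEstimate:
    def test_identical_scores(self, rng):
        s = rng.integers(0, 5, 100)
        truth = np.arange(100) < 40
        assert estimate_paired_auc_correlation(s, s, truth) == pytest.approx(1.0)

    def test_anti_monotone_clipped_to_zero(self):
        s1 = np.array([0, 1, 2, 3, 0, 1, 2, 3])
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        assert estimate_paired_auc_correlation(s1, -s1, truth) == 0.0

    def test_independent_scores_near_zero(self, rng):
        n = 4000
        truth = np.arange(n) < n // 2
        s1 = rng.integers(0, 5, n)
        s2 = rng.permutation(s1)
        r = estimate_paired_auc_correlation(s1, s2, truth)
        assert r <= 3.0 / math.sqrt(n // 2)  # clipped at 0 below

    def test_constant_class_term_dropped_with_warning(self):
        s1 = np.array([2, 2, 2, 0, 1, 2])
        s2 = np.array([1, 2, 3, 0, 1, 2])
        truth = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        with pytest.warns(UserWarning, match="positive"):
            r = estimate_paired_auc_correlation(s1, s2, truth)
        assert 0.0 <= r <= 1.0


class TestYouden:
    def test_perfect_binary_classifier(self):
        roc = empirical_roc([1, 1, 0, 0], [1, 1, 0, 0])
        cutoff, j = youden_optimal(roc)
        assert (cutoff, j) == (0.5, 1.0)

    def test_chance_scores_give_zero_j(self):
        roc = empirical_roc([0, 1, 0, 1], [1, 1, 0, 0])
        _, j = youden_optimal(roc)
        assert j == pytest.approx(0.0)

    def test_plane_count_example(self):
        scores = [4, 3, 3, 2, 1, 1, 0, 2]
        truth = [1, 1, 1, 1, 0, 0, 0, 0]
        roc = empirical_roc(scores, truth)
        cutoff, j = youden_optimal(roc)
        assert cutoff == 1.5  # sensitivity-favoring tie against 2.5
        assert j == pytest.approx(0.75)

    def test_no_interior_point_rejected(self):
        roc = empirical_roc([1, 1], [1, 0])
        with pytest.raises(ValueError, match="interior"):
            youden_optimal(roc)

    def test_equals_exhaustive_threshold_search(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            scores = rng.integers(0, 5, n)
            truth = rng.random(n) < 0.5
            if truth.all() or not truth.any() or len(set(scores.tolist())) < 2:
                continue
            cutoff, j = youden_optimal(empirical_roc(scores, truth))
            o_cut, o_j = brute_force_youden(scores.tolist(), truth.tolist())
            assert j == pytest.approx(o_j, abs=1e-12)
            assert cutoff == pytest.approx(o_cut)


# --------------------------------------------------------------------------
# Two-proportion comparison
# --------------------------------------------------------------------------

class TestCompareProportions:
    def test_identical_proportions(self):
        assert compare_proportions(5, 10, 5, 10).p_value == pytest.approx(1.0)

    def test_exact_fallback_matches_hypergeometric_enumeration(self):
        res = compare_proportions(10, 10, 0, 10)
        assert res.method == "exact"
        # only the two extreme tables are as extreme: 2 / C(20, 10)
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert res.p_value == pytest.approx(1.083e-5, abs=2e-8)

    def test_decision_change_proportions(self):
        # upgrade-correct rates of the two readers: 38% vs 39%
        assert 44 / 115 == pytest.approx(0.3826, abs=5e-5)
        assert 27 / 70 == pytest.approx(0.3857, abs=5e-5)
        res = compare_proportions(44, 115, 27, 70)
        assert res.method == "chi-square"
        assert res.p_value > 0.05

    def test_chi_square_against_scipy(self):
        res = compare_proportions(40, 100, 25, 110)
        chi2, p, _, _ = stats.chi2_contingency(
            [[40, 60], [25, 85]], correction=False
        )
        assert res.statistic == pytest.approx(chi2)
        assert res.p_value == pytest.approx(p)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_proportions(0, 0, 1, 10)
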