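"""Diagnostic-accuracy statistics for paired reader studies.

Everything a two-reader, two-mode diagnostic accuracy study needs once the
lesion-level verdicts exist: 2x2 metrics against the pathology gold
standard, the McNemar paired test, Cohen's kappa with the conventional
interpretation bands, the empirical ROC over ordinal ratings with the
Hanley-McNeil standard error and correlated-AUC z-test, the Youden-index
optimal cutoff, and a two-proportion comparison.

Proportions are carried as exact :class:`fractions.Fraction` ratios and
rounded (half away from zero, one decimal) only at the reporting edge, so
printed percents are reproducible to the digit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticMetrics",
    "PairedAgreementTable",
    "AgreementResult",
    "TestResult",
    "ROCResult",
    "metrics_from_table",
    "mcnemar_test",
    "cohen_kappa",
    "empirical_roc",
    "hanley_mcneil_se",
    "compare_auc_paired",
    "estimate_paired_auc_correlation",
    "youden_optimal",
    "compare_proportions",
    "percent_string",
]

#: Two-sided significance threshold used throughout the reporting layer.
ALPHA = 0.05

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy")


def percent_string(ratio: Fraction, ndigits: int = 1) -> str:
    """Render an exact ratio as a percent, rounded half away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    dec = (
        Decimal(ratio.numerator) / Decimal(ratio.denominator) * 100
    ).quantize(quantum, rounding=ROUND_HALF_UP)
    return f"{dec}"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """TP/FP/FN/TN counts of one diagnostic mode against pathology."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive_truth(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative_truth(self) -> int:
        return self.fp + self.tn

    @classmethod
    def from_verdicts(
        cls, predicted_positive: Sequence[bool], truth_positive: Sequence[bool]
    ) -> "ContingencyTable2x2":
        pred = np.asarray(predicted_positive, dtype=bool)
        truth = np.asarray(truth_positive, dtype=bool)
        if pred.shape != truth.shape:
            raise ValueError("predictions and truth must be aligned")
        return cls(
            tp=int(np.sum(pred & truth)),
            fp=int(np.sum(pred & ~truth)),
            fn=int(np.sum(~pred & truth)),
            tn=int(np.sum(~pred & ~truth)),
        )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sens/spec/PPV/NPV/accuracy as exact ratios.

    A metric whose denominator is zero is ``None`` (undefined) rather than
    an error, so degenerate strata still report the remaining metrics.
    """

    sensitivity: Optional[Fraction]
    specificity: Optional[Fraction]
    ppv: Optional[Fraction]
    npv: Optional[Fraction]
    accuracy: Optional[Fraction]

    def as_floats(self) -> dict[str, Optional[float]]:
        return {
            name: (None if v is None else float(v))
            for name, v in self._items()
        }

    def as_percent_strings(self) -> dict[str, Optional[str]]:
        """Percent strings rounded half-away-from-zero to 1 decimal."""
        return {
            name: (None if v is None else percent_string(v))
            for name, v in self._items()
        }

    def _items(self):
        return [(name, getattr(self, name)) for name in METRIC_NAMES]


def metrics_from_table(t: ContingencyTable2x2) -> DiagnosticMetrics:
    """Closed-form diagnostic proportions from a 2x2 table."""
    if t.total == 0:
        raise ValueError("empty contingency table")

    def ratio(num: int, den: int) -> Optional[Fraction]:
        if den == 0:
            warnings.warn("zero denominator; metric undefined", stacklevel=3)
            return None
        return Fraction(num, den)

    return DiagnosticMetrics(
        sensitivity=ratio(t.tp, t.tp + t.fn),
        specificity=ratio(t.tn, t.tn + t.fp),
        ppv=ratio(t.tp, t.tp + t.fp),
        npv=ratio(t.tn, t.tn + t.fn),
        accuracy=ratio(t.tp + t.tn, t.total),
    )


@dataclass(frozen=True)
class TestResult:
    """A hypothesis-test outcome; ``statistic`` may be undefined."""

    statistic: Optional[float]
    p_value: Optional[float]
    method: str

    @property
    def significant(self) -> Optional[bool]:
        if self.p_value is None:
            return None
        return self.p_value < ALPHA


def mcnemar_test(b: int, c: int, mode: str = "auto") -> TestResult:
    """McNemar test on the discordant pair counts of two paired modes.

    ``b`` and ``c`` are the two off-diagonal cells of the paired 2x2
    cross-tabulation.  ``mode`` selects the variant:

    * ``exact`` — two-sided binomial tail with success probability 1/2 over
      the ``b + c`` discordant pairs;
    * ``asymptotic`` — continuity-corrected chi-square,
      ``(|b - c| - 1)^2 / (b + c)`` on 1 df;
    * ``auto`` — exact when ``b + c < 25``, asymptotic otherwise.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    n = b + c
    if n == 0:
        return TestResult(statistic=None, p_value=1.0, method="exact")
    if mode == "auto":
        mode = "exact" if n < 25 else "asymptotic"
    if mode == "exact":
        k = min(b, c)
        p = min(1.0, 2.0 * float(stats.binom.cdf(k, n, 0.5)))
        return TestResult(statistic=float(k), p_value=p, method="exact")
    chi2 = (abs(b - c) - 1) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(statistic=chi2, p_value=p, method="continuity-corrected")


@dataclass(frozen=True)
class PairedAgreementTable:
    """2x2 cross-tabulation of two raters' dichotomous calls.

    ``pp``: both positive; ``pn``: rater 1 positive, rater 2 negative;
    ``np``: rater 1 negative, rater 2 positive; ``nn``: both negative.
    """

    pp: int
    pn: int
    np: int
    nn: int

    def __post_init__(self) -> None:
        for name in ("pp", "pn", "np", "nn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total == 0:
            raise ValueError("empty agreement table")

    @property
    def total(self) -> int:
        return self.pp + self.pn + self.np + self.nn

    @property
    def discordants(self) -> tuple[int, int]:
        return self.pn, self.np

    @classmethod
    def from_verdicts(
        cls, rater1_positive: Sequence[bool], rater2_positive: Sequence[bool]
    ) -> "PairedAgreementTable":
        r1 = np.asarray(rater1_positive, dtype=bool)
        r2 = np.asarray(rater2_positive, dtype=bool)
        if r1.shape != r2.shape:
            raise ValueError("rater sequences must be aligned")
        return cls(
            pp=int(np.sum(r1 & r2)),
            pn=int(np.sum(r1 & ~r2)),
            np=int(np.sum(~r1 & r2)),
            nn=int(np.sum(~r1 & ~r2)),
        )


#: Conventional interpretation bands for Cohen's kappa.
KAPPA_BANDS = (
    (Fraction(1, 5), "poor"),
    (Fraction(2, 5), "fair"),
    (Fraction(3, 5), "moderate"),
    (Fraction(4, 5), "good"),
    (Fraction(1, 1), "perfect"),
)


@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    observed_agreement: float
    chance_agreement: float
    band: str
    kappa_exact: Fraction = field(repr=False)

    @property
    def kappa_rounded(self) -> float:
        """Kappa to 2 decimals, half away from zero (reporting style)."""
        dec = (
            Decimal(self.kappa_exact.numerator)
            / Decimal(self.kappa_exact.denominator)
        ).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
        return float(dec)


def _kappa_band(kappa: Fraction) -> str:
    for upper, name in KAPPA_BANDS:
        if kappa <= upper:
            return name
    return "perfect"


def cohen_kappa(t: PairedAgreementTable) -> AgreementResult:
    """Cohen's kappa with banded interpretation.

    Bands: poor <= 0.2 < fair <= 0.4 < moderate <= 0.6 < good <= 0.8
    < perfect <= 1.  Computed exactly in rational arithmetic; raises if
    chance agreement is 1 (kappa undefined).
    """
    n = t.total
    p_o = Fraction(t.pp + t.nn, n)
    r1_pos = Fraction(t.pp + t.pn, n)
    r2_pos = Fraction(t.pp + t.np, n)
    p_e = r1_pos * r2_pos + (1 - r1_pos) * (1 - r2_pos)
    if p_e == 1:
        raise ZeroDivisionError("chance agreement is 1; kappa undefined")
    kappa = (p_o - p_e) / (1 - p_e)
    return AgreementResult(
        kappa=float(kappa),
        observed_agreement=float(p_o),
        chance_agreement=float(p_e),
        band=_kappa_band(kappa),
        kappa_exact=kappa,
    )


# ---------------------------------------------------------------------------
# ROC / AUC machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC over ordinal scores, higher score = more suspicious.

    ``operating_points`` runs from (0, 0) to (1, 1) as (1 - specificity,
    sensitivity) pairs, one per achievable threshold.  ``thresholds`` holds
    the cutoff attached to each interior point: the midpoint between the
    two adjacent achievable score values (so a 0-4 plane-count scale yields
    cutoffs 0.5, 1.5, 2.5, 3.5).
    """

    operating_points: tuple[tuple[float, float], ...]
    thresholds: tuple[float, ...]
    auc: float
    se_auc: float
    youden_j: float
    optimal_cutoff: Optional[float]
    n_pos: int
    n_neg: int


def empirical_roc(
    scores: Sequence[float], truth: Sequence[bool]
) -> ROCResult:
    """Empirical ROC of ordinal scores against a dichotomous truth.

    The AUC (trapezoidal) equals the tie-corrected pairwise statistic
    (concordant pairs + half the tied pairs) / (n_pos * n_neg).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and truth must be aligned 1-d sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    values = np.unique(s)  # ascending
    # counts per distinct value, by class
    pos_counts = np.array([(s[y] == v).sum() for v in values], dtype=float)
    neg_counts = np.array([(s[~y] == v).sum() for v in values], dtype=float)
    # classify positive iff score >= values[j]; j from len..0 sweeps (0,0)->(1,1)
    tp_at = np.concatenate(([0.0], np.cumsum(pos_counts[::-1])))  # j = m..0
    fp_at = np.concatenate(([0.0], np.cumsum(neg_counts[::-1])))
    tpr = tp_at / n_pos
    fpr = fp_at / n_neg
    points = tuple(zip(fpr.tolist(), tpr.tolist()))

    # interior thresholds: midpoints between adjacent distinct values,
    # aligned with points[1:-1]
    mids = ((values[:-1] + values[1:]) / 2.0)[::-1]
    thresholds = tuple(mids.tolist())

    auc = float(np.trapezoid(tpr, fpr))
    se = hanley_mcneil_se(auc, n_pos, n_neg)

    j_values = tpr - fpr
    youden_j = float(j_values.max())
    optimal_cutoff: Optional[float] = None
    if len(thresholds) > 0:
        interior_j = j_values[1:-1]
        best = interior_j.max()
        # rationally equal J values may differ in the last float bit, so
        # tie detection uses a small absolute tolerance; ties broken toward
        # higher sensitivity
        candidates = np.flatnonzero(interior_j >= best - 1e-12)
        pick = candidates[np.argmax(tpr[1:-1][candidates])]
        optimal_cutoff = float(thresholds[pick])

    return ROCResult(
        operating_points=points,
        thresholds=thresholds,
        auc=auc,
        se_auc=se,
        youden_j=youden_j,
        optimal_cutoff=optimal_cutoff,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def youden_optimal(roc: ROCResult) -> tuple[float, float]:
    """Youden-optimal cutoff and index J = max(sens + spec - 1).

    The cutoff is the midpoint between the two adjacent achievable score
    values bracketing the maximizing threshold; ties broken toward higher
    sensitivity.  Requires at least one interior operating point.
    """
    if roc.optimal_cutoff is None:
        raise ValueError("ROC has no interior operating point")
    interior = roc.operating_points[1:-1]
    j = max(tpr - fpr for fpr, tpr in interior)
    return roc.optimal_cutoff, float(j)


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an empirical AUC.

    With A the AUC, Q1 = A / (2 - A) and Q2 = 2 A^2 / (1 + A):

        SE^2 = [A(1-A) + (n_pos - 1)(Q1 - A^2) + (n_neg - 1)(Q2 - A^2)]
               / (n_pos * n_neg)
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("each class needs at least one observation")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    # float round-off can push a degenerate variance a hair below zero
    return math.sqrt(max(var, 0.0))


def compare_auc_paired(
    auc1: float, auc2: float, se1: float, se2: float, r: float = 0.0
) -> TestResult:
    """z-test for the difference of two (possibly correlated) AUCs.

        z = (A1 - A2) / sqrt(se1^2 + se2^2 - 2 r se1 se2)

    ``r`` is the correlation between the two AUC estimates (0 reduces to
    the unpaired comparison).  A zero denominator yields an undefined
    statistic, signalled by ``statistic=None``.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be >= 0")
    var = se1 * se1 + se2 * se2 - 2.0 * r * se1 * se2
    if var <= 0.0:
        if auc1 == auc2:
            return TestResult(statistic=None, p_value=1.0, method="degenerate")
        return TestResult(statistic=None, p_value=None, method="degenerate")
    z = (auc1 - auc2) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return TestResult(statistic=z, p_value=p, method="hanley-mcneil-z")


def estimate_paired_auc_correlation(
    scores1: Sequence[float], scores2: Sequence[float], truth: Sequence[bool]
) -> float:
    """Correlation input for :func:`compare_auc_paired` from paired ratings.

    Average of the Spearman rank correlations between the two score sets
    within the positive class and within the negative class, clipped to
    [0, 1].  A class whose scores are constant in either set contributes
    nothing (dropped with a warning).
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if not (s1.shape == s2.shape == y.shape):
        raise ValueError("scores and truth must be aligned")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    terms = []
    for mask, label in ((y, "positive"), (~y, "negative")):
        a, b = s1[mask], s2[mask]
        if np.unique(a).size < 2 or np.unique(b).size < 2:
            warnings.warn(
                f"constant scores within the {label} class; term dropped",
                stacklevel=2,
            )
            continue
        rho = float(stats.spearmanr(a, b).statistic)
        if not math.isnan(rho):
            terms.append(rho)
    if not terms:
        return 0.0
    return float(np.clip(np.mean(terms), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Two-proportion comparison
# ---------------------------------------------------------------------------

def compare_proportions(a: int, n1: int, b: int, n2: int) -> TestResult:
    """Two-sided comparison of two independent proportions a/n1 vs b/n2.

    Pearson chi-square without continuity correction by default; falls back
    to the exact conditional (Fisher) test when any expected cell count is
    below 5 or any observed cell is empty.
    """
    if not (0 <= a <= n1) or not (0 <= b <= n2):
        raise ValueError("counts must satisfy 0 <= a <= n1 and 0 <= b <= n2")
    if n1 == 0 or n2 == 0:
        raise ValueError("group sizes must be positive")
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    expected = np.outer(row, col) / table.sum()
    if (expected < 5).any() or (table == 0).any():
        res = stats.fisher_exact(table, alternative="two-sided")
        return TestResult(statistic=None, p_value=float(res.pvalue), method="exact")
    if a / n1 == b / n2:
        return TestResult(statistic=0.0, p_value=1.0, method="chi-square")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(chi2), p_value=float(p), method="chi-square")
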