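"""Binary-call evaluation and association statistics.

Confusion-table metrics (sensitivity, specificity, accuracy, false
positive/negative rates), ROC/AUC, Fisher's exact test, Pearson's
chi-squared, Mann-Whitney U and Spearman rank correlation — the toolkit
used to evaluate methylation calls against clinical outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "ConfusionTable",
    "DiagnosticReport",
    "RocResult",
    "confusion_metrics",
    "roc_auc",
    "fisher_exact_2x2",
    "pearson_chi2",
    "mann_whitney_u",
    "spearman_rho",
]


@dataclass
class ConfusionTable:
    """2x2 counts of predicted vs observed binary outcome (positive = event)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_calls(cls, predicted, observed) -> "ConfusionTable":
        pred = np.asarray(predicted, dtype=bool)
        obs = np.asarray(observed, dtype=bool)
        if pred.shape != obs.shape:
            raise ValueError("predicted and observed must have equal length")
        return cls(
            tp=int(np.sum(pred & obs)),
            fp=int(np.sum(pred & ~obs)),
            tn=int(np.sum(~pred & ~obs)),
            fn=int(np.sum(~pred & obs)),
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiagnosticReport:
    """Threshold-fixed classifier performance, as fractions in [0, 1]."""

    sensitivity: float
    specificity: float
    accuracy: float
    false_positive_rate: float
    false_negative_rate: float
    table: ConfusionTable

    def percent(self, digits: int = 1) -> dict[str, float]:
        """Metrics as percentages rounded to ``digits`` decimals (0.1% default)."""
        return {
            "sensitivity": round(100.0 * self.sensitivity, digits),
            "specificity": round(100.0 * self.specificity, digits),
            "accuracy": round(100.0 * self.accuracy, digits),
            "false_positive_rate": round(100.0 * self.false_positive_rate, digits),
            "false_negative_rate": round(100.0 * self.false_negative_rate, digits),
        }


@dataclass
class RocResult:
    """ROC curve points (all thresholds, ties stepped together) and trapezoid AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion_metrics(table: ConfusionTable) -> DiagnosticReport:
    """Sensitivity, specificity, accuracy and error rates from a 2x2 table.

    Requires at least one observed positive and one observed negative so
    every metric is defined.
    """
    pos = table.tp + table.fn
    neg = table.tn + table.fp
    if pos < 1 or neg < 1:
        raise ValueError("both outcome classes must be represented (empty margin)")
    sens = table.tp / pos
    spec = table.tn / neg
    acc = (table.tp + table.tn) / table.total
    return DiagnosticReport(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        false_positive_rate=1.0 - spec,
        false_negative_rate=1.0 - sens,
        table=table,
    )


def roc_auc(scores, labels) -> RocResult:
    """ROC over all score thresholds (higher score = positive) with trapezoid AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, thresh = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresh, auc=auc)


def _enumerate_fisher(a: int, b: int, c: int, d: int):
    """Hypergeometric pmf over all tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    return ks, pmf


def fisher_exact_2x2(table, mid_p: bool = False):
    """Two-sided Fisher's exact test with the odds ratio for a 2x2 table.

    The two-sided p-value sums the hypergeometric probabilities of every
    margin-fixed table no more likely than the observed one (the
    minimum-likelihood convention).  ``mid_p=True`` instead counts the
    observed table's own probability at half weight.  The odds ratio is
    (a*d)/(b*c); a zero in b or c gives ``inf``, an undefined 0/0 gives NaN.

    Returns ``(p_value, odds_ratio)``.
    """
    (a, b), (c, d) = [[int(x) for x in row] for row in table]
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("table is all zero")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    if mid_p:
        ks, pmf = _enumerate_fisher(a, b, c, d)
        p_obs = float(pmf[ks == a][0])
        lesser = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
        p = lesser - 0.5 * p_obs
    else:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(min(p, 1.0)), odds


def pearson_chi2(table):
    """Pearson's chi-squared test of independence on an r x c count table.

    No continuity correction.  Returns ``(statistic, p_value, dof)``; a zero
    expected cell raises (degenerate margins).
    """
    arr = np.asarray(table, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin: expected counts undefined")
    stat, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p), int(dof)


def mann_whitney_u(x, y):
    """Mann-Whitney U (midrank ties) with a two-sided p-value.

    Exact enumeration for small tie-free samples (both n <= 20); normal
    approximation with tie correction otherwise.  Returns ``(U_x, p)`` with
    U counted for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y):
    """Spearman rank correlation (Pearson on midranks) with t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
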