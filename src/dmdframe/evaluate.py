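"""Diagnostic performance and the cohort-level statistical comparisons.

DMD is the positive class throughout.  Sensitivity is the fraction of true
DMD cases called DMD, specificity the fraction of true BMD cases called
BMD, and the *diagnostic coincidence rate* is overall accuracy,
(tp + tn) / n.  Pairs where either the truth or the prediction is
indeterminate are excluded from the 2x2 table and tallied separately.

Two rules' coincidence rates are compared with an uncorrected Pearson
chi-square on the (correct, incorrect) x (rule A, rule B) table, treating
the two rule evaluations as independent samples even when they score the
same patients.  That construction is the conventional one in the clinical
literature this package mirrors; a paired McNemar test on the discordant
pairs is offered as the statistically orthodox alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .classify import PhenotypeLabel

__all__ = [
    "ComparisonResult",
    "ConfusionTable",
    "DiagnosticPerformance",
    "compare_coincidence_chi2",
    "diagnostic_performance",
    "mcnemar_paired",
    "two_sample_t_from_summary",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts with DMD as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    @property
    def n_correct(self) -> int:
        return self.tp + self.tn


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Rates derived from a confusion table, raw fractions retained.

    A rate whose denominator is zero (no positives, or no negatives) is
    ``None`` — reported as missing, never coerced to 0.
    """

    table: ConfusionTable
    n_indeterminate: int = 0

    @property
    def sensitivity(self) -> float | None:
        d = self.table.n_positive
        return self.table.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.table.n_negative
        return self.table.tn / d if d else None

    @property
    def coincidence_rate(self) -> float | None:
        d = self.table.n
        return self.table.n_correct / d if d else None

    def as_dict(self, ndigits: int = 2) -> dict:
        """Report block with percentages rounded for display (raw values
        live on the dataclass)."""

        def pct(x: float | None) -> float | None:
            return None if x is None else round(100.0 * x, ndigits)

        t = self.table
        return {
            "n": t.n,
            "tp": t.tp,
            "fn": t.fn,
            "fp": t.fp,
            "tn": t.tn,
            "n_indeterminate": self.n_indeterminate,
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "coincidence_rate_pct": pct(self.coincidence_rate),
        }


def diagnostic_performance(
    truth: list[PhenotypeLabel], predicted: list[PhenotypeLabel]
) -> DiagnosticPerformance:
    """Score predictions against ground truth (positive class: DMD)."""
    if len(truth) != len(predicted):
        raise ValueError(
            f"truth ({len(truth)}) and predicted ({len(predicted)}) differ in length"
        )
    tp = fn = fp = tn = skipped = 0
    for t, p in zip(truth, predicted):
        t, p = PhenotypeLabel(t), PhenotypeLabel(p)
        if PhenotypeLabel.INDETERMINATE in (t, p):
            skipped += 1
        elif t is PhenotypeLabel.DMD:
            tp, fn = (tp + 1, fn) if p is PhenotypeLabel.DMD else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if p is PhenotypeLabel.BMD else (tn, fp + 1)
    return DiagnosticPerformance(
        table=ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn), n_indeterminate=skipped
    )


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    df: float
    method: str
    warning: str | None = None


def compare_coincidence_chi2(
    a: DiagnosticPerformance,
    b: DiagnosticPerformance,
    correction: bool = False,
) -> ComparisonResult:
    """Pearson chi-square comparing two rules' coincidence rates.

    Builds the (correct, incorrect) x (rule A, rule B) contingency table
    and tests homogeneity at 1 df.  Continuity (Yates) correction is off by
    default; a warning is attached when any expected cell is below 1.
    """
    rows = []
    for perf in (a, b):
        t = perf.table
        if t.n == 0:
            raise ValueError("cannot compare a performance with an empty 2x2 table")
        rows.append([t.n_correct, t.n - t.n_correct])
    chi2, p, df, expected = stats.chi2_contingency(rows, correction=correction)
    warning = None
    if (expected < 1).any():
        warning = "expected cell count below 1; chi-square approximation unreliable"
    return ComparisonResult(
        statistic=float(chi2),
        p_value=float(p),
        df=float(df),
        method="pearson_chi2_yates" if correction else "pearson_chi2",
        warning=warning,
    )


def mcnemar_paired(
    truth: list[PhenotypeLabel],
    pred_a: list[PhenotypeLabel],
    pred_b: list[PhenotypeLabel],
    exact: bool = True,
) -> ComparisonResult:
    """Paired McNemar test on per-patient correctness of two rules.

    The orthodox paired alternative to :func:`compare_coincidence_chi2`
    when both rules score the same patients; not the construction used for
    the headline comparison, which this package replicates as published.
    Pairs with an indeterminate truth or prediction on either side are
    dropped.
    """
    b = c = 0
    for t, pa, pb in zip(truth, pred_a, pred_b, strict=True):
        if PhenotypeLabel.INDETERMINATE in (PhenotypeLabel(t), PhenotypeLabel(pa), PhenotypeLabel(pb)):
            continue
        ok_a, ok_b = pa == t, pb == t
        if ok_a and not ok_b:
            b += 1
        elif ok_b and not ok_a:
            c += 1
    n_disc = b + c
    if exact:
        p = float(stats.binomtest(min(b, c), n_disc, 0.5).pvalue) if n_disc else 1.0
        return ComparisonResult(
            statistic=float(min(b, c)), p_value=p, df=math.nan, method="mcnemar_exact"
        )
    chi2 = (abs(b - c) - 1) ** 2 / n_disc if n_disc else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if n_disc else 1.0
    return ComparisonResult(statistic=chi2, p_value=p, df=1.0, method="mcnemar_cc")


def two_sample_t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    pooled: bool = True,
) -> tuple[float, float, float]:
    """Two-sided two-sample t test from summary statistics.

    Pooled-variance Student t by default (the convention in the clinical
    tables this package reproduces); ``pooled=False`` gives Welch.
    Returns ``(t, df, p)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=pooled
    )
    if pooled:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), df, float(res.pvalue)
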