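"""Accuracy and agreement statistics for dental-age estimates.

Covers the standard evaluation battery for an age-estimation method:

* :func:`bias_report` — DA-CA bias: mean difference with t-based and
  bootstrap confidence intervals, one-sample and paired t tests, absolute
  deviation summaries in half-year bins, and the conventional accuracy bands
  (|DA-CA| < 1 yr accurate, > 2 yr inaccurate).
* :func:`correlation_report` — Pearson's r and Spearman's rho.
* :func:`cohen_kappa` / :func:`rater_comparison` — unweighted (optionally
  linear/quadratic weighted) Cohen's kappa per tooth between two raters.
* :func:`method_comparison` — paired dental ages under two reference-table
  sets (e.g. a local calibration against the original standard).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from .core import FDI_TEETH, DentalChart
from .calibration import CohortDataset
from .conversion import score_to_age
from .errors import (
    ConstantInput,
    CoverageError,
    LengthMismatch,
    PerfectExpectedAgreement,
    StageBelowCoverage,
    SubjectMismatch,
)
from .scoring import total_maturity_score
from .tables import ReferenceTables

__all__ = [
    "BiasReport",
    "CorrelationReport",
    "RaterComparison",
    "MethodComparison",
    "bias_report",
    "correlation_report",
    "cohen_kappa",
    "agreement_label",
    "rater_comparison",
    "method_comparison",
]

DEFAULT_BOOTSTRAP = 2000
HIST_BIN_WIDTH = 0.5


@dataclass(frozen=True)
class BiasReport:
    """Bias (DA - CA) statistics for paired age vectors."""

    n: int
    mean_diff: float
    sd: float
    ci95: Tuple[float, float]
    p_one_sample: float
    p_paired: float
    t_statistic: float
    bootstrap_ci95: Tuple[float, float]
    median_abs_dev: float
    abs_dev_histogram: Tuple[Tuple[float, float, int], ...]  # (lo, hi, count)
    pct_within_1yr: float
    pct_beyond_2yr: float
    degenerate_variance: bool = False

    def summary(self) -> str:
        lines = [
            f"n:               {self.n}",
            f"mean DA-CA:      {self.mean_diff:+.3f} yr  (SD {self.sd:.3f})",
            f"95% CI:          ({self.ci95[0]:+.3f}, {self.ci95[1]:+.3f})",
            f"bootstrap CI:    ({self.bootstrap_ci95[0]:+.3f}, {self.bootstrap_ci95[1]:+.3f})",
            f"one-sample t:    t={self.t_statistic:.3f}, p={self.p_one_sample:.4g}"
            + ("  [degenerate variance]" if self.degenerate_variance else ""),
            f"median |DA-CA|:  {self.median_abs_dev:.3f} yr",
            f"within 1 yr:     {self.pct_within_1yr:.1f}%    beyond 2 yr: {self.pct_beyond_2yr:.1f}%",
        ]
        return "\n".join(lines)


def bias_report(
    da: Sequence[float],
    ca: Sequence[float],
    *,
    seed: int,
    n_boot: int = DEFAULT_BOOTSTRAP,
) -> BiasReport:
    """Full bias battery on paired dental/chronological ages.

    The bootstrap CI is a seeded percentile bootstrap of the mean difference
    (``n_boot`` resamples); ``seed`` is mandatory so reports are reproducible.
    When all differences are equal the t statistic is undefined and the
    report is flagged ``degenerate_variance`` with NaN p-values.
    """
    da = np.asarray(da, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if da.shape != ca.shape or da.ndim != 1:
        raise LengthMismatch(f"paired vectors must be equal-length 1-d, got {da.shape} vs {ca.shape}")
    n = len(da)
    if n < 2:
        raise LengthMismatch("need at least 2 pairs")
    diffs = da - ca
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        t_stat = p_one = p_paired = float("nan")
        ci = (mean, mean)
    else:
        t_res = sps.ttest_1samp(diffs, 0.0)
        t_stat, p_one = float(t_res.statistic), float(t_res.pvalue)
        p_paired = float(sps.ttest_rel(da, ca).pvalue)
        half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        ci = (mean - half, mean + half)
    rng = np.random.default_rng(seed)
    boot = rng.choice(diffs, size=(n_boot, n), replace=True).mean(axis=1)
    boot_ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    abs_dev = np.abs(diffs)
    n_bins = max(1, int(np.ceil((abs_dev.max() + 1e-12) / HIST_BIN_WIDTH)))
    edges = HIST_BIN_WIDTH * np.arange(n_bins + 1)
    counts, _ = np.histogram(abs_dev, bins=edges)
    hist = tuple(
        (float(edges[i]), float(edges[i + 1]), int(counts[i])) for i in range(n_bins)
    )
    return BiasReport(
        n=n,
        mean_diff=mean,
        sd=sd,
        ci95=ci,
        p_one_sample=p_one,
        p_paired=p_paired,
        t_statistic=t_stat,
        bootstrap_ci95=boot_ci,
        median_abs_dev=float(np.median(abs_dev)),
        abs_dev_histogram=hist,
        pct_within_1yr=float(100.0 * np.mean(abs_dev < 1.0)),
        pct_beyond_2yr=float(100.0 * np.mean(abs_dev > 2.0)),
        degenerate_variance=degenerate,
    )


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson and Spearman correlation between two paired vectors."""

    n: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


def correlation_report(x: Sequence[float], y: Sequence[float]) -> CorrelationReport:
    """Pearson's r and Spearman's rho (midrank ties) with p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise LengthMismatch(f"paired vectors must be equal-length 1-d, got {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise LengthMismatch("need at least 3 pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInput("correlation is undefined for a constant vector")
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    return CorrelationReport(
        n=len(x),
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
    )


def cohen_kappa(
    r1: Sequence[str],
    r2: Sequence[str],
    weights: Optional[str] = None,
) -> float:
    """Cohen's kappa between two categorical rating vectors.

    Unweighted by default; pass ``weights="linear"`` or ``"quadratic"`` for
    the ordinal-weighted variants.  Raises
    :class:`PerfectExpectedAgreement` when both raters use a single shared
    category (chance agreement 1, kappa undefined).
    """
    r1, r2 = list(r1), list(r2)
    if len(r1) != len(r2):
        raise LengthMismatch(f"rating vectors differ in length: {len(r1)} vs {len(r2)}")
    if len(r1) == 0:
        raise LengthMismatch("empty rating vectors")
    if len(set(r1)) == 1 and set(r1) == set(r2):
        raise PerfectExpectedAgreement(
            "both raters used the single category "
            f"{r1[0]!r}; chance agreement is 1 and kappa is undefined"
        )
    return float(cohen_kappa_score(r1, r2, weights=weights))


def agreement_label(kappa: float) -> str:
    """Altman's qualitative band for a kappa value (poor .. very good)."""
    if kappa < 0.2:
        return "poor"
    if kappa < 0.4:
        return "fair"
    if kappa < 0.6:
        return "moderate"
    if kappa <= 0.8:
        return "good"
    return "very good"


@dataclass(frozen=True)
class RaterComparison:
    """Per-tooth kappa between two raters and its arithmetic mean."""

    per_tooth_kappa: Mapping[int, float]
    mean_kappa: float
    n_subjects: int


def rater_comparison(
    charts1: Mapping[str, DentalChart],
    charts2: Mapping[str, DentalChart],
    weights: Optional[str] = None,
) -> RaterComparison:
    """Kappa per tooth over a common set of subjects, plus the 7-tooth mean."""
    ids1, ids2 = set(charts1), set(charts2)
    if ids1 != ids2:
        raise SubjectMismatch(
            f"rating sets cover different subjects ({len(ids1 - ids2)} only in first, "
            f"{len(ids2 - ids1)} only in second)"
        )
    order = sorted(ids1)
    per_tooth = {}
    for fdi in FDI_TEETH:
        a = [charts1[i].stage(fdi) for i in order]
        b = [charts2[i].stage(fdi) for i in order]
        try:
            per_tooth[fdi] = cohen_kappa(a, b, weights=weights)
        except PerfectExpectedAgreement:
            # both raters used a single shared stage, which means they agree
            # on every subject: report perfect agreement for the tooth
            per_tooth[fdi] = 1.0
    return RaterComparison(
        per_tooth_kappa=per_tooth,
        mean_kappa=float(np.mean(list(per_tooth.values()))),
        n_subjects=len(order),
    )


@dataclass(frozen=True)
class MethodComparison:
    """Paired dental ages under two table sets with bias and correlation."""

    subject_ids: Tuple[str, ...]
    da_a: np.ndarray
    da_b: np.ndarray
    bias: BiasReport  # on DA(a) - DA(b)
    correlation: CorrelationReport


def method_comparison(
    cohort: CohortDataset,
    tables_a: ReferenceTables,
    tables_b: ReferenceTables,
    *,
    seed: int,
) -> MethodComparison:
    """Compare the dental ages two reference-table sets assign to one cohort.

    Both sets must cover every observed (sex, tooth, stage); a gap raises
    :class:`CoverageError` naming the failing population.
    """
    ids, da_a, da_b = [], [], []
    for subject in cohort.subjects:
        row = []
        for tables in (tables_a, tables_b):
            try:
                total = total_maturity_score(tables.score_table, subject).total
            except StageBelowCoverage as exc:
                raise CoverageError(
                    f"table set {tables.population!r} cannot score subject "
                    f"{subject.id}: {exc}"
                ) from exc
            row.append(score_to_age(tables.grid(subject.sex), total).dental_age)
        ids.append(subject.id)
        da_a.append(row[0])
        da_b.append(row[1])
    da_a = np.asarray(da_a)
    da_b = np.asarray(da_b)
    return MethodComparison(
        subject_ids=tuple(ids),
        da_a=da_a,
        da_b=da_b,
        bias=bias_report(da_a, da_b, seed=seed),
        correlation=correlation_report(da_a, da_b),
    )
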