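"""Test-retest stability statistics for discounting measures.

Two complementary views of stability across repeated sessions:

* *Relative* stability — do participants keep their rank order?  Assessed
  with Pearson correlations between time points, with a default Bayes
  factor quantifying the evidence for a nonzero population correlation.
  The Bayes factor uses the exact sampling density of the sample
  correlation r under a stretched-beta prior on the population correlation
  (width ``kappa``, default 1, i.e. uniform on (-1, 1)), the two-sided
  default used by common Bayesian software.
* *Absolute* stability / trait-vs-state decomposition — the intraclass
  correlation from a two-way model with absolute agreement, single
  measures: ICC = (MSR - MSE) / (MSR + (k-1)MSE + k(MSC - MSE)/n).
  ICC x 100% is read as the share of variance attributable to stable
  between-subject (trait-like) differences; the complement is
  within-subject (state-like).

Interpretation bands follow the conventional cutoffs: correlations are
weak (|r| <= .35), moderate (.36-.67), strong (.68-.9) or very strong
(>= .9); Bayes factors 0.3-3 are weak evidence, 3-10 moderate and > 10
strong for H1 (mirrored below 1/3 for H0); ICCs below 0.50 are poor,
0.50-0.75 moderate, 0.75-0.90 good, above 0.90 excellent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "BayesCorrelation",
    "ICCResult",
    "pearson_r",
    "bf10_pearson",
    "classify_r",
    "classify_bf",
    "classify_icc",
    "zscore",
    "icc_absolute_agreement",
    "StabilityAnalysis",
    "StabilityResults",
]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; errors on constant input."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def _log_lik_rho(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    """Log of the exact density of the sample correlation r given rho,
    dropping rho-free factors.  Hypergeometric form of the classical
    sampling distribution."""
    rho = np.asarray(rho, dtype=float)
    return (
        (n - 1) / 2 * np.log1p(-(rho**2))
        - (2 * n - 3) / 2 * np.log1p(-rho * r)
        + np.log(special.hyp2f1(0.5, 0.5, (2 * n - 1) / 2, (rho * r + 1) / 2))
    )


def _log_prior(rho: np.ndarray, kappa: float) -> np.ndarray:
    a = 1.0 / kappa
    return (
        (a - 1) * np.log1p(-np.asarray(rho, dtype=float) ** 2)
        - math.log(special.beta(a, a))
        - (2 * a - 1) * math.log(2.0)
    )


@dataclass(frozen=True)
class BayesCorrelation:
    """A Pearson correlation with its default Bayes factor and posterior CI."""

    r: float
    n: int
    kappa: float
    bf10: float
    rho_ci: tuple[float, float]

    @property
    def r_band(self) -> str:
        return classify_r(self.r)

    @property
    def bf_band(self) -> str:
        return classify_bf(self.bf10)

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "n": self.n,
            "kappa": self.kappa,
            "bf10": self.bf10,
            "rho_ci": list(self.rho_ci),
            "r_band": self.r_band,
            "bf_band": self.bf_band,
        }


def bf10_pearson(
    r: float, n: int, kappa: float = 1.0, ci_level: float = 0.95
) -> BayesCorrelation:
    """Default Bayes factor for a nonzero correlation, from r and n alone.

    BF10 is the ratio of the marginal likelihood of r under the
    stretched-beta prior on the population correlation to its likelihood
    at rho = 0, evaluated by adaptive quadrature over (-1, 1).  Also
    returns the central posterior interval for the correlation.

    The two-sided factor is symmetric in the sign of r and increasing in
    |r| at fixed n.
    """
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be < 1")
    if n < 3:
        raise ValueError("need n >= 3")
    if kappa <= 0:
        raise ValueError("kappa must be positive")

    ll0 = _log_lik_rho(np.array(0.0), r, n)

    def integrand(rho):
        return np.exp(_log_lik_rho(rho, r, n) - ll0 + _log_prior(rho, kappa))

    bf, err = integrate.quad(integrand, -1.0, 1.0, limit=200)
    if not np.isfinite(bf) or bf <= 0 or (bf > 1e-12 and err / bf > 1e-6):
        raise RuntimeError(
            f"Bayes-factor quadrature did not converge (value={bf}, err={err})"
        )

    # posterior CI on a dense grid
    grid = np.linspace(-1 + 1e-9, 1 - 1e-9, 20001)
    logp = _log_lik_rho(grid, r, n) + _log_prior(grid, kappa)
    p = np.exp(logp - logp.max())
    cdf = integrate.cumulative_trapezoid(p, grid, initial=0.0)
    cdf /= cdf[-1]
    alpha = (1.0 - ci_level) / 2.0
    lo = float(np.interp(alpha, cdf, grid))
    hi = float(np.interp(1.0 - alpha, cdf, grid))
    return BayesCorrelation(r=float(r), n=int(n), kappa=float(kappa), bf10=float(bf), rho_ci=(lo, hi))


def classify_r(r: float) -> str:
    """Strength band for a correlation coefficient (classified on |r|)."""
    a = abs(r)
    if a > 1:
        raise ValueError("|r| must be <= 1")
    if a <= 0.35:
        return "weak"
    if a <= 0.67:
        return "moderate"
    if a < 0.9:
        return "strong"
    return "very strong"


def classify_bf(bf10: float) -> str:
    """Evidence band for a Bayes factor BF10.

    The published bands cover the H1 side (0.3-3 weak, 3-10 moderate,
    > 10 strong); values below 0.3 are mirrored onto the H0 side
    (1/10-1/3 moderate H0, below 1/10 strong H0) for completeness.
    """
    if bf10 <= 0:
        raise ValueError("bf10 must be positive")
    if bf10 > 10:
        return "strong H1"
    if bf10 >= 3:
        return "moderate H1"
    if bf10 >= 0.3:
        return "weak"
    if bf10 >= 0.1:
        return "moderate H0"
    return "strong H0"


def zscore(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0 and sample (ddof=1) standard deviation 1."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("z-scores undefined for constant input")
    return (v - v.mean()) / sd


@dataclass(frozen=True)
class ICCResult:
    """Absolute-agreement single-measure ICC with its F-based 95% CI."""

    icc: float
    ci95: tuple[float, float]
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_raters: int

    @property
    def band(self) -> str:
        return classify_icc(self.icc)

    @property
    def pct_between(self) -> float:
        """ICC x 100: percent of variance attributed to trait-like
        (between-subject) differences."""
        return self.icc * 100.0

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "ci95": list(self.ci95),
            "ms_rows": self.ms_rows,
            "ms_cols": self.ms_cols,
            "ms_error": self.ms_error,
            "n_subjects": self.n_subjects,
            "k_raters": self.k_raters,
            "band": self.band,
            "pct_between": self.pct_between,
        }


def classify_icc(icc: float) -> str:
    """Reliability band for an intraclass correlation."""
    if icc > 1:
        raise ValueError("icc cannot exceed 1")
    if icc < 0.50:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc <= 0.90:
        return "good"
    return "excellent"


def icc_absolute_agreement(
    matrix, ci_level: float = 0.95
) -> ICCResult:
    """Two-way, absolute-agreement, single-measure ICC from a complete
    subjects x sessions matrix.

    The coefficient is built from the two-way ANOVA mean squares
    (rows = subjects, columns = sessions):

        ICC = (MSR - MSE) / (MSR + (k-1)MSE + k(MSC - MSE)/n)

    which is the same arithmetic for the two-way random and two-way mixed
    absolute-agreement definitions.  The confidence interval uses the
    F-based method with a Satterthwaite degrees-of-freedom approximation
    for the denominator.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x sessions)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 sessions")
    if np.isnan(m).any():
        raise ValueError("matrix has missing cells; no imputation is performed")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 1.0

    # F-based CI (single measure, absolute agreement)
    alpha = 1.0 - ci_level
    if mse == 0 and msc == 0:
        lo = hi = 1.0
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if np.isfinite(a):
            v_num = (a * msc + b * mse) ** 2
            v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = v_num / v_den
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
        else:
            lo = hi = 1.0
    return ICCResult(
        icc=float(icc),
        ci95=(float(lo), float(hi)),
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        n_subjects=int(n),
        k_raters=int(k),
    )


class StabilityAnalysis:
    """Relative and absolute stability of a discounting measure over sessions.

    Built from a long AUC table with columns ``participant_id``,
    ``timepoint``, ``task`` and the chosen measure column.  ``fit`` computes,
    per task: pairwise between-timepoint correlations with Bayes factors,
    and the absolute-agreement ICC of the (optionally z-scored) measure;
    plus between-task correlations at each time point.

    Parameters
    ----------
    auc_table
        Long table, one row per participant x timepoint x task.
    measure
        Column to analyze (default ``"auc_ord"``).
    zscore_scope
        ``"pooled"`` standardizes each task's values across all
        participant x timepoint observations, preserving mean differences
        between time points so absolute agreement stays meaningful;
        ``"per_timepoint"`` standardizes within each time point (which
        erases mean shifts); ``"none"`` uses raw values.
    kappa
        Prior width for the correlation Bayes factor.
    """

    def __init__(
        self,
        auc_table: pd.DataFrame,
        measure: str = "auc_ord",
        zscore_scope: str = "pooled",
        kappa: float = 1.0,
    ):
        required = {"participant_id", "timepoint", "task", measure}
        missing = required - set(auc_table.columns)
        if missing:
            raise ValueError(f"AUC table lacks columns {sorted(missing)}")
        if zscore_scope not in ("pooled", "per_timepoint", "none"):
            raise ValueError(f"unknown zscore_scope {zscore_scope!r}")
        self.data = auc_table.copy()
        self.measure = measure
        self.zscore_scope = zscore_scope
        self.kappa = float(kappa)

    def _wide(self, task: str) -> pd.DataFrame:
        sub = self.data[self.data["task"] == task]
        wide = sub.pivot(index="participant_id", columns="timepoint", values=self.measure)
        if wide.isna().any().any():
            bad = wide[wide.isna().any(axis=1)].index.tolist()
            raise ValueError(f"task {task!r}: incomplete participants {bad}")
        return wide.sort_index()

    def fit(self) -> "StabilityResults":
        tasks = sorted(self.data["task"].unique())
        timepoints = sorted(self.data["timepoint"].unique())
        retest: dict[str, dict[tuple[int, int], BayesCorrelation]] = {}
        iccs: dict[str, ICCResult] = {}
        for task in tasks:
            wide = self._wide(task)
            retest[task] = {}
            for t1, t2 in itertools.combinations(timepoints, 2):
                r = pearson_r(wide[t1], wide[t2])
                retest[task][(t1, t2)] = bf10_pearson(r, len(wide), self.kappa)
            z = wide.to_numpy(dtype=float)
            if self.zscore_scope == "pooled":
                z = zscore(z.ravel()).reshape(z.shape)
            elif self.zscore_scope == "per_timepoint":
                z = np.column_stack([zscore(z[:, j]) for j in range(z.shape[1])])
            iccs[task] = icc_absolute_agreement(z)
        cross: dict[int, dict[tuple[str, str], BayesCorrelation]] = {}
        if len(tasks) > 1:
            for tp in timepoints:
                cross[tp] = {}
                for ta, tb in itertools.combinations(tasks, 2):
                    wa = self._wide(ta)[tp]
                    wb = self._wide(tb)[tp]
                    joined = pd.concat([wa, wb], axis=1, join="inner")
                    r = pearson_r(joined.iloc[:, 0], joined.iloc[:, 1])
                    cross[tp][(ta, tb)] = bf10_pearson(r, len(joined), self.kappa)
        return StabilityResults(self, retest, iccs, cross)


class StabilityResults:
    """Fitted stability statistics; see :class:`StabilityAnalysis`."""

    def __init__(self, analysis, retest, iccs, cross_task):
        self.analysis = analysis
        self.retest = retest
        self.iccs = iccs
        self.cross_task = cross_task

    def summary(self) -> str:
        lines = [
            f"Stability of {self.analysis.measure} "
            f"(z-score scope: {self.analysis.zscore_scope}, "
            f"kappa = {self.analysis.kappa:g})",
            "",
            "Test-retest correlations",
            f"{'task':<14}{'pair':<10}{'r':>7}{'BF10':>10}  "
            f"{'95% CI':<18}{'r band':<12}{'BF band'}",
        ]
        for task, pairs in self.retest.items():
            for (t1, t2), bc in pairs.items():
                ci = f"[{bc.rho_ci[0]:.2f}, {bc.rho_ci[1]:.2f}]"
                lines.append(
                    f"{task:<14}{f'{t1} vs {t2}':<10}{bc.r:>7.2f}{bc.bf10:>10.2f}  "
                    f"{ci:<18}{bc.r_band:<12}{bc.bf_band}"
                )
        lines += ["", "Intraclass correlations (absolute agreement, single measures)"]
        lines.append(
            f"{'task':<14}{'ICC':>6}  {'95% CI':<16}{'band':<12}{'% trait-like'}"
        )
        for task, res in self.iccs.items():
            ci = f"[{res.ci95[0]:.2f}, {res.ci95[1]:.2f}]"
            lines.append(
                f"{task:<14}{res.icc:>6.2f}  {ci:<16}{res.band:<12}"
                f"{res.pct_between:.0f}%"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "measure": self.analysis.measure,
            "zscore_scope": self.analysis.zscore_scope,
            "kappa": self.analysis.kappa,
            "retest": {
                task: {
                    f"{t1}-{t2}": bc.to_dict() for (t1, t2), bc in pairs.items()
                }
                for task, pairs in self.retest.items()
            },
            "icc": {task: res.to_dict() for task, res in self.iccs.items()},
            "cross_task": {
                str(tp): {f"{ta}|{tb}": bc.to_dict() for (ta, tb), bc in pairs.items()}
                for tp, pairs in self.cross_task.items()
            },
        }
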