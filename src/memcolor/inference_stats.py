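"""Hypothesis tests used in the residual analysis.

Pearson chi-square on 2x2 report tables (no continuity correction — the
uncorrected statistic is what the verbal-report analysis uses), Welch and
paired t-tests, a two-sided variance-ratio F test, and balanced full-factorial
ANOVA for two or three two-level factors.

p-values that underflow double precision are also reported as log10(p) so
effect magnitudes like 1e-40 remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "AnovaResult",
    "chi2_2x2",
    "welch_t",
    "paired_t",
    "variance_f_test",
    "factorial_anova",
]


class DegenerateDataError(ValueError):
    """Test preconditions violated (zero margins, zero variance, imbalance)."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    log10_p: float

    def as_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df,
                "p": self.p, "log10_p": self.log10_p}


def _result(statistic: float, df, p: float, log10_p: float | None = None) -> TestResult:
    if log10_p is None:
        log10_p = float(np.log10(p)) if p > 0 else -np.inf
    return TestResult(float(statistic), df, float(p), float(log10_p))


def chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], df = 1.

    No Yates continuity correction.  Requires all marginal totals > 0.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise DegenerateDataError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateDataError("degenerate table: a zero row or column margin")
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return _result(stat, int(df), p, stats.chi2.logsf(stat, df) / np.log(10))


def welch_t(x, y) -> TestResult:
    """Two-sample t-test not assuming equal variance (Welch–Satterthwaite)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return _result(0.0, float(len(x) + len(y) - 2), 1.0, 0.0)
        raise DegenerateDataError("both samples constant with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    logp = (stats.t.logsf(abs(res.statistic), res.df) + np.log(2)) / np.log(10)
    return _result(res.statistic, float(res.df), res.pvalue, logp)


def paired_t(x, y) -> TestResult:
    """One-sample t-test on paired differences x − y; two-sided."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DegenerateDataError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise DegenerateDataError("need n >= 2 pairs")
    d = x - y
    if d.var(ddof=1) == 0:
        if d.mean() == 0:
            return _result(0.0, float(len(d) - 1), 1.0, 0.0)
        # all differences equal and nonzero: evidence is unbounded; report
        # an infinite statistic with the minimal representable p
        return _result(np.inf * np.sign(d.mean()), float(len(d) - 1),
                       0.0, -np.inf)
    res = stats.ttest_rel(x, y)
    df = float(len(d) - 1)
    logp = (stats.t.logsf(abs(res.statistic), df) + np.log(2)) / np.log(10)
    return _result(res.statistic, df, res.pvalue, logp)


def variance_f_test(x, y) -> TestResult:
    """Two-sided variance-ratio F test.

    The statistic is var(x)/var(y) (numerator = first argument); the two-sided
    p doubles the smaller tail.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vy == 0:
        raise DegenerateDataError("zero variance in denominator sample")
    F = vx / vy
    df1, df2 = len(x) - 1, len(y) - 1
    upper = stats.f.sf(F, df1, df2)
    lower = stats.f.cdf(F, df1, df2)
    p = min(1.0, 2.0 * min(upper, lower))
    log_tail = (stats.f.logsf(F, df1, df2) if upper <= lower
                else stats.f.logcdf(F, df1, df2))
    logp = min(0.0, (log_tail + np.log(2)) / np.log(10))
    return _result(F, (float(df1), float(df2)), p, logp)


@dataclass(frozen=True)
class AnovaResult:
    """Per-term sums of squares, df, F and p for a balanced factorial design."""

    terms: dict[str, dict]
    residual_ss: float
    residual_df: int
    total_ss: float

    def as_dict(self) -> dict:
        return {"terms": self.terms, "residual_ss": self.residual_ss,
                "residual_df": self.residual_df, "total_ss": self.total_ss}


def factorial_anova(values, factors: dict[str, np.ndarray]) -> AnovaResult:
    """Full-factorial ANOVA for 2 or 3 two-level factors, balanced design.

    Balanced two-level designs make the effect contrasts orthogonal, so the
    sum of squares of each main effect and interaction is simply
    N · (contrast mean)² with the ±1 coding, and Type I/II/III decompositions
    coincide.  Unbalanced input raises (use a regression framework for that).
    """
    y = np.asarray(values, dtype=float)
    names = list(factors)
    if len(names) not in (2, 3):
        raise DegenerateDataError("factorial_anova supports 2 or 3 factors")
    codes = {}
    for name in names:
        f = np.asarray(factors[name])
        if f.shape != y.shape:
            raise DegenerateDataError(f"factor {name!r} length mismatch")
        levels = np.unique(f)
        if len(levels) != 2:
            raise DegenerateDataError(f"factor {name!r} must have 2 levels, "
                                      f"got {len(levels)}")
        codes[name] = np.where(f == levels[1], 1.0, -1.0)
    # balance check: every cell of the full cross must have equal count
    cell_key = sum((codes[n] > 0).astype(int) * (2**i) for i, n in enumerate(names))
    counts = np.bincount(cell_key.astype(int), minlength=2 ** len(names))
    if len(set(counts)) != 1 or counts[0] == 0:
        raise DegenerateDataError(
            f"unbalanced design (cell counts {sorted(set(counts))}); "
            "use a regression-based ANOVA instead")

    N = len(y)
    grand = y.mean()
    total_ss = float(((y - grand) ** 2).sum())

    from itertools import combinations

    terms: dict[str, dict] = {}
    model_ss = 0.0
    for order in range(1, len(names) + 1):
        for combo in combinations(names, order):
            contrast = np.prod([codes[n] for n in combo], axis=0)
            effect = float((y * contrast).mean())  # half-difference estimate
            ss = N * effect**2
            terms[":".join(combo)] = {"ss": ss, "df": 1}
            model_ss += ss
    resid_ss = max(total_ss - model_ss, 0.0)
    resid_df = N - 1 - len(terms)
    if resid_df <= 0:
        raise DegenerateDataError("no residual degrees of freedom")
    ms_resid = resid_ss / resid_df
    for term in terms.values():
        F = term["ss"] / term["df"] / ms_resid if ms_resid > 0 else np.inf
        p = float(stats.f.sf(F, term["df"], resid_df))
        term["F"] = float(F)
        term["p"] = p
        term["log10_p"] = float(stats.f.logsf(F, term["df"], resid_df) / np.log(10))
    return AnovaResult(terms, resid_ss, resid_df, total_ss)
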