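"""Test-retest reliability statistics.

T-RT% is the absolute percentage difference 200*|test - retest|/(test +
retest). Reliability is summarized by the two-way intraclass correlation
coefficient from the subjects x sessions mean-squares decomposition
(absolute-agreement single-measure by default, consistency optional), with
F-based 95% confidence intervals and the conventional qualitative bands
(<0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, >0.9 excellent; boundary
values are assigned to the higher band). Agreement is further described by
Bland-Altman bias and limits, and paired differences are tested with the
exact Wilcoxon signed-rank test. No multiple-comparison adjustment is
applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "trt_percent",
    "IccResult",
    "icc_two_way",
    "icc_band",
    "BlandAltman",
    "bland_altman",
    "WilcoxonResult",
    "paired_wilcoxon",
    "rank_association",
    "group_difference",
]


def trt_percent(test, retest):
    """Absolute percentage test-retest difference: 200|T - RT| / (T + RT).

    Symmetric, scale-invariant, and bounded in [0, 200) for positive pairs.
    Accepts scalars or arrays; the pair sum must be positive.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    s = test + retest
    if np.any(s <= 0):
        raise ValueError("test + retest must be positive for T-RT%")
    out = 200.0 * np.abs(test - retest) / s
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str
    form: str  # "absolute" (ICC(2,1)) or "consistency" (ICC(3,1))
    n_subjects: int
    defined: bool = True
    message: str = ""


def _mean_squares(data: np.ndarray):
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((data - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, max(mse, 0.0)


def icc_two_way(test, retest, form: str = "absolute", alpha: float = 0.05) -> IccResult:
    """Two-way single-measure ICC for paired test/retest data.

    ``form="absolute"`` gives the two-way random-effects absolute-agreement
    ICC (sessions as random raters); ``form="consistency"`` the two-way
    mixed consistency ICC. Confidence limits follow the standard F-based
    formulas. Requires at least 3 complete pairs; zero total variance yields
    a flagged undefined result.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.shape != retest.shape or test.ndim != 1:
        raise ValueError("test and retest must be equal-length 1-D arrays")
    if test.size < 3:
        raise ValueError("ICC requires at least 3 complete pairs")
    if not (np.all(np.isfinite(test)) and np.all(np.isfinite(retest))):
        raise ValueError("ICC inputs must be finite")
    if form not in ("absolute", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")

    data = np.column_stack([test, retest])
    n, k = data.shape
    msr, msc, mse = _mean_squares(data)

    total_var = np.var(data)
    if total_var <= 1e-30 * max(abs(data.mean()), 1.0) ** 2:
        return IccResult(np.nan, np.nan, np.nan, "undefined", form, n, False,
                         "zero total variance: ICC undefined")

    if form == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        icc = (msr - mse) / denom
        if mse <= 1e-30 * total_var:
            # perfect agreement: degenerate F distributions
            return IccResult(1.0, 1.0, 1.0, icc_band(1.0), form, n, True,
                             "zero within-subject variance")
        a = k * icc / (n * (1 - icc))
        b = 1 + k * icc * (n - 1) / (n * (1 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        icc = (msr - mse) / (msr + (k - 1) * mse)
        if mse <= 1e-30 * total_var:
            return IccResult(1.0, 1.0, 1.0, icc_band(1.0), form, n, True,
                             "zero within-subject variance")
        fstat = msr / mse
        df2 = (n - 1) * (k - 1)
        fl = fstat / sps.f.ppf(1 - alpha / 2, n - 1, df2)
        fu = fstat * sps.f.ppf(1 - alpha / 2, df2, n - 1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)

    icc = float(min(icc, 1.0))
    return IccResult(icc, float(lo), float(min(hi, 1.0)), icc_band(icc), form, n)


def icc_band(icc: float) -> str:
    """Qualitative reliability band; boundaries go to the higher band."""
    if not np.isfinite(icc):
        return "undefined"
    if icc > 1.0 + 1e-12:
        raise ValueError("ICC cannot exceed 1")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def bland_altman(test, retest) -> BlandAltman:
    """Bias = mean(test - retest); limits of agreement = bias +/- 1.96 SD."""
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if test.shape != retest.shape or test.size < 2:
        raise ValueError("Bland-Altman requires at least 2 complete pairs")
    d = test - retest
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, bias - 1.96 * sd, bias + 1.96 * sd, sd, d.size)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_effective: int
    degenerate: bool = False


def paired_wilcoxon(test, retest, alternative: str = "two-sided") -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired outcomes.

    Zero differences are dropped; the exact null distribution is used
    whenever scipy can compute it (small n, no ties), otherwise the normal
    approximation. All-zero differences give a flagged degenerate result.
    """
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    d = test - retest
    nz = d[d != 0]
    if nz.size == 0:
        return WilcoxonResult(np.nan, np.nan, 0, degenerate=True)
    try:
        res = sps.wilcoxon(nz, zero_method="wilcox", alternative=alternative, method="exact")
    except ValueError:
        res = sps.wilcoxon(nz, zero_method="wilcox", alternative=alternative, method="approx")
    return WilcoxonResult(float(res.statistic), float(res.pvalue), int(nz.size))


def rank_association(x, y):
    """Spearman rank correlation (midrank ties). Constant input -> NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with at least 3 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def group_difference(*groups):
    """Kruskal-Wallis H statistic and p across two or more groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    stat, p = sps.kruskal(*groups)
    return float(stat), float(p)


def plot_bland_altman(test, retest, ax=None, label: str | None = None):
    """Optional Bland-Altman scatter (requires matplotlib)."""
    import matplotlib.pyplot as plt

    ba = bland_altman(test, retest)
    test = np.asarray(test, dtype=float)
    retest = np.asarray(retest, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((test + retest) / 2, test - retest, s=18, label=label)
    for y, ls in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="k", lw=0.8, ls=ls)
    ax.set_xlabel("mean of test and retest")
    ax.set_ylabel("test - retest")
    return ax
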