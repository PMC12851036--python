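"""Method-agreement statistics between wearable-derived ocular deviations and
a reference test.

* ICC — two-way random-effects, absolute-agreement, single-measurement form
  (ICC(A,1) / "ICC2"), computed from the two-way ANOVA mean squares, with the
  standard F-based 95 % confidence interval. This is the conventional choice
  for method-comparison studies.
* Bland–Altman — bias (mean difference) and 95 % limits of agreement at
  bias ± 1.96 x SD, with approximate confidence intervals on bias and limits.
* Folded empirical CDF ("mountain plot") — folded percentiles peaking at the
  median of the differences.
* Stratified tables — the same statistics per stratum (direction, age group,
  sex, eyelid phenotype), with undersized strata flagged rather than dropped.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementResult",
    "BlandAltmanResult",
    "agreement_summary",
    "icc_absolute_agreement",
    "bland_altman",
    "folded_ecdf",
    "stratified_agreement",
    "bland_altman_plot",
    "mountain_plot",
]

MIN_N_ESTIMATE = 3
MIN_N_CI = 5


@dataclass
class AgreementResult:
    icc: float
    icc_ci95: tuple[float, float]
    bias: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int
    means: np.ndarray
    diffs: np.ndarray
    bias_ci95: tuple[float, float] | None = None
    loa_low_ci95: tuple[float, float] | None = None
    loa_high_ci95: tuple[float, float] | None = None


def _paired(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired measurements must have equal length")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("paired measurements must be finite")
    return a, b


def icc_absolute_agreement(a, b, confidence: float = 0.95):
    """ICC(A,1) from the two-way ANOVA decomposition of n subjects x 2 methods.

    Returns ``(icc, (ci_low, ci_high))``. Raises for n < 3 or when the data
    carry no variance at all (the coefficient is undefined there).
    """
    a, b = _paired(a, b)
    n = a.size
    if n < MIN_N_ESTIMATE:
        raise ValueError(f"ICC needs at least {MIN_N_ESTIMATE} paired observations")
    k = 2
    data = np.column_stack([a, b])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(data, grand):
        raise ValueError("degenerate input: no variance in either method")
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)  # between subjects
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)  # between methods
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom

    # F-based interval (McGraw & Wong case 2A, single measurement)
    alpha = 1.0 - confidence
    a_coef = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
    b_coef = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a_coef):
        num = (a_coef * msc + b_coef * mse) ** 2
        den = (a_coef * msc) ** 2 / (k - 1) + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    else:
        lower = upper = 1.0
    return float(icc), (float(lower), float(upper))


def bland_altman(a, b, loa_multiplier: float = 1.96) -> BlandAltmanResult:
    """Mean-difference analysis: d = A - B, limits at bias ± 1.96 x SD(d)."""
    a, b = _paired(a, b)
    n = a.size
    if n < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low = bias - loa_multiplier * sd
    loa_high = bias + loa_multiplier * sd
    result = BlandAltmanResult(
        bias=bias, loa_low=loa_low, loa_high=loa_high, sd=sd, n=n,
        means=(a + b) / 2.0, diffs=d,
    )
    if n >= MIN_N_CI:
        t = stats.t.ppf(0.975, n - 1)
        se_bias = sd / np.sqrt(n)
        se_loa = sd * np.sqrt(1.0 / n + loa_multiplier**2 / (2.0 * (n - 1)))
        result.bias_ci95 = (bias - t * se_bias, bias + t * se_bias)
        result.loa_low_ci95 = (loa_low - t * se_loa, loa_low + t * se_loa)
        result.loa_high_ci95 = (loa_high - t * se_loa, loa_high + t * se_loa)
    return result


def folded_ecdf(differences):
    """Folded empirical percentiles min(p, 1-p), peaking at the median.

    Returns ``(sorted_values, folded_probabilities)`` using Hazen plotting
    positions p_i = (i - 0.5) / n.
    """
    d = np.sort(np.asarray(differences, dtype=float).ravel())
    if d.size == 0:
        raise ValueError("need at least one difference")
    p = (np.arange(1, d.size + 1) - 0.5) / d.size
    return d, np.minimum(p, 1.0 - p)


def agreement_summary(a, b) -> AgreementResult:
    icc, ci = icc_absolute_agreement(a, b)
    ba = bland_altman(a, b)
    return AgreementResult(
        icc=icc, icc_ci95=ci, bias=ba.bias, loa_low=ba.loa_low,
        loa_high=ba.loa_high, n=ba.n,
    )


def stratified_agreement(
    df: pd.DataFrame,
    by: list[str] | str | None = None,
    method_a: str = "method_a",
    method_b: str = "method_b",
) -> pd.DataFrame:
    """Per-stratum ICC and Bland–Altman table with a pooled row.

    Strata below the estimation minimum are kept in the table with a flag
    instead of being silently dropped.
    """
    if method_a not in df.columns or method_b not in df.columns:
        raise ValueError(f"data must have columns {method_a!r} and {method_b!r}")
    groups: list[tuple[str, pd.DataFrame]] = [("pooled", df)]
    if by:
        by = [by] if isinstance(by, str) else list(by)
        for key, sub in df.groupby(by, sort=True, observed=True):
            key = key if isinstance(key, tuple) else (key,)
            groups.append(("/".join(map(str, key)), sub))
    rows = []
    for name, sub in groups:
        n = len(sub)
        row = {"stratum": name, "n": n, "flag": ""}
        if n < MIN_N_ESTIMATE:
            row["flag"] = f"n<{MIN_N_ESTIMATE}: too small to estimate"
            rows.append(row)
            continue
        try:
            icc, ci = icc_absolute_agreement(sub[method_a], sub[method_b])
        except ValueError as exc:
            row["flag"] = str(exc)
            rows.append(row)
            continue
        ba = bland_altman(sub[method_a], sub[method_b])
        row.update(
            icc=icc, icc_lo=ci[0], icc_hi=ci[1], bias=ba.bias,
            loa_low=ba.loa_low, loa_high=ba.loa_high,
        )
        if n < MIN_N_CI:
            row["flag"] = f"n<{MIN_N_CI}: confidence intervals unreliable"
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")


# ---------------------------------------------------------------------------
# plots (optional artifacts)
# ---------------------------------------------------------------------------

def bland_altman_plot(a, b, ax=None, label: str | None = None, color="C0"):
    """Mean-difference plot with bias and 95 % limits of agreement."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ba = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(ba.means, ba.diffs, s=12, alpha=0.6, color=color, label=label)
    ax.axhline(ba.bias, color=color, lw=1.5)
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color=color, lw=1.0, ls="--")
    ax.set_xlabel("mean of methods (deg)")
    ax.set_ylabel("difference (deg)")
    return ax


def mountain_plot(differences, ax=None, label: str | None = None, color="C0"):
    """Folded empirical CDF of the differences."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    v, p = folded_ecdf(differences)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(v, p, color=color, label=label)
    ax.set_xlabel("difference (deg)")
    ax.set_ylabel("folded percentile")
    ax.set_ylim(0, 0.55)
    return ax
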