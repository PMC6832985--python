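"""Agreement statistics between two measurement systems.

Used to validate sensor-derived spatiotemporal gait estimates against a
gold standard (instrumented walkway, visual step count) on paired values:
Bland-Altman bias and limits of agreement (bias +/- 1.96 SD of the paired
differences, also expressed as a percentage of the grand mean of the
pair averages), the intraclass correlation coefficient in its two-way
random-effects, absolute-agreement, single-measure form, Pearson's r and
the RMSE. ICC values are classed as excellent (> 0.9), good (0.75-0.9),
moderate (0.5-0.75) or poor (< 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass
class AgreementReport:
    """Agreement summary for one paired feature."""

    bias: float
    loa_low: float
    loa_high: float
    loa_pct: float
    icc: float
    icc_class: str
    r: float
    rmse: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("agreement statistics require at least 3 pairs")
    return x, y


def bland_altman(x, y) -> tuple[float, float, float, float]:
    """(bias, loa_low, loa_high, loa_pct) for paired measurements.

    bias = mean(x - y); the limits of agreement are bias +/- 1.96 times the
    SD of the differences; loa_pct expresses the LoA half-width as a
    percentage of the grand mean of the pair averages.
    """
    x, y = _paired(x, y)
    d = x - y
    bias = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    grand = float(((x + y) / 2).mean())
    loa_pct = float(half / grand * 100.0) if grand != 0 else np.nan
    return bias, bias - half, bias + half, loa_pct


def icc_agreement(x, y) -> tuple[float, str]:
    """Two-way random, absolute-agreement, single-measure ICC and its class.

    From the two-way ANOVA decomposition with n targets and k = 2 raters:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    where MSR, MSC and MSE are the rows (targets), columns (raters) and
    error mean squares. Zero total variance leaves the coefficient
    undefined (NaN, class "undefined").
    """
    x, y = _paired(x, y)
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(data, grand):
        return float("nan"), "undefined"
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom != 0 else float("nan")
    return icc, icc_class(icc)


def icc_class(icc: float) -> str:
    """Qualitative ICC class at the 0.9 / 0.75 / 0.5 thresholds."""
    if np.isnan(icc):
        return "undefined"
    if icc > 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def pearson_rmse(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation and root-mean-squared error."""
    x, y = _paired(x, y)
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        return float("nan"), rmse
    r = float(np.corrcoef(x, y)[0, 1])
    return r, rmse


def agreement_report(x, y) -> AgreementReport:
    """All agreement statistics for one paired feature."""
    x, y = _paired(x, y)
    bias, lo, hi, pct = bland_altman(x, y)
    icc, klass = icc_agreement(x, y)
    r, rmse = pearson_rmse(x, y)
    return AgreementReport(
        bias=bias, loa_low=lo, loa_high=hi, loa_pct=pct,
        icc=icc, icc_class=klass, r=r, rmse=rmse, n=len(x),
    )
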