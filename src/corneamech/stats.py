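"""Cohort statistics: Pearson correlations, OLS, paired t, Bland-Altman.

All tests are parametric and two-tailed with significance at α = 0.05;
correlations additionally carry the ``**`` marker at p < 0.001, matching the
convention of the clinical report this battery reproduces. Sample (n−1)
moment denominators throughout. No multiple-testing correction is applied —
raw per-pair p-values are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    DegenerateTestError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedCorrelationError,
)

__all__ = [
    "CorrelationResult",
    "RegressionFit",
    "BlandAltmanResult",
    "PairedTestResult",
    "CorrelationMatrix",
    "pearson",
    "correlation_matrix",
    "ols_fit",
    "bland_altman",
    "paired_t",
]


def _as_pair(x: Sequence[float], y: Sequence[float], min_n: int) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1:
        raise InvalidInputError("series must be one-dimensional")
    if xa.size != ya.size:
        raise InvalidInputError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < min_n:
        raise InsufficientDataError(f"need at least {min_n} pairs, got {xa.size}")
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(ya))):
        raise InvalidInputError("series contain non-finite values")
    return xa, ya


def _star(p: float) -> str:
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson r with its two-tailed p (t-transform, n−2 df) and star code."""

    r: float
    p_two_tailed: float
    n: int

    @property
    def star(self) -> str:
        return _star(self.p_two_tailed)


@dataclass(frozen=True)
class RegressionFit:
    """Simple least-squares line y = slope·x + intercept."""

    slope: float
    intercept: float
    r: float
    p_slope: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two paired methods via differences vs means."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    proportional_slope: float
    proportional_p: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    p_two_tailed: float
    mean_difference: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with two-tailed significance.

    p is obtained from t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom,
    which is what ``scipy.stats.pearsonr`` computes for two-sided tests.
    """
    xa, ya = _as_pair(x, y, min_n=3)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    res = sps.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), p_two_tailed=float(res.pvalue), n=xa.size)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric matrix of pairwise correlation results; diagonal undefined."""

    names: tuple[str, ...]
    cells: Mapping[tuple[str, str], CorrelationResult]

    def get(self, a: str, b: str) -> CorrelationResult:
        key = (a, b) if (a, b) in self.cells else (b, a)
        return self.cells[key]

    def _frame(self, attr: str, diagonal) -> pd.DataFrame:
        frame = pd.DataFrame(index=list(self.names), columns=list(self.names), dtype=object)
        for a in self.names:
            for b in self.names:
                if a == b:
                    frame.loc[a, b] = diagonal
                else:
                    frame.loc[a, b] = getattr(self.get(a, b), attr)
        return frame

    def r_frame(self) -> pd.DataFrame:
        return self._frame("r", np.nan).astype(float)

    def p_frame(self) -> pd.DataFrame:
        return self._frame("p_two_tailed", np.nan).astype(float)

    def star_frame(self) -> pd.DataFrame:
        return self._frame("star", "----")


def correlation_matrix(variables: Mapping[str, Sequence[float]]) -> CorrelationMatrix:
    """All pairwise Pearson correlations among named, equal-length series."""
    names = tuple(variables)
    if len(names) < 2:
        raise InvalidInputError("need at least two variables")
    cells: dict[tuple[str, str], CorrelationResult] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            cells[(a, b)] = pearson(variables[a], variables[b])
    return CorrelationMatrix(names=names, cells=cells)


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Least-squares line of y on x; the slope p equals the Pearson p."""
    xa, ya = _as_pair(x, y, min_n=3)
    if np.ptp(xa) == 0:
        raise InvalidInputError("regression undefined for constant x")
    res = sps.linregress(xa, ya)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_slope=float(res.pvalue),
        n=xa.size,
    )


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman agreement of two methods measuring the same quantity.

    Differences d = a − b are set against pairwise means (a + b)/2; the
    limits of agreement are bias ± 1.96·SD(d); proportional bias is the OLS
    slope of d on the means with its two-tailed p.
    """
    aa, ba = _as_pair(a, b, min_n=3)
    d = aa - ba
    m = (aa + ba) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.ptp(m) == 0:
        slope, p = 0.0, 1.0
    elif np.ptp(d) == 0:
        slope, p = 0.0, 1.0
    else:
        fit = sps.linregress(m, d)
        slope, p = float(fit.slope), float(fit.pvalue)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        proportional_slope=slope,
        proportional_p=p,
        n=aa.size,
    )


def paired_t(a: Sequence[float], b: Sequence[float]) -> PairedTestResult:
    """Paired two-tailed t-test on a − b, n−1 degrees of freedom."""
    aa, ba = _as_pair(a, b, min_n=2)
    d = aa - ba
    if np.ptp(d) == 0:
        raise DegenerateTestError("paired differences have zero variance")
    res = sps.ttest_rel(aa, ba)
    return PairedTestResult(
        t_statistic=float(res.statistic),
        p_two_tailed=float(res.pvalue),
        mean_difference=float(np.mean(d)),
        n=aa.size,
    )
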