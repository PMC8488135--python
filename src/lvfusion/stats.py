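"""Agreement statistics for multi-method LV measurements.

Paired t-tests with Bonferroni-corrected significance, the two-way
mixed-effects absolute-agreement average-measure intraclass correlation
ICC(A,k) (McGraw & Wong), classical two-method Bland-Altman limits of
agreement, and the multi-method variant where each method is compared
with the per-subject mean of all methods and symmetric limits are
derived from the pooled SD of those differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "DEFAULT_ALPHA_CORRECTED",
    "PairedComparison",
    "ICCResult",
    "BlandAltmanResult",
    "paired_t",
    "icc_a_k",
    "bland_altman_two",
    "bland_altman_multi",
]

#: two-tailed significance threshold after Bonferroni correction for the
#: three echo methods: 0.05 / 3
DEFAULT_ALPHA_CORRECTED = 0.05 / 3.0


@dataclass(frozen=True)
class PairedComparison:
    mean_difference: float
    sd_difference: float
    t_statistic: float
    p_value: float
    alpha_corrected: float
    significant: bool
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")
        if self.significant != (self.p_value < self.alpha_corrected):
            raise ValueError("significance flag inconsistent with p and alpha")


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model: str
    n_subjects: int
    k_raters: int

    def __post_init__(self) -> None:
        if self.icc > 1.0 + 1e-12:
            raise ValueError("ICC cannot exceed 1")
        if self.n_subjects < 2 or self.k_raters < 2:
            raise ValueError("ICC requires n >= 2 subjects and k >= 2 raters")


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: np.ndarray | float
    loa_lower: float
    loa_upper: float
    sd_difference: float
    n: int
    k: int = 2


def paired_t(
    x: np.ndarray, y: np.ndarray, alpha_corrected: float = DEFAULT_ALPHA_CORRECTED
) -> PairedComparison:
    """Classical paired t-test on d = x − y with n − 1 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise ValueError("zero-variance differences: t statistic undefined")
    t, p = sps.ttest_rel(x, y)
    return PairedComparison(
        mean_difference=float(d.mean()),
        sd_difference=sd,
        t_statistic=float(t),
        p_value=float(p),
        alpha_corrected=alpha_corrected,
        significant=bool(p < alpha_corrected),
        n=n,
    )


def icc_a_k(ratings: np.ndarray) -> ICCResult:
    """ICC(A,k): two-way, absolute agreement, average of k measures.

    From the two-way ANOVA mean squares with rows = subjects and
    columns = methods:

        ICC(A,k) = (MS_R − MS_E) / (MS_R + (MS_C − MS_E) / n)
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be an n×k table")
    if np.isnan(x).any():
        raise ValueError("ratings table must be complete (no missing cells)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC requires n >= 2 subjects and k >= 2 methods")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (ms_c - ms_e) / n
    icc = 1.0 if denom == 0.0 else (ms_r - ms_e) / denom
    return ICCResult(
        icc=float(icc),
        model="two-way mixed, absolute agreement, average of k measures (ICC(A,k))",
        n_subjects=n,
        k_raters=k,
    )


def bland_altman_two(x: np.ndarray, y: np.ndarray) -> BlandAltmanResult:
    """Two-method Bland-Altman: bias and 95% limits of agreement.

    d = x − y; bias = mean(d); LoA = bias ± 1.96·SD(d), within which 95%
    of the differences are expected to fall.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("Bland-Altman requires equal-length 1D arrays, n >= 3")
    d = x - y
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd_difference=sd,
        n=len(x),
        k=2,
    )


def bland_altman_multi(methods: np.ndarray) -> BlandAltmanResult:
    """Multi-method Bland-Altman against the per-subject mean.

    For an n×k table (k ≥ 3 methods), differences are taken from each
    method to the mean of the measurements for each subject:
    d_ij = x_ij − mean_j(x_ij).  Per-method biases are the column means
    of d (they sum to zero by construction) and the symmetric 95% limits
    of agreement are ±1.96 times the SD of all n·k pooled differences.
    """
    x = np.asarray(methods, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError(
            "bland_altman_multi requires an n×k table with k >= 3 "
            "(use bland_altman_two for two methods)"
        )
    if np.isnan(x).any():
        raise ValueError("methods table must be complete")
    n, k = x.shape
    d = x - x.mean(axis=1, keepdims=True)
    biases = d.mean(axis=0)
    sd = float(np.std(d.ravel(), ddof=1))
    half = 1.96 * sd
    return BlandAltmanResult(
        bias=biases,
        loa_lower=-half,
        loa_upper=half,
        sd_difference=sd,
        n=n,
        k=k,
    )
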