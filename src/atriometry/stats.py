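"""Method- and rater-agreement statistics.

Bland–Altman analysis (bias, its 95% CI, and limits of agreement at
bias ± 2·SD of the differences), intraclass correlation ICC(3,1)
(two-way mixed model, consistency, single measures) with its F-bound
confidence interval, Pearson/Spearman correlation, and normality-gated
summarization using Tukey's hinges for the interquartile range.

Conventions fixed across the package: differences are oriented as
calculated minus reference (matching the signed volume-error definition),
the limits-of-agreement multiplier defaults to 2 rather than 1.96, and the
bias CI uses the t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "BlandAltmanResult",
    "ICCResult",
    "bland_altman",
    "icc_two_way_mixed_consistency_single",
    "correlation",
    "tukey_hinges",
    "summarize",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired measurements of one quantity by two methods or raters."""

    x: np.ndarray
    y: np.ndarray
    label_x: str = "x"
    label_y: str = "y"

    def __post_init__(self):
        x = np.asarray(self.x, float)
        y = np.asarray(self.y, float)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(x) < 2:
            raise ValueError(f"need at least 2 pairs, got {len(x)}")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("paired measurements must not contain missing values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self):
        return len(self.x)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    bias_ci: tuple
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci: tuple
    p_value: float
    significant: bool
    model_tag: str = "two-way mixed, consistency, single measures"


def bland_altman(data: PairedMeasurements,
                 loa_multiplier: float = 2.0,
                 ci_level: float = 0.95) -> BlandAltmanResult:
    """Bland–Altman agreement of two paired methods.

    Differences are x - y (first method minus second; orient the pair as
    calculated-minus-reference for method comparisons).  Bias is the mean
    difference with a t-based CI; limits of agreement are
    bias ± loa_multiplier * SD of the differences.
    """
    d = data.x - data.y
    n = len(d)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    tcrit = float(sps.t.ppf(0.5 + ci_level / 2.0, n - 1))
    half = tcrit * sd / np.sqrt(n)
    return BlandAltmanResult(
        bias=bias,
        bias_ci=(bias - half, bias + half),
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        sd_diff=sd,
        n=n,
    )


def icc_two_way_mixed_consistency_single(table, alpha: float = 0.05) -> ICCResult:
    """ICC(3,1): two-way mixed model, consistency, single measures.

    Parameters
    ----------
    table : (n_subjects, k_raters) array
        Complete ratings table; rows are subjects, columns raters.

    Notes
    -----
    From the two-way ANOVA decomposition,

        ICC(3,1) = (MS_B - MS_E) / (MS_B + (k - 1) MS_E)

    with MS_B the between-subject and MS_E the residual mean square.  The
    CI follows the Shrout–Fleiss F-bound construction; the p-value is the
    upper tail of F = MS_B / MS_E with (n-1, (n-1)(k-1)) df.
    """
    t = np.asarray(table, float)
    if t.ndim != 2:
        raise ValueError("ratings table must be 2-D (subjects x raters)")
    n, k = t.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 raters, got {n} x {k}")
    if not np.isfinite(t).all():
        raise ValueError("ratings table is incomplete (non-finite entries)")

    grand = t.mean()
    ss_total = ((t - grand) ** 2).sum()
    if ss_total == 0:
        raise ValueError("ratings table has zero total variance")
    ss_rows = k * ((t.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((t.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_err = ss_err / df_err

    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

    if ms_err == 0:
        f_obs = np.inf
        ci = (1.0, 1.0)
        p = 0.0
    else:
        f_obs = ms_rows / ms_err
        fl = f_obs / sps.f.ppf(1 - alpha / 2, df_rows, df_err)
        fu = f_obs * sps.f.ppf(1 - alpha / 2, df_err, df_rows)
        ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
        p = float(sps.f.sf(f_obs, df_rows, df_err))
    return ICCResult(
        icc=float(icc),
        ci=(float(ci[0]), float(ci[1])),
        p_value=p,
        significant=p < alpha,
    )


def correlation(x, y, method: str = "pearson") -> dict:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return {"coefficient": float(r), "p_value": float(p)}


def tukey_hinges(values) -> tuple:
    """Median and Tukey's hinges (lower, median, upper).

    The hinges are the medians of the lower and upper halves, each half
    including the overall median position when n is odd.
    """
    v = np.sort(np.asarray(values, float))
    n = len(v)
    if n < 3:
        raise ValueError("need >= 3 values for hinges")

    def _at(pos_1idx: float) -> float:
        # positions are integers or integers + 1/2
        lo = int(np.floor(pos_1idx)) - 1
        if pos_1idx == np.floor(pos_1idx):
            return float(v[lo])
        return float((v[lo] + v[lo + 1]) / 2.0)

    median = _at((n + 1) / 2.0) if n % 2 else float((v[n // 2 - 1] + v[n // 2]) / 2)
    m = (n + 1) // 2               # size of each half, median included if odd n
    h = (m + 1) / 2.0              # hinge position within a half
    lower = _at(h)
    upper = _at(n + 1 - h)
    return lower, median, upper


def summarize(values, normality_alpha: float = 0.05) -> dict:
    """Normality-gated descriptive summary of one variable.

    A Shapiro–Wilk test selects the report form: mean ± SD when normality
    is not rejected at ``normality_alpha``, otherwise median with the
    Tukey-hinge interquartile range.
    """
    v = np.asarray(values, float)
    if len(v) < 3:
        raise ValueError("need >= 3 values to summarize")
    p = float(sps.shapiro(v).pvalue)
    if p >= normality_alpha:
        return {
            "form": "mean_sd",
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "normality_p": p,
        }
    lo, med, hi = tukey_hinges(v)
    return {
        "form": "median_iqr",
        "median": med,
        "iqr": (lo, hi),
        "normality_p": p,
    }
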