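"""ICH-style method-validation statistics.

Recovery and precision aggregates (mean, sample SD, RSD%, variance),
detection limits (LOD = 3.3 sigma/S, LOQ = 10 sigma/S with sigma the SD
of the calibration intercept and S the slope), and the two-method
comparison used on tablet assays: a pooled-variance two-tailed t test
(df = n_a + n_b - 2) and a variance-ratio F test (larger variance in the
numerator, df = (n-1, n-1)), both judged against alpha = 0.05 critical
values.

The published validation tables for this assay ship as packaged CSV
fixtures (replicate recoveries, printed summary cells and printed t/F
statistics).  A ``consistent`` flag marks the handful of printed cells
that do not follow from their own printed replicates or summaries; those
are recorded rather than silently "corrected".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RecoverySummary",
    "MethodComparison",
    "TTestResult",
    "FTestResult",
    "recovery",
    "summarize",
    "lod_loq",
    "two_sample_t",
    "pooled_t_from_summary",
    "variance_ratio_f",
    "f_from_summary",
    "compare_methods",
    "t_critical",
    "f_critical",
    "load_lab_mixture_recoveries",
    "load_lab_mixture_summaries",
    "load_tablet_recoveries",
    "load_tablet_summaries",
    "load_tablet_comparisons",
]

#: Critical values printed alongside the published comparison (alpha =
#: 0.05, two-tailed t at df 10 and F at (5, 5)); other dfs fall back to
#: the scipy distributions.
_T_CRITICAL_TABLE = {(10, 0.05): 2.228}
_F_CRITICAL_TABLE = {(5, 5, 0.05): 5.050}


@dataclass
class RecoverySummary:
    """Replicate recoveries with their precision aggregates (percent)."""

    n: int
    recoveries_pct: tuple[float, ...]
    mean_pct: float
    sd_pct: float
    rsd_pct: float
    variance: float

    @classmethod
    def from_moments(cls, mean_pct: float, variance: float, n: int
                     ) -> "RecoverySummary":
        """Summary built from printed moments (no replicate list)."""
        sd = math.sqrt(variance)
        return cls(n=n, recoveries_pct=(), mean_pct=mean_pct, sd_pct=sd,
                   rsd_pct=100.0 * sd / mean_pct, variance=variance)


@dataclass
class TTestResult:
    t_stat: float
    df: int
    critical: float

    @property
    def passed(self) -> bool:
        """True when the methods are statistically indistinguishable."""
        return self.t_stat < self.critical


@dataclass
class FTestResult:
    f_stat: float
    df_pair: tuple[int, int]
    critical: float

    @property
    def passed(self) -> bool:
        return self.f_stat < self.critical


@dataclass
class MethodComparison:
    """Joint accuracy (t) and precision (F) comparison of two methods."""

    t_stat: float
    t_critical: float
    df_t: int
    f_stat: float
    f_critical: float
    df_f_pair: tuple[int, int]

    @property
    def t_pass(self) -> bool:
        return self.t_stat < self.t_critical

    @property
    def f_pass(self) -> bool:
        return self.f_stat < self.f_critical


def recovery(found_ug_per_ml: float, true_ug_per_ml: float) -> float:
    """Recovery percentage, 100 * found / true."""
    if true_ug_per_ml <= 0:
        raise ValueError("true concentration must be > 0")
    return 100.0 * found_ug_per_ml / true_ug_per_ml


def summarize(recoveries_pct: Sequence[float]) -> RecoverySummary:
    """Mean, sample SD (n-1 denominator), RSD% and variance."""
    vals = np.asarray(recoveries_pct, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 replicates to summarize")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return RecoverySummary(
        n=int(vals.size),
        recoveries_pct=tuple(float(v) for v in vals),
        mean_pct=mean,
        sd_pct=sd,
        rsd_pct=100.0 * sd / mean,
        variance=sd * sd,
    )


def lod_loq(sigma_intercept_au: float, slope_au_per_ug_ml: float
            ) -> tuple[float, float]:
    """Detection and quantitation limits: (3.3 sigma/S, 10 sigma/S)."""
    if slope_au_per_ug_ml <= 0:
        raise ValueError("slope must be > 0")
    if sigma_intercept_au < 0:
        raise ValueError("sigma must be >= 0")
    return (3.3 * sigma_intercept_au / slope_au_per_ug_ml,
            10.0 * sigma_intercept_au / slope_au_per_ug_ml)


def t_critical(df: int, alpha: float = 0.05) -> float:
    """Two-tailed critical t; bundled value at df 10, scipy elsewhere."""
    return _T_CRITICAL_TABLE.get((df, alpha),
                                 float(sps.t.ppf(1 - alpha / 2, df)))


def f_critical(df1: int, df2: int, alpha: float = 0.05) -> float:
    """Upper-tail critical F; bundled value at (5, 5), scipy elsewhere."""
    return _F_CRITICAL_TABLE.get((df1, df2, alpha),
                                 float(sps.f.ppf(1 - alpha, df1, df2)))


def pooled_t_from_summary(mean_a: float, var_a: float, n_a: int,
                          mean_b: float, var_b: float, n_b: int,
                          alpha: float = 0.05) -> TTestResult:
    """Pooled-variance two-tailed t from summary moments."""
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need n >= 2")
    df = n_a + n_b - 2
    pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
    diff = abs(mean_a - mean_b)
    if pooled == 0:
        t = 0.0 if diff == 0 else math.inf
    else:
        t = diff / math.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    return TTestResult(t_stat=float(t), df=df, critical=t_critical(df, alpha))


def two_sample_t(summary_a: RecoverySummary, summary_b: RecoverySummary,
                 alpha: float = 0.05) -> TTestResult:
    """Pooled t test between two recovery summaries."""
    return pooled_t_from_summary(summary_a.mean_pct, summary_a.variance,
                                 summary_a.n, summary_b.mean_pct,
                                 summary_b.variance, summary_b.n, alpha)


def f_from_summary(var_a: float, n_a: int, var_b: float, n_b: int,
                   alpha: float = 0.05) -> FTestResult:
    """Variance-ratio F (larger variance over smaller)."""
    if var_a <= 0 or var_b <= 0:
        raise ValueError("both variances must be > 0")
    if var_a >= var_b:
        f, dfs = var_a / var_b, (n_a - 1, n_b - 1)
    else:
        f, dfs = var_b / var_a, (n_b - 1, n_a - 1)
    return FTestResult(f_stat=float(f), df_pair=dfs,
                       critical=f_critical(*dfs, alpha))


def variance_ratio_f(summary_a: RecoverySummary, summary_b: RecoverySummary,
                     alpha: float = 0.05) -> FTestResult:
    return f_from_summary(summary_a.variance, summary_a.n,
                          summary_b.variance, summary_b.n, alpha)


def compare_methods(summary_a: RecoverySummary, summary_b: RecoverySummary,
                    alpha: float = 0.05) -> MethodComparison:
    """Full t + F comparison of two methods on the same sample."""
    t = two_sample_t(summary_a, summary_b, alpha)
    f = variance_ratio_f(summary_a, summary_b, alpha)
    return MethodComparison(
        t_stat=t.t_stat, t_critical=t.critical, df_t=t.df,
        f_stat=f.f_stat, f_critical=f.critical, df_f_pair=f.df_pair,
    )


# -- packaged validation fixtures ----------------------------------------

def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("triquant.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_lab_mixture_recoveries() -> pd.DataFrame:
    """Published per-mixture recoveries of the nine specificity mixtures."""
    return _load_csv("lab_mixture_recoveries.csv")


def load_lab_mixture_summaries() -> pd.DataFrame:
    """Published mean/SD/RSD cells for the specificity study, with a
    ``consistent`` flag marking cells reproducible from the replicates."""
    return _load_csv("lab_mixture_summaries.csv")


def load_tablet_recoveries() -> pd.DataFrame:
    """Published six-replicate tablet-assay recoveries per method/analyte."""
    return _load_csv("tablet_assay_recoveries.csv")


def load_tablet_summaries() -> pd.DataFrame:
    """Published tablet-assay summary cells with consistency flags."""
    return _load_csv("tablet_assay_summaries.csv")


def load_tablet_comparisons() -> pd.DataFrame:
    """Published t/F statistics (and their critical values) comparing each
    candidate method against the reference method."""
    return _load_csv("tablet_assay_comparisons.csv")
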