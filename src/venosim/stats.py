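"""Validation statistics: accuracy, repeatability, agreement and ANOVA.

The bench-style statistics compare a test measurement series against a
reference series: bias and SD of the differences, RMS percent error,
linear regression forced through the origin (in line with Ohm's law),
and Bland-Altman limits of agreement.  State comparisons use classical
one-way fixed-effects ANOVA.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ValidationReport",
    "BlandAltmanResult",
    "AnovaResult",
    "accuracy_report",
    "regression_through_origin",
    "bland_altman",
    "one_way_anova",
    "repeatability_report",
]

#: Limits-of-agreement multiplier (normal 95% interval).
LOA_MULTIPLIER = 1.96


class StatsError(ValueError):
    pass


def _as_pairs(reference, test) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(reference, dtype=float)
    y = np.asarray(test, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("reference and test must be matched 1-D sequences")
    if x.size < 2:
        raise StatsError("need at least 2 measurement pairs")
    return x, y


@dataclass(frozen=True)
class ValidationReport:
    """Agreement summary between a test and a reference series."""

    bias: float              # mean(test - reference)
    sd: float                # sample SD (n-1) of the differences
    rms_percent: float       # RMS of 100*(test-ref)/ref
    rms_absolute: float      # RMS of (test - ref), same units as input
    slope: float             # origin-forced regression slope
    r_squared: float
    loa_lower: float         # bias - 1.96*SD
    loa_upper: float         # bias + 1.96*SD
    n: int

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray        # abscissa: pairwise means
    differences: np.ndarray  # ordinate: test - reference


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int

    def to_dict(self) -> dict:
        return asdict(self)


def regression_through_origin(reference, test) -> tuple[float, float]:
    """Least-squares slope of y = b*x and its R**2.

    slope = sum(x*y) / sum(x**2); R**2 = 1 - SS_res / SS_tot with
    SS_tot about the mean of y (so R**2 may be negative for a poor fit
    through the origin).
    """
    x, y = _as_pairs(reference, test)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise StatsError("all reference values are zero")
    slope = float(np.sum(x * y)) / sxx
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_res == 0 else 1.0 - ss_res / ss_tot
    return slope, r2


def accuracy_report(reference, test) -> ValidationReport:
    """Bias, dispersion, RMS error and origin-forced fit of test vs truth."""
    x, y = _as_pairs(reference, test)
    if np.any(x == 0):
        raise StatsError("zero reference value: RMS percent error undefined")
    diff = y - x
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    rms_pct = float(np.sqrt(np.mean((100.0 * diff / x) ** 2)))
    rms_abs = float(np.sqrt(np.mean(diff ** 2)))
    slope, r2 = regression_through_origin(x, y)
    return ValidationReport(
        bias=bias, sd=sd, rms_percent=rms_pct, rms_absolute=rms_abs,
        slope=slope, r_squared=r2,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        n=int(x.size),
    )


def bland_altman(reference, test) -> BlandAltmanResult:
    """Pairwise differences vs means with 95% limits of agreement."""
    x, y = _as_pairs(reference, test)
    diff = y - x
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=bias,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        means=0.5 * (x + y),
        differences=diff,
    )


def one_way_anova(*groups: Sequence[float]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from sums of squares.

    F = (SS_between / (k-1)) / (SS_within / (N-k)); p from the F
    distribution.  Identical constant groups give F = 0, p = 1.
    """
    if len(groups) < 2:
        raise StatsError("ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise StatsError("every group needs n >= 2")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else np.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    p = 0.0 if np.isinf(f) else float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(f_statistic=float(f), p_value=p,
                       df_between=df_b, df_within=df_w)


def repeatability_report(m1, m2) -> ValidationReport:
    """Repeat-measurement agreement; measurement #1 acts as reference."""
    return accuracy_report(m1, m2)
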