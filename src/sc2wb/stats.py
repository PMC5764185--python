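"""Nonparametric population statistics over per-cell metrics.

Single-cell localization and expression distributions are summarized without
distributional assumptions: median, interquartile range
``IQR = Q3 - Q1`` (quartiles by linear interpolation between order
statistics, the common "type 7" rule), and the nonparametric skew
``S = (mean - median) / sd`` -- positive for a heavy right tail.  Technical
variance across replicate devices/wells is the CV of a chosen summary field,
and cross-modality agreement is the correlation of per-timepoint medians with
an ordinary least-squares fit and its 95% confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence
import warnings

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "DistributionSummary",
    "TimecourseSummary",
    "CorrelationResult",
    "summarize",
    "replicate_variation",
    "cross_modality_correlation",
    "timecourse",
    "localization_histogram",
]


@dataclass(frozen=True)
class DistributionSummary:
    """Nonparametric summary of one per-cell metric over a population."""

    n: int
    mean: float
    median: float
    sd: float  # sample (n-1)
    skew: float  # (mean - median) / sd; NaN when sd == 0
    q1: float
    q3: float
    iqr: float
    cv: float  # 100 * sd / mean (%)

    def as_dict(self) -> dict:
        return asdict(self)


def summarize(values: Sequence[float]) -> DistributionSummary:
    """Compute the nonparametric distribution summary of a sample (n >= 2).

    Quartiles use linear interpolation between order statistics; the sd is
    the sample (n-1) standard deviation; skew is ``(mean - median)/sd`` and
    is NaN (degenerate sample) when sd is 0.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError(f"summarize needs at least 2 values, got {v.size}")
    mean = float(np.mean(v))
    median = float(np.median(v))
    sd = float(np.std(v, ddof=1))
    q1, q3 = (float(q) for q in np.quantile(v, [0.25, 0.75]))
    return DistributionSummary(
        n=int(v.size),
        mean=mean,
        median=median,
        sd=sd,
        skew=(mean - median) / sd if sd > 0 else float("nan"),
        q1=q1,
        q3=q3,
        iqr=q3 - q1,
        cv=100.0 * sd / mean if mean != 0 else float("nan"),
    )


def replicate_variation(
    summaries: Sequence[DistributionSummary], field: str = "median"
) -> dict[str, float]:
    """Technical variation of a summary field across replicates.

    Returns mean, sample s.d. and CV (%) of ``field`` (e.g. ``median``,
    ``skew``, ``iqr``) over >= 2 replicate summaries.
    """
    if len(summaries) < 2:
        raise ValueError("replicate_variation needs at least 2 replicates")
    vals = np.asarray([getattr(s, field) for s in summaries], dtype=np.float64)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    return {
        "field": field,
        "n": len(summaries),
        "mean": mean,
        "sd": sd,
        "cv": 100.0 * sd / abs(mean) if mean != 0 else float("nan"),
    }


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    method: str
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int


def cross_modality_correlation(
    a: Sequence[float], b: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Correlate two paired series (e.g. per-timepoint medians of two assays).

    Returns the correlation coefficient (Pearson by default, Spearman by
    flag) plus the ordinary least-squares fit of ``b`` on ``a`` with 95%
    confidence intervals for slope and intercept.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"paired series length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError("need at least 3 paired points")
    if method == "pearson":
        rho = float(sps.pearsonr(a, b).statistic)
    elif method == "spearman":
        rho = float(sps.spearmanr(a, b).statistic)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    model = sm.OLS(b, sm.add_constant(a)).fit()
    ci = model.conf_int(alpha=0.05)
    return CorrelationResult(
        rho=rho,
        method=method,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        n=int(a.size),
    )


@dataclass(frozen=True)
class TimecourseSummary:
    """Per-timepoint distribution summaries and the time-to-peak."""

    timepoints: tuple[float, ...]
    summaries: tuple[DistributionSummary, ...]
    time_to_peak: float  # timepoint maximizing the median (earliest on ties)

    def medians(self) -> np.ndarray:
        return np.asarray([s.median for s in self.summaries])


def timecourse(records: Mapping[float, Sequence[float]]) -> TimecourseSummary:
    """Summarize a per-timepoint metric (e.g. nuclear fraction) over time.

    ``records`` maps timepoint (minutes) to the per-cell values measured at
    that timepoint.  Timepoints with fewer than 2 detected values are
    excluded with a warning.  Time-to-peak is the timepoint whose median is
    largest, the earliest one on ties.
    """
    tps, sums = [], []
    for tp in sorted(records):
        vals = np.asarray(records[tp], dtype=np.float64)
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            warnings.warn(f"timepoint {tp} has {vals.size} detected values; excluded")
            continue
        tps.append(float(tp))
        sums.append(summarize(vals))
    if len(tps) < 2:
        raise ValueError("timecourse needs at least 2 usable timepoints")
    medians = np.asarray([s.median for s in sums])
    return TimecourseSummary(
        timepoints=tuple(tps),
        summaries=tuple(sums),
        time_to_peak=tps[int(np.argmax(medians))],
    )


def localization_histogram(
    values: Sequence[float], bins: int = 20, value_range: tuple[float, float] = (0.0, 1.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of a localization fraction on a fixed [0, 1] grid (20 bins)."""
    v = np.asarray(values, dtype=np.float64)
    return np.histogram(v[~np.isnan(v)], bins=bins, range=value_range)
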