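"""Method-comparison statistics: OLS regression, Bland-Altman, tidal shares.

Regression is unweighted ordinary least squares with the EIT value as y and
the spirometry value as x, matching the reporting form ``y = a*x + b``.
Bland-Altman works on differences d = x - y against means m = (x + y) / 2
with 95% limits of agreement bias +- 1.96 * sd(d) (sample sd) and a
proportional-error slope (OLS of d on m).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats

from .breath_phase import BreathSegmentation
from .eit_signal import SUB_ROIS, RegionalVolumeSeries

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "TidalDistribution",
    "linear_regression",
    "bland_altman",
    "tidal_distribution",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    proportional_slope: float
    n: int


@dataclass
class TidalDistribution:
    """Percent of the global tidal amplitude per sub-ROI.

    ``per_breath`` has shape (n_breaths, 3) ordered (ventral, middle,
    dorsal); ``mean`` is the record value.  Because regional extrema need
    not be simultaneous, per-breath rows may sum to more than 100% unless
    ``renormalize`` was requested.
    """

    per_breath: np.ndarray
    mean: np.ndarray
    rois: Tuple[str, ...] = SUB_ROIS
    renormalized: bool = False


def _as_pairs(x: Sequence[float], y: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    return x, y


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS fit y = slope * x + intercept with r^2 = squared Pearson r.

    Requires n >= 3 finite pairs and var(x) > 0.
    """
    x, y = _as_pairs(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 pairs for regression")
    if np.var(x) == 0:
        raise ValueError("var(x) is zero: regression undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n=int(x.size),
    )


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman statistics of method x against method y (d = x - y)."""
    x, y = _as_pairs(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 pairs for Bland-Altman analysis")
    d = x - y
    m = (x + y) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.var(m) > 0:
        slope = float(np.polyfit(m, d, 1)[0])
    else:
        slope = 0.0
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        proportional_slope=slope,
        n=int(x.size),
    )


def tidal_distribution(
    v: RegionalVolumeSeries,
    seg: BreathSegmentation,
    renormalize: bool = False,
) -> TidalDistribution:
    """Per-breath regional share of the global tidal amplitude, in percent.

    Per complete breath: ``100 * ptp(V_ROI) / ptp(V_global)`` within the
    cycle, for the ventral, middle and dorsal regions.  The global amplitude
    is the denominator, so asynchronous regional extrema can push the row
    sum above 100%; ``renormalize=True`` rescales each row to exactly 100.

    Raises
    ------
    ValueError
        On zero global amplitude or no complete breath.
    """
    complete = seg.complete_cycles
    if not complete:
        raise ValueError("no complete breath in record")
    rows = []
    for cyc in complete:
        g = float(np.ptp(v["global"][cyc.start : cyc.stop]))
        if g <= 0:
            raise ValueError("zero global tidal amplitude in a cycle")
        row = [
            100.0 * float(np.ptp(v[roi][cyc.start : cyc.stop])) / g
            for roi in SUB_ROIS
        ]
        rows.append(row)
    per_breath = np.asarray(rows, dtype=float)
    if renormalize:
        per_breath = per_breath / per_breath.sum(axis=1, keepdims=True) * 100.0
    return TidalDistribution(
        per_breath=per_breath,
        mean=per_breath.mean(axis=0),
        renormalized=renormalize,
    )
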