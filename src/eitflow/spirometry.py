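"""Phase metrics from the spirometric flow signal and EIT/spirometry pairing.

Spirometry measures flow directly (ml/s, inspiratory positive), so the late
phases use the arithmetic mean of the flow samples in the window rather
than a slope of an integrated volume.  Peaks are searched independently on
the spirometry signal; the breath segmentation is shared with the EIT arm
and transferred by time (the two records share a clock, optionally after a
cross-correlation lag correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .breath_phase import BreathSegmentation, PhaseFlowMetrics, MetricsSummary, METRIC_NAMES
from .eit_signal import RegionalFlowSeries

__all__ = [
    "SpiroFlowSeries",
    "PairedMetricSet",
    "extract_spiro_metrics",
    "estimate_lag",
    "align_and_pair",
]


@dataclass
class SpiroFlowSeries:
    """Spirometric flow trace in ml/s (inspiratory flow positive)."""

    flow: np.ndarray
    fs: float = 100.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        if self.flow.ndim != 1 or self.flow.size < 2:
            raise ValueError("flow must be a 1-D series with >= 2 samples")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.flow).all():
            raise ValueError("flow contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.flow.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.flow.size) / self.fs


def extract_spiro_metrics(
    spiro: SpiroFlowSeries,
    seg: BreathSegmentation,
    delay: float = 0.5,
    window: float = 3.0,
) -> List[PhaseFlowMetrics]:
    """PIF/LIF/PEF/LEF of the spirometry signal per complete breath.

    The segmentation (from the simultaneously recorded EIT arm) is mapped to
    the spirometry timebase.  Because the onset detector places an onset one
    EIT frame after the flow sign change, the physiological onset lies in
    the preceding frame interval; the transferred window is therefore
    shifted back by one EIT frame so the cycle keeps its own inspiratory
    peak and never swallows the next breath's onset.  PIF/PEF are the
    per-cycle maximum/minimum flow samples (earliest on ties); LIF/LEF are
    the mean flow over the window starting ``delay`` s after the respective
    peak, snapped to the nearest samples and clipped to the cycle and
    record.
    """
    complete = seg.complete_cycles
    if not complete:
        raise ValueError("no complete breath in segmentation")
    f = spiro.flow
    m = f.size
    shift = 1.0 / seg.fs
    out: List[PhaseFlowMetrics] = []
    for b, cyc in enumerate(complete):
        t_start, t_stop = seg.cycle_times(cyc)
        # the extra half-frame trim at the end keeps the next breath's onset
        # out of the window even after sub-frame lag corrections
        t_start -= shift
        t_stop -= 1.5 * shift
        i0 = max(int(math.ceil((t_start - spiro.t0) * spiro.fs - 1e-9)), 0)
        i1 = min(int(math.ceil((t_stop - spiro.t0) * spiro.fs - 1e-9)), m)
        seg_f = f[i0:i1]
        if seg_f.size == 0:
            out.append(
                PhaseFlowMetrics(
                    breath=b,
                    roi="global",
                    pif=float("nan"),
                    t_pif=float("nan"),
                    lif=float("nan"),
                    pef=float("nan"),
                    t_pef=float("nan"),
                    lef=float("nan"),
                    flags=("empty_cycle",),
                )
            )
            continue
        i_max = int(np.argmax(seg_f))
        i_min = int(np.argmin(seg_f))
        t_pif = spiro.t0 + (i0 + i_max) / spiro.fs
        t_pef = spiro.t0 + (i0 + i_min) / spiro.fs

        flags: List[str] = []

        def _mean_flow(t_peak: float, name: str) -> float:
            j0 = int(math.floor((t_peak + delay - spiro.t0) * spiro.fs + 0.5))
            j1 = int(math.floor((t_peak + delay + window - spiro.t0) * spiro.fs + 0.5))
            expected = j1 - j0 + 1
            lo = max(j0, 0, i0)
            hi = min(j1, m - 1, i1 - 1)
            if hi < lo:
                flags.append(f"{name}_rejected")
                return float("nan")
            coverage = (hi - lo + 1) / expected
            if coverage < 1.0 - 1e-12:
                flags.append(f"{name}_truncated")
            if coverage < 0.8:
                flags.append(f"{name}_rejected")
                return float("nan")
            return float(f[lo : hi + 1].mean())

        lif = _mean_flow(t_pif, "lif")
        lef = _mean_flow(t_pef, "lef")
        out.append(
            PhaseFlowMetrics(
                breath=b,
                roi="global",
                pif=float(seg_f[i_max]),
                t_pif=t_pif,
                lif=lif,
                pef=float(seg_f[i_min]),
                t_pef=t_pef,
                lef=lef,
                flags=tuple(flags),
            )
        )
    return out


def estimate_lag(
    eit_flow: RegionalFlowSeries,
    spiro: SpiroFlowSeries,
    max_lag: float,
) -> float:
    """Lag (s) of the EIT record relative to spirometry by cross-correlation.

    The global EIT flow is linearly interpolated onto the spirometry grid;
    the returned lag maximizes the correlation of ``spiro(t)`` with
    ``eit(t - lag)``, searched over +-``max_lag``.  A positive lag means the
    EIT events happen later on the shared clock.

    Raises
    ------
    ValueError
        If the best correlation sits on the search boundary (unalignable
        records).
    """
    t_e = eit_flow.times
    f_e = eit_flow["global"]
    t_s = spiro.times
    g = spiro.flow - spiro.flow.mean()
    max_shift = int(round(max_lag * spiro.fs))
    if max_shift < 1:
        raise ValueError("max_lag shorter than one spirometry sample")
    best: Tuple[float, int] = (-np.inf, 0)
    for k in range(-max_shift, max_shift + 1):
        lag = k / spiro.fs
        e = np.interp(t_s, t_e + lag, f_e, left=np.nan, right=np.nan)
        ok = np.isfinite(e)
        if ok.sum() < 2:
            continue
        ei = e[ok] - e[ok].mean()
        gi = g[ok]
        denom = math.sqrt(float(ei @ ei) * float(gi @ gi))
        if denom == 0:
            continue
        c = float(ei @ gi) / denom
        if c > best[0]:
            best = (c, k)
    if abs(best[1]) >= max_shift:
        raise ValueError("unalignable records: best lag at search boundary")
    return best[1] / spiro.fs


@dataclass
class PairedMetricSet:
    """Simultaneous (EIT, spirometry) value pairs for the four metrics."""

    pairs: Dict[str, Tuple[float, float]]  # metric -> (eit, spiro)

    def __post_init__(self) -> None:
        missing = set(METRIC_NAMES) - set(self.pairs)
        if missing:
            raise ValueError(f"missing metric pairs: {sorted(missing)}")

    def eit(self, metric: str) -> float:
        return self.pairs[metric][0]

    def spiro(self, metric: str) -> float:
        return self.pairs[metric][1]


def align_and_pair(
    eit_summary: MetricsSummary, spiro_summary: MetricsSummary
) -> PairedMetricSet:
    """Pair record-level global means of the four metrics across the two arms."""
    pairs = {
        name: (eit_summary.mean["global"][name], spiro_summary.mean["global"][name])
        for name in METRIC_NAMES
    }
    return PairedMetricSet(pairs=pairs)
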