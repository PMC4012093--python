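"""Breath segmentation and the four phase metrics PIF, LIF, PEF, LEF.

A respiratory cycle is delimited by inspiration onsets detected on the
global backward-difference flow.  Within each complete cycle:

* PIF / PEF are the maximum / minimum of the regional flow over the cycle
  (earliest sample on ties), with their times;
* LIF / LEF are the average slope of the regional volume curve over a
  window of ``window`` seconds starting ``delay`` seconds after the PIF /
  PEF time point (defaults 3.0 s and 0.5 s).  The windowed average rejects
  the cardiac oscillation riding on the aeration signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .eit_signal import ROI_NAMES, RegionalFlowSeries, RegionalVolumeSeries

__all__ = [
    "BreathCycle",
    "BreathSegmentation",
    "PeakFlows",
    "PhaseFlowMetrics",
    "MetricsSummary",
    "METRIC_NAMES",
    "segment_breaths",
    "detect_peak_flows",
    "late_flow",
    "extract_metrics",
    "summarize",
]

METRIC_NAMES: Tuple[str, ...] = ("pif", "lif", "pef", "lef")


@dataclass(frozen=True)
class BreathCycle:
    """Half-open sample range [start, stop) on the volume timebase."""

    start: int
    stop: int
    complete: bool

    def duration(self, fs: float) -> float:
        return (self.stop - self.start) / fs


@dataclass
class BreathSegmentation:
    """Ordered, non-overlapping respiratory cycles of one record."""

    cycles: List[BreathCycle]
    expected_duration: float  # s, from the respiratory-rate hint
    fs: float
    t0: float = 0.0

    @property
    def complete_cycles(self) -> List[BreathCycle]:
        return [c for c in self.cycles if c.complete]

    @property
    def n_complete(self) -> int:
        return len(self.complete_cycles)

    @property
    def onsets(self) -> np.ndarray:
        """Detected inspiration-onset sample indices.

        The detector never places an onset at sample 0, so a cycle starting
        there is the leading partial segment, not an onset.
        """
        return np.asarray([c.start for c in self.cycles if c.start > 0], dtype=int)

    def cycle_times(self, cycle: BreathCycle) -> Tuple[float, float]:
        """(t_start, t_stop) of a cycle in seconds."""
        return (self.t0 + cycle.start / self.fs, self.t0 + cycle.stop / self.fs)


def segment_breaths(
    v_global: np.ndarray | Sequence[float],
    fs: float,
    rr_hint: float,
    t0: float = 0.0,
) -> BreathSegmentation:
    """Detect respiratory cycles from the global volume (or impedance) curve.

    Inspiration onsets are upward zero-crossings of the backward-difference
    flow.  To stay robust against noise around zero flow late in expiration,
    a crossing only counts when the flow subsequently climbs above 25% of
    the record's maximum positive flow; the onset is placed at the last
    sample where flow was still at or below 2.5% of that maximum.  Onsets
    closer than half the expected cycle duration (refractory period) to the
    previous one are discarded.

    Leading and trailing partial cycles are kept but flagged incomplete; an
    interior cycle is complete when its duration is within +-50% of the
    expected duration ``60 / rr_hint``, the trailing cycle when it spans at
    least 75% of it.

    Raises
    ------
    ValueError
        If the record is shorter than one expected cycle, or no respiratory
        activity is found (flat signal / no qualifying onset).
    """
    v = np.asarray(v_global, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("v_global must be a 1-D series with >= 2 samples")
    if not rr_hint > 0:
        raise ValueError("rr_hint must be positive")
    expected = 60.0 / rr_hint
    duration = (v.size - 1) / fs
    if duration < 0.9 * expected:
        raise ValueError("no complete breath: record shorter than one expected cycle")
    if np.ptp(v) == 0:
        raise ValueError("no respiratory activity: flat signal")

    f = np.diff(v) * fs  # f[m] is flow at volume index m + 1
    fmax = float(f.max())
    if fmax <= 0:
        raise ValueError("no respiratory activity: no positive flow")
    hi = 0.25 * fmax
    lo = 0.025 * fmax

    above = f >= hi
    run_starts = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    refractory = 0.5 * expected * fs

    onsets: List[int] = []
    for m in run_starts:
        j = int(m)
        while j > 0 and f[j - 1] > lo:
            j -= 1
        onset = j + 1  # volume-sample index
        if onsets and onset - onsets[-1] < refractory:
            continue
        onsets.append(onset)
    if not onsets:
        raise ValueError("no respiratory activity: no inspiration onset found")

    cycles: List[BreathCycle] = []
    if onsets[0] >= max(2, int(round(0.05 * expected * fs))):
        cycles.append(BreathCycle(0, onsets[0], False))
    for a, b in zip(onsets, onsets[1:]):
        dur = (b - a) / fs
        cycles.append(BreathCycle(a, b, abs(dur - expected) <= 0.5 * expected))
    a = onsets[-1]
    dur = (v.size - a) / fs
    cycles.append(BreathCycle(a, v.size, 0.75 * expected <= dur <= 1.5 * expected))
    return BreathSegmentation(cycles=cycles, expected_duration=expected, fs=fs, t0=t0)


@dataclass(frozen=True)
class PeakFlows:
    """Peak flows of one region over one cycle (PEF negative by convention)."""

    pif: float
    t_pif: float
    pef: float
    t_pef: float


def detect_peak_flows(
    flow: RegionalFlowSeries, cycle: BreathCycle
) -> Dict[str, PeakFlows]:
    """Per-ROI maximum (PIF) and minimum (PEF) flow over one complete cycle.

    Ties are broken by the earliest sample.  Times are reported on the flow
    timebase (sample n of the flow sits at volume time point n + 1).
    """
    if not cycle.complete:
        raise ValueError("cannot compute peak flows on an incomplete cycle")
    j0 = max(cycle.start, 1) - 1  # flow-array index range for the cycle
    j1 = cycle.stop - 1
    times = flow.times
    out: Dict[str, PeakFlows] = {}
    for roi, f in flow.data.items():
        seg = f[j0:j1]
        if seg.size == 0:
            raise ValueError("cycle contains no flow samples")
        i_max = int(np.argmax(seg))
        i_min = int(np.argmin(seg))
        out[roi] = PeakFlows(
            pif=float(seg[i_max]),
            t_pif=float(times[j0 + i_max]),
            pef=float(seg[i_min]),
            t_pef=float(times[j0 + i_min]),
        )
    return out


def _window_indices(
    t_start: float, t_stop: float, fs: float, t0: float
) -> Tuple[int, int]:
    """Nearest-sample index pair (inclusive) for a time window."""
    i0 = int(math.floor((t_start - t0) * fs + 0.5))
    i1 = int(math.floor((t_stop - t0) * fs + 0.5))
    return i0, i1


def late_flow(
    volume: np.ndarray,
    fs: float,
    t_peak: float,
    delay: float = 0.5,
    window: float = 3.0,
    estimator: str = "ols",
    t0: float = 0.0,
    bounds: Tuple[int, int] | None = None,
) -> Tuple[float, float]:
    """Average slope of V(t) over [t_peak + delay, t_peak + delay + window].

    Window boundaries snap to the nearest sample; the window is clipped to
    the record and, when ``bounds`` (a half-open sample range, typically the
    breath) is given, to that range as well.

    Parameters
    ----------
    estimator:
        ``"ols"`` (default): ordinary-least-squares slope of V versus t over
        the window samples — robust against the cardiac oscillation.
        ``"endpoint"``: (V_end - V_start) / (t_end - t_start).

    Returns
    -------
    (slope, coverage):
        Slope in ml/s and the fraction of expected window samples actually
        used (1.0 when nothing was clipped).

    Raises
    ------
    ValueError
        If the clipped window holds fewer than two samples.
    """
    v = np.asarray(volume, dtype=float)
    if delay < 0 or window <= 0:
        raise ValueError("delay must be >= 0 and window > 0")
    if estimator not in ("ols", "endpoint"):
        raise ValueError(f"unknown estimator {estimator!r}")
    i0, i1 = _window_indices(t_peak + delay, t_peak + delay + window, fs, t0)
    expected = i1 - i0 + 1
    lo, hi = max(i0, 0), min(i1, v.size - 1)
    if bounds is not None:
        lo = max(lo, bounds[0])
        hi = min(hi, bounds[1] - 1)
    if hi - lo < 1:
        raise ValueError("empty late-flow window")
    coverage = (hi - lo + 1) / expected
    t = t0 + np.arange(lo, hi + 1) / fs
    seg = v[lo : hi + 1]
    if estimator == "ols":
        slope = float(np.polyfit(t, seg, 1)[0])
    else:
        slope = float((seg[-1] - seg[0]) / (t[-1] - t[0]))
    return slope, coverage


#: minimum window coverage below which a late-flow value is rejected
MIN_WINDOW_COVERAGE = 0.8


@dataclass
class PhaseFlowMetrics:
    """The four phase metrics of one region in one breath (ml/s)."""

    breath: int
    roi: str
    pif: float
    t_pif: float
    lif: float
    pef: float
    t_pef: float
    lef: float
    flags: Tuple[str, ...] = ()

    def value(self, metric: str) -> float:
        return getattr(self, metric)


def _flow_reversal(
    flow_seg: np.ndarray, vol_seg: np.ndarray, pif: float, pef: float
) -> bool:
    """Flag counter-phase flow (e.g. pendelluft) within a cycle."""
    span = pif - pef
    if span <= 0:
        return False
    eps = 0.02 * span
    i_peak_vol = int(np.argmax(vol_seg))
    insp = flow_seg[: max(i_peak_vol, 1)]
    exp = flow_seg[max(i_peak_vol, 1) :]
    return bool((insp < -eps).any() or (exp > eps).any())


def extract_metrics(
    flow: RegionalFlowSeries,
    volume: RegionalVolumeSeries,
    seg: BreathSegmentation,
    delay: float = 0.5,
    window: float = 3.0,
    estimator: str = "ols",
) -> List[PhaseFlowMetrics]:
    """Compute PIF/LIF/PEF/LEF per ROI for every complete breath.

    Incomplete (leading/trailing partial) cycles are skipped.  A late-flow
    window clipped by the record or breath is flagged ``*_truncated``; below
    80% coverage the value is rejected (NaN, ``*_rejected``).

    Raises
    ------
    ValueError
        If the segmentation has no complete breath.
    """
    complete = seg.complete_cycles
    if not complete:
        raise ValueError("no complete breath in record")
    results: List[PhaseFlowMetrics] = []
    for b, cycle in enumerate(complete):
        peaks = detect_peak_flows(flow, cycle)
        j0 = max(cycle.start, 1) - 1
        j1 = cycle.stop - 1
        for roi in ROI_NAMES:
            pk = peaks[roi]
            flags: List[str] = []
            vals = {}
            for name, t_peak in (("lif", pk.t_pif), ("lef", pk.t_pef)):
                try:
                    slope, cov = late_flow(
                        volume[roi],
                        volume.fs,
                        t_peak,
                        delay=delay,
                        window=window,
                        estimator=estimator,
                        t0=volume.t0,
                        bounds=(cycle.start, cycle.stop),
                    )
                except ValueError:
                    slope, cov = float("nan"), 0.0
                if cov < 1.0 - 1e-12:
                    flags.append(f"{name}_truncated")
                if cov < MIN_WINDOW_COVERAGE:
                    slope = float("nan")
                    flags.append(f"{name}_rejected")
                vals[name] = slope
            if _flow_reversal(
                flow[roi][j0:j1], volume[roi][cycle.start : cycle.stop], pk.pif, pk.pef
            ):
                flags.append("flow_reversal")
            results.append(
                PhaseFlowMetrics(
                    breath=b,
                    roi=roi,
                    pif=pk.pif,
                    t_pif=pk.t_pif,
                    lif=vals["lif"],
                    pef=pk.pef,
                    t_pef=pk.t_pef,
                    lef=vals["lef"],
                    flags=tuple(flags),
                )
            )
    return results


@dataclass
class MetricsSummary:
    """Mean +- sample sd of each metric per ROI across complete breaths."""

    mean: Dict[str, Dict[str, float]]  # roi -> metric -> mean
    sd: Dict[str, Dict[str, float]]  # roi -> metric -> sample sd (ddof=1)
    n_breaths: Dict[str, int]

    def rois(self) -> List[str]:
        return list(self.mean.keys())


def summarize(metrics: Sequence[PhaseFlowMetrics]) -> MetricsSummary:
    """Aggregate per-breath metrics into per-ROI mean +- sd.

    NaN values (rejected windows) are excluded per metric.  Sample sd uses
    ddof=1 and is NaN when only one breath contributes.
    """
    if not metrics:
        raise ValueError("no metrics to summarize")
    rois = sorted({m.roi for m in metrics}, key=lambda r: (ROI_NAMES + (r,)).index(r))
    mean: Dict[str, Dict[str, float]] = {}
    sd: Dict[str, Dict[str, float]] = {}
    n_breaths: Dict[str, int] = {}
    for roi in rois:
        rows = [m for m in metrics if m.roi == roi]
        n_breaths[roi] = len(rows)
        mean[roi] = {}
        sd[roi] = {}
        for name in METRIC_NAMES:
            vals = np.asarray([r.value(name) for r in rows], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                mean[roi][name] = float("nan")
                sd[roi][name] = float("nan")
            else:
                mean[roi][name] = float(vals.mean())
                sd[roi][name] = (
                    float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
                )
    return MetricsSummary(mean=mean, sd=sd, n_breaths=n_breaths)
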