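"""Pressure-controlled-ventilation simulator with closed-form ground truth.

Three lung compartments (ventral, middle, dorsal strip of the tomogram)
fill and empty exponentially once per ventilator cycle.  With cycle time
``T_c = 60 / rr``, inspiratory time ``T_i`` and expiratory time ``T_e``,
the volume of compartment *r* above its end-expiratory level is

* inspiration (0 <= u < T_i)::

      V_r(u) = f_r * V_T * (1 - exp(-u / tau_i)) / (1 - exp(-T_i / tau_i))

* expiration (T_i <= u < T_c)::

      V_r(u) = f_r * V_T * (exp(-(u - T_i) / tau_e) - exp(-T_e / tau_e))
               / (1 - exp(-T_e / tau_e))

where ``u`` is the time into the cycle and ``f_r`` the compartment's share
of the tidal volume.  Both branches are normalized so each breath reaches
exactly ``f_r * V_T`` at end-inspiration and returns exactly to baseline at
end-expiration, giving exact periodic ground truth.

The EIT arm distributes each compartment signal uniformly over its ROI
pixels (arbitrary impedance gain), optionally low-pass filters it ("tissue
inertance"), adds a cardiac sinusoid to the middle-ROI pixels and seeded
Gaussian pixel noise.  The spirometry arm is the analytic derivative of the
global volume sampled at the spirometer rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .eit_signal import ROI_NAMES, SUB_ROIS, PixelFrameSeries, ROILayout
from .spirometry import SpiroFlowSeries

__all__ = [
    "VentilatorSettings",
    "LungModelConfig",
    "BreathTruth",
    "GroundTruth",
    "compartment_volumes",
    "compartment_flows",
    "simulate_record",
    "analytic_ground_truth",
    "lavage_preset",
]


@dataclass(frozen=True)
class VentilatorSettings:
    """Ventilator settings of a pressure-controlled mode.

    ``rr`` in breaths/min, ``ie_ratio`` as the I/E quotient (1.0 means 1:1),
    ``v_t`` in ml.  ``peep`` (mbar) and ``fio2`` are metadata only.
    """

    rr: float = 8.0
    ie_ratio: float = 1.0
    v_t: float = 300.0
    peep: float = 5.0
    fio2: float = 0.5

    def __post_init__(self) -> None:
        if not self.rr > 0:
            raise ValueError("rr must be positive")
        if not self.v_t > 0:
            raise ValueError("v_t must be positive")
        if not self.ie_ratio > 0:
            raise ValueError("ie_ratio must be positive")

    @property
    def cycle_duration(self) -> float:
        """Duration of one full respiratory cycle in s (60 / RR)."""
        return 60.0 / self.rr

    @property
    def t_insp(self) -> float:
        """Inspiratory time in s: cycle * I / (I + E)."""
        return self.cycle_duration * self.ie_ratio / (1.0 + self.ie_ratio)

    @property
    def t_exp(self) -> float:
        """Expiratory time in s."""
        return self.cycle_duration - self.t_insp


@dataclass(frozen=True)
class LungModelConfig:
    """Generative lung model: compartment shares, time constants, artifacts.

    ``fractions`` are the (ventral, middle, dorsal) shares of the tidal
    volume and must sum to 1.  ``cardiac_rel`` is the cardiac-oscillation
    amplitude as a fraction of V_T (added to middle-ROI pixels only;
    heart region lies mid-thorax).  ``noise_sd`` is the per-pixel Gaussian
    noise sd relative to the per-pixel share of the global tidal amplitude.
    ``spiro_noise_sd`` is relative to the peak spirometric flow.
    ``inertance_tau`` (s), when set, applies a first-order low-pass to the
    EIT signal path only, mimicking tissue inertance.
    """

    fractions: Tuple[float, float, float] = (0.2, 0.5, 0.3)
    tau_insp: Tuple[float, float, float] = (0.8, 0.6, 0.7)
    tau_exp: Tuple[float, float, float] = (0.8, 0.6, 0.7)
    cardiac_rel: float = 0.02
    cardiac_freq: float = 1.5
    noise_sd: float = 0.0
    spiro_noise_sd: float = 0.0
    inertance_tau: Optional[float] = None
    impedance_gain: float = 0.01

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.size != 3 or (f < 0).any():
            raise ValueError("fractions must be 3 non-negative values")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {f.sum()!r}")
        for tau in (*self.tau_insp, *self.tau_exp):
            if not tau > 0:
                raise ValueError("time constants must be positive")
        if self.inertance_tau is not None and not self.inertance_tau > 0:
            raise ValueError("inertance_tau must be positive when set")


def _comp_volume(
    u: np.ndarray, f: float, tau_i: float, tau_e: float, t_i: float, t_e: float, v_t: float
) -> np.ndarray:
    v = np.empty_like(u)
    insp = u < t_i
    v[insp] = f * v_t * (1.0 - np.exp(-u[insp] / tau_i)) / (1.0 - math.exp(-t_i / tau_i))
    ue = u[~insp] - t_i
    v[~insp] = (
        f
        * v_t
        * (np.exp(-ue / tau_e) - math.exp(-t_e / tau_e))
        / (1.0 - math.exp(-t_e / tau_e))
    )
    return v


def _comp_flow(
    u: np.ndarray, f: float, tau_i: float, tau_e: float, t_i: float, t_e: float, v_t: float
) -> np.ndarray:
    """Analytic derivative of the compartment volume (right-continuous)."""
    q = np.empty_like(u)
    insp = u < t_i
    q[insp] = (
        f * v_t / (tau_i * (1.0 - math.exp(-t_i / tau_i))) * np.exp(-u[insp] / tau_i)
    )
    ue = u[~insp] - t_i
    q[~insp] = (
        -f * v_t / (tau_e * (1.0 - math.exp(-t_e / tau_e))) * np.exp(-ue / tau_e)
    )
    return q


def compartment_volumes(
    t: np.ndarray, vent: VentilatorSettings, model: LungModelConfig
) -> np.ndarray:
    """Closed-form compartment volumes, shape (3, len(t)), in ml."""
    t = np.asarray(t, dtype=float)
    u = np.mod(t, vent.cycle_duration)
    out = np.empty((3, t.size))
    for r, (f, ti, te) in enumerate(zip(model.fractions, model.tau_insp, model.tau_exp)):
        out[r] = _comp_volume(u, f, ti, te, vent.t_insp, vent.t_exp, vent.v_t)
    return out


def compartment_flows(
    t: np.ndarray, vent: VentilatorSettings, model: LungModelConfig
) -> np.ndarray:
    """Closed-form compartment flows, shape (3, len(t)), in ml/s."""
    t = np.asarray(t, dtype=float)
    u = np.mod(t, vent.cycle_duration)
    out = np.empty((3, t.size))
    for r, (f, ti, te) in enumerate(zip(model.fractions, model.tau_insp, model.tau_exp)):
        out[r] = _comp_flow(u, f, ti, te, vent.t_insp, vent.t_exp, vent.v_t)
    return out


def _lowpass(x: np.ndarray, fs: float, tau: float) -> np.ndarray:
    """Zero-phase first-order low-pass along the last axis.

    Applied forward and backward (scipy ``filtfilt``) so fast transients
    (the inspiratory/expiratory peaks) are attenuated without a group
    delay: slow late-phase slopes pass through unchanged, which is exactly
    the error structure tissue inertance imposes on the EIT signal path.
    """
    from scipy.signal import filtfilt

    a_c = 1.0 - math.exp(-1.0 / (fs * tau))
    return filtfilt([a_c], [1.0, a_c - 1.0], x, axis=-1)


@dataclass
class BreathTruth:
    """Analytic metric values of one region in one complete breath."""

    breath: int
    roi: str
    pif: float
    t_pif: float
    lif: float
    pef: float
    t_pef: float
    lef: float


@dataclass
class GroundTruth:
    """Closed-form truth for a simulated record (noise- and cardiac-free).

    ``eit`` holds per-breath metrics on the discrete EIT grid, calibrated
    exactly the way the analysis calibrates (one global tidal amplitude for
    the whole record); ``spiro`` holds the global-ROI metrics on the
    spirometer grid in true ml/s.  ``continuous`` carries the analytic peak
    flows of the underlying continuous waveform.
    """

    onsets_s: np.ndarray  # true breath onset times
    onset_indices: np.ndarray  # onset sample indices on the EIT grid
    cycles: List[Tuple[int, int, bool]]  # (start, stop, complete) EIT samples
    z_t: float  # tidal impedance amplitude (impedance units)
    calibration: float  # ml of calibrated volume per ml of model volume
    eit: List[BreathTruth]
    spiro: List[BreathTruth]
    continuous: Dict[str, Dict[str, float]]  # roi -> {"pif": ..., "pef": ...}

    def metric_array(self, arm: str, roi: str, metric: str) -> np.ndarray:
        rows = self.eit if arm == "eit" else self.spiro
        return np.asarray(
            [getattr(b, metric) for b in rows if b.roi == roi], dtype=float
        )


def _detected_onset_index(s: float, fs: float) -> int:
    """Sample index at which the analysis detects an onset at true time s."""
    return int(math.floor(s * fs + 1e-9)) + 1


def _truth_cycles(
    onsets_s: np.ndarray, fs: float, n: int, t_c: float
) -> Tuple[np.ndarray, List[Tuple[int, int, bool]]]:
    idx = np.asarray([_detected_onset_index(s, fs) for s in onsets_s], dtype=int)
    idx = idx[idx < n]
    cycles: List[Tuple[int, int, bool]] = []
    for a, b in zip(idx, idx[1:]):
        dur = (b - a) / fs
        cycles.append((int(a), int(b), abs(dur - t_c) <= 0.5 * t_c))
    a = int(idx[-1])
    dur = (n - a) / fs
    cycles.append((a, n, 0.75 * t_c <= dur <= 1.5 * t_c))
    return idx, cycles


def _window_slope(
    v: np.ndarray,
    fs: float,
    t_peak: float,
    delay: float,
    window: float,
    bounds: Tuple[int, int],
    estimator: str,
) -> float:
    """Late-flow truth on a sampled closed-form volume curve."""
    i0 = int(math.floor((t_peak + delay) * fs + 0.5))
    i1 = int(math.floor((t_peak + delay + window) * fs + 0.5))
    lo = max(i0, 0, bounds[0])
    hi = min(i1, v.size - 1, bounds[1] - 1)
    t = np.arange(lo, hi + 1) / fs
    seg = v[lo : hi + 1]
    if estimator == "ols":
        return float(np.polyfit(t, seg, 1)[0])
    return float((seg[-1] - seg[0]) / (t[-1] - t[0]))


def analytic_ground_truth(
    vent: VentilatorSettings,
    model: LungModelConfig,
    fs_eit: float = 13.0,
    fs_spiro: float = 100.0,
    duration: float = 60.0,
    delay: float = 0.5,
    window: float = 3.0,
    estimator: str = "ols",
) -> GroundTruth:
    """Closed-form metric truth on both sampling grids.

    Evaluates the analytic compartment model directly on the EIT and
    spirometer grids and applies the metric definitions (window snapping,
    tie-breaking, record-level calibration) to the exact waveform.  Cardiac
    oscillation and noise are disturbances the analysis must reject, so they
    never enter the truth; the inertance low-pass, when configured, does
    affect the EIT-side truth (it acts on the signal path).
    """
    t_c, t_i = vent.cycle_duration, vent.t_insp
    n = int(round(duration * fs_eit))
    t_eit = np.arange(n) / fs_eit
    comp = compartment_volumes(t_eit, vent, model)
    if model.inertance_tau is not None:
        comp = _lowpass(comp, fs_eit, model.inertance_tau)
    vols: Dict[str, np.ndarray] = dict(zip(SUB_ROIS, comp))
    vols["global"] = comp.sum(axis=0)

    n_breaths = int(math.ceil(duration / t_c - 1e-9))
    onsets_s = np.arange(n_breaths) * t_c
    onset_idx, cycles = _truth_cycles(onsets_s, fs_eit, n, t_c)

    amps = [float(np.ptp(vols["global"][a:b])) for a, b, ok in cycles if ok]
    if not amps:
        raise ValueError("duration too short: no complete breath in truth")
    mean_amp = float(np.mean(amps))
    calibration = vent.v_t / mean_amp
    z_t = model.impedance_gain * mean_amp

    eit_rows: List[BreathTruth] = []
    for b_idx, (a, b, ok) in enumerate(c for c in cycles):
        if not ok:
            continue
        for roi in ROI_NAMES:
            v = vols[roi]
            d = np.diff(v) * fs_eit  # d[m] at sample m + 1, time (m+1)/fs
            seg = d[max(a, 1) - 1 : b - 1]
            i_max = int(np.argmax(seg))
            i_min = int(np.argmin(seg))
            t_pif = (max(a, 1) + i_max) / fs_eit
            t_pef = (max(a, 1) + i_min) / fs_eit
            lif = _window_slope(v, fs_eit, t_pif, delay, window, (a, b), estimator)
            lef = _window_slope(v, fs_eit, t_pef, delay, window, (a, b), estimator)
            eit_rows.append(
                BreathTruth(
                    breath=len([r for r in eit_rows if r.roi == roi]),
                    roi=roi,
                    pif=float(seg[i_max]) * calibration,
                    t_pif=t_pif,
                    lif=lif * calibration,
                    pef=float(seg[i_min]) * calibration,
                    t_pef=t_pef,
                    lef=lef * calibration,
                )
            )

    # spirometry arm: true flow on the spirometer grid, no calibration and
    # no inertance (measured at the airway, outside the thorax)
    m = int(round(duration * fs_spiro))
    t_sp = np.arange(m) / fs_spiro
    flow_sp = compartment_flows(t_sp, vent, model).sum(axis=0)
    spiro_rows: List[BreathTruth] = []
    breath = 0
    for a, b, ok in cycles:
        if not ok:
            continue
        # the detected onset lags the physiological one by a frame: shift
        # the transferred window back by one EIT frame, trimming an extra
        # half frame at the end (mirrors extract_spiro_metrics)
        t_start, t_stop = (a - 1) / fs_eit, (b - 1.5) / fs_eit
        i0 = max(int(math.ceil(t_start * fs_spiro - 1e-9)), 0)
        i1 = min(int(math.ceil(t_stop * fs_spiro - 1e-9)), m)
        seg = flow_sp[i0:i1]
        i_max = int(np.argmax(seg))
        i_min = int(np.argmin(seg))
        t_pif = (i0 + i_max) / fs_spiro
        t_pef = (i0 + i_min) / fs_spiro

        def _mean_flow(t_peak: float) -> float:
            j0 = int(math.floor((t_peak + delay) * fs_spiro + 0.5))
            j1 = int(math.floor((t_peak + delay + window) * fs_spiro + 0.5))
            lo_j = max(j0, 0, i0)
            hi_j = min(j1, m - 1, i1 - 1)
            return float(flow_sp[lo_j : hi_j + 1].mean())

        spiro_rows.append(
            BreathTruth(
                breath=breath,
                roi="global",
                pif=float(seg[i_max]),
                t_pif=t_pif,
                lif=_mean_flow(t_pif),
                pef=float(seg[i_min]),
                t_pef=t_pef,
                lef=_mean_flow(t_pef),
            )
        )
        breath += 1

    continuous: Dict[str, Dict[str, float]] = {}
    k_i = np.asarray(
        [
            f * vent.v_t / (ti * (1.0 - math.exp(-t_i / ti)))
            for f, ti in zip(model.fractions, model.tau_insp)
        ]
    )
    k_e = np.asarray(
        [
            f * vent.v_t / (te * (1.0 - math.exp(-vent.t_exp / te)))
            for f, te in zip(model.fractions, model.tau_exp)
        ]
    )
    for roi, ki, ke in zip(SUB_ROIS, k_i, k_e):
        continuous[roi] = {"pif": float(ki), "pef": float(-ke)}
    continuous["global"] = {"pif": float(k_i.sum()), "pef": float(-k_e.sum())}

    return GroundTruth(
        onsets_s=onsets_s,
        onset_indices=onset_idx,
        cycles=cycles,
        z_t=z_t,
        calibration=calibration,
        eit=eit_rows,
        spiro=spiro_rows,
        continuous=continuous,
    )


def simulate_record(
    vent: VentilatorSettings,
    model: LungModelConfig,
    duration: float = 60.0,
    fs_eit: float = 13.0,
    fs_spiro: float = 100.0,
    seed: Optional[int] = None,
    layout: Optional[ROILayout] = None,
) -> Tuple[PixelFrameSeries, SpiroFlowSeries, GroundTruth]:
    """Generate a paired EIT tomogram series and spirometric flow trace.

    All randomness derives from ``seed``; identical seeds give identical
    outputs.  Returns (frames, spiro, ground_truth).
    """
    if duration < vent.cycle_duration:
        raise ValueError("duration must cover at least one respiratory cycle")
    if fs_eit >= fs_spiro:
        warnings.warn(
            "fs_eit >= fs_spiro: EIT grid is not coarser than spirometry",
            stacklevel=2,
        )
    layout = layout if layout is not None else ROILayout()
    rng = np.random.default_rng(seed)

    n = int(round(duration * fs_eit))
    t_eit = np.arange(n) / fs_eit
    comp = compartment_volumes(t_eit, vent, model)
    if model.inertance_tau is not None:
        comp = _lowpass(comp, fs_eit, model.inertance_tau)

    frames = np.zeros((n, layout.n_rows, layout.n_cols))
    gain = model.impedance_gain
    n_lung_px = 0
    for roi, v_r in zip(SUB_ROIS, comp):
        rows = layout.rows(roi)
        n_px = (rows.stop - rows.start) * layout.n_cols
        n_lung_px += n_px
        frames[:, rows, :] = (gain * v_r / n_px)[:, None, None]
    if model.cardiac_rel > 0:
        rows = layout.rows("middle")
        n_px = (rows.stop - rows.start) * layout.n_cols
        cardiac = (
            gain
            * model.cardiac_rel
            * vent.v_t
            * np.sin(2.0 * math.pi * model.cardiac_freq * t_eit)
            / n_px
        )
        frames[:, rows, :] += cardiac[:, None, None]
    if model.noise_sd > 0:
        sd = model.noise_sd * gain * vent.v_t / n_lung_px
        frames += rng.normal(0.0, sd, frames.shape)
    pixel_series = PixelFrameSeries(frames=frames, fs=fs_eit, t0=0.0)

    m = int(round(duration * fs_spiro))
    t_sp = np.arange(m) / fs_spiro
    flow = compartment_flows(t_sp, vent, model).sum(axis=0)
    if model.spiro_noise_sd > 0:
        flow = flow + rng.normal(0.0, model.spiro_noise_sd * float(np.abs(flow).max()), m)
    spiro = SpiroFlowSeries(flow=flow, fs=fs_spiro, t0=0.0)

    truth = analytic_ground_truth(
        vent, model, fs_eit=fs_eit, fs_spiro=fs_spiro, duration=duration
    )
    return pixel_series, spiro, truth


def study_conditions(
    n_subjects: int = 7,
    n_settings: int = 6,
    seed: Optional[int] = None,
    tau_base: Tuple[float, float, float] = (2.2, 1.9, 2.0),
    noise_sd: float = 0.02,
    spiro_noise_sd: float = 0.005,
    cardiac_rel: float = 0.0,
    inertance_tau: Optional[float] = None,
    rr: float = 8.0,
    ie_ratio: float = 1.0,
) -> List[Tuple[VentilatorSettings, LungModelConfig, int]]:
    """Condition grid for method-comparison studies (subjects x settings).

    Mirrors the shape of a 7-subjects-by-6-settings validation design:
    subject weights are drawn uniformly from 20-26 kg, the tidal volume per
    setting alternates between 15 and 20 ml/kg across PEEP levels, and each
    subject carries its own mild (+-10%) time-constant jitter.  Returns
    (ventilator, model, record_seed) triples; all randomness derives from
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    conditions: List[Tuple[VentilatorSettings, LungModelConfig, int]] = []
    for _ in range(n_subjects):
        weight = float(rng.uniform(20.0, 26.0))
        jitter = float(rng.uniform(0.9, 1.1))
        taus = tuple(float(tau * jitter) for tau in tau_base)
        for s in range(n_settings):
            vt_per_kg = 15.0 if s % 2 == 0 else 20.0
            peep = float((s // 2) * 5)
            vent = VentilatorSettings(rr=rr, ie_ratio=ie_ratio, v_t=vt_per_kg * weight, peep=peep)
            model = LungModelConfig(
                tau_insp=taus,
                tau_exp=taus,
                cardiac_rel=cardiac_rel,
                noise_sd=noise_sd,
                spiro_noise_sd=spiro_noise_sd,
                inertance_tau=inertance_tau,
            )
            conditions.append((vent, model, int(rng.integers(0, 2**31))))
    return conditions


def lavage_preset(
    model: LungModelConfig, dorsal_scale: float = 0.11 / 0.36
) -> LungModelConfig:
    """Shift the amplitude pattern toward a surfactant-depletion injury.

    Scales the dorsal (dependent) share down (default to the 0.36 -> 0.11
    pattern) and renormalizes the shares to 1.  A generative preset, not a
    reproduction of any measured distribution.
    """
    f = np.asarray(model.fractions, dtype=float)
    f[2] *= dorsal_scale
    f /= f.sum()
    return replace(model, fractions=tuple(float(x) for x in f))
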