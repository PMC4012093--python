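"""Regional impedance extraction, volume calibration and flow derivation.

The tomogram is a ``T x rows x cols`` stack of relative impedance change.
Rows are anatomical: row 0 is the most ventral row, the last row the most
dorsal.  A :class:`ROILayout` partitions the rows into ventral, middle and
dorsal strips plus an excluded block that never enters any regional sum; the
global region is the union of the three strips.

Processing chain::

    PixelFrameSeries --extract_roi_series--> RegionalImpedanceSeries
        --calibrate_volume--> RegionalVolumeSeries
        --differentiate--> RegionalFlowSeries

Units are fixed: volumes in ml, times in s, flows in ml/s.  Impedance is
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "ROI_NAMES",
    "SUB_ROIS",
    "PixelFrameSeries",
    "ROILayout",
    "RegionalImpedanceSeries",
    "RegionalVolumeSeries",
    "RegionalFlowSeries",
    "extract_roi_series",
    "compute_tidal_amplitude",
    "calibrate_volume",
    "differentiate",
]

#: All regions, global first.
ROI_NAMES: Tuple[str, ...] = ("global", "ventral", "middle", "dorsal")
#: The three disjoint strips whose union is the global region.
SUB_ROIS: Tuple[str, ...] = ("ventral", "middle", "dorsal")


@dataclass
class PixelFrameSeries:
    """A tomogram time series of relative impedance change.

    Parameters
    ----------
    frames:
        Array of shape ``(T, rows, cols)``; dimensionless relative impedance
        change per pixel.  ``T >= 2`` and all values finite.
    fs:
        Sampling rate in frames per second (> 0).
    t0:
        Time of the first frame in seconds.
    """

    frames: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (T, rows, cols) array, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite pixel values")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> Tuple[int, int]:
        """(rows, cols) of a single frame."""
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_frames) / self.fs


RowRange = Tuple[int, int]


@dataclass(frozen=True)
class ROILayout:
    """Half-open row ranges partitioning the tomogram rows.

    The default is the 32x32 layout: ventral rows [0, 8), middle [8, 16),
    dorsal [16, 24); the dorsal-most block [24, 32) is excluded because it
    contains no lung.  The three strips plus the excluded range must be
    disjoint and cover all rows.  Any matrix size works as long as the
    ranges are consistent, so reduced test matrices (e.g. 8x8) are fine.
    """

    ventral: RowRange = (0, 8)
    middle: RowRange = (8, 16)
    dorsal: RowRange = (16, 24)
    excluded: RowRange = (24, 32)
    n_rows: int = 32
    n_cols: int = 32

    def __post_init__(self) -> None:
        covered = np.zeros(self.n_rows, dtype=int)
        for lo, hi in (self.ventral, self.middle, self.dorsal, self.excluded):
            if not (0 <= lo <= hi <= self.n_rows):
                raise ValueError(f"row range ({lo}, {hi}) outside 0..{self.n_rows}")
            covered[lo:hi] += 1
        if (covered > 1).any():
            raise ValueError("ROI row ranges overlap")
        if (covered == 0).any():
            raise ValueError("ROI row ranges do not cover every row")

    def rows(self, roi: str) -> slice:
        """Row slice for one sub-region ('ventral' | 'middle' | 'dorsal')."""
        lo, hi = getattr(self, roi)
        return slice(lo, hi)

    def mask(self, roi: str) -> np.ndarray:
        """Boolean pixel mask of shape (n_rows, n_cols) for any region."""
        m = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        if roi == "global":
            for sub in SUB_ROIS:
                m[self.rows(sub), :] = True
        else:
            m[self.rows(roi), :] = True
        return m


@dataclass
class _RegionalSeries:
    """Per-ROI time series keyed by ROI name (shared container logic)."""

    data: Dict[str, np.ndarray]
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = {k: np.asarray(v, dtype=float) for k, v in self.data.items()}
        lengths = {v.size for v in self.data.values()}
        if len(lengths) != 1:
            raise ValueError("all regional series must have equal length")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    def __getitem__(self, roi: str) -> np.ndarray:
        return self.data[roi]

    @property
    def n_samples(self) -> int:
        return next(iter(self.data.values())).size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class RegionalImpedanceSeries(_RegionalSeries):
    """Per-ROI relative impedance change Z_ROI(t), dimensionless."""


@dataclass
class RegionalVolumeSeries(_RegionalSeries):
    """Per-ROI calibrated volume V_ROI(t) in ml.

    ``v_t`` (ml) and ``z_t`` (dimensionless) record the calibration pair
    used to scale impedance into volume.
    """

    v_t: float = float("nan")
    z_t: float = float("nan")


@dataclass
class RegionalFlowSeries(_RegionalSeries):
    """Per-ROI gas flow V'_ROI(t) in ml/s (backward difference).

    Sample ``n`` of a flow series corresponds to time point ``n + 1`` of the
    originating volume series: the first volume sample has no flow value, so
    the series is one sample shorter and :attr:`times` starts at
    ``t0 + 1/fs``.
    """

    @property
    def times(self) -> np.ndarray:  # shifted: sample n <-> volume sample n+1
        return self.t0 + (np.arange(self.n_samples) + 1.0) / self.fs


def extract_roi_series(
    frames: PixelFrameSeries, layout: ROILayout | None = None
) -> RegionalImpedanceSeries:
    """Sum pixel values over each ROI to obtain Z_ROI(t).

    The global series is the sum of the three strips by construction, so
    Z_global(t) = Z_ventral(t) + Z_middle(t) + Z_dorsal(t) holds exactly.
    Excluded rows contribute to no region.

    Raises
    ------
    ValueError
        If the frame matrix shape disagrees with the layout.
    """
    layout = layout if layout is not None else ROILayout()
    rows, cols = frames.shape
    if rows != layout.n_rows or cols != layout.n_cols:
        raise ValueError(
            f"frame matrix is {rows}x{cols}, layout expects "
            f"{layout.n_rows}x{layout.n_cols}"
        )
    data: Dict[str, np.ndarray] = {}
    for roi in SUB_ROIS:
        data[roi] = frames.frames[:, layout.rows(roi), :].sum(axis=(1, 2))
    data["global"] = data["ventral"] + data["middle"] + data["dorsal"]
    return RegionalImpedanceSeries(data=data, fs=frames.fs, t0=frames.t0)


def compute_tidal_amplitude(z: RegionalImpedanceSeries, seg) -> float:
    """Tidal difference Z_T of the global impedance signal.

    Per complete respiratory cycle the amplitude is max - min of Z_global
    within the cycle (robust to in-cycle drift and to segmentation boundary
    jitter); Z_T is the mean amplitude over all complete cycles.

    Raises
    ------
    ValueError
        If the segmentation holds no complete breath, or the signal is flat
        (Z_T == 0, uncalibratable record).
    """
    zg = z["global"]
    amplitudes = [
        float(np.ptp(zg[c.start : c.stop])) for c in seg.cycles if c.complete
    ]
    if not amplitudes:
        raise ValueError("no complete breath: cannot compute tidal amplitude")
    z_t = float(np.mean(amplitudes))
    if z_t <= 0.0:
        raise ValueError("zero tidal amplitude: record cannot be calibrated")
    return z_t


def calibrate_volume(
    z: RegionalImpedanceSeries, v_t: float, z_t: float
) -> RegionalVolumeSeries:
    """Scale impedance to volume: V_ROI(t) = Z_ROI(t) * v_t / z_t.

    One global ``z_t`` calibrates all four regions, which preserves
    additivity and makes the regional volumes sum to the regional
    distribution of the tidal volume ``v_t``.
    """
    if not v_t > 0:
        raise ValueError("tidal volume v_t must be positive")
    if not z_t > 0:
        raise ValueError("tidal impedance z_t must be positive")
    scale = v_t / z_t
    data = {roi: series * scale for roi, series in z.data.items()}
    return RegionalVolumeSeries(data=data, fs=z.fs, t0=z.t0, v_t=v_t, z_t=z_t)


def differentiate(v: RegionalVolumeSeries) -> RegionalFlowSeries:
    """Backward-difference flow: V'(t_n) = (V(t_n) - V(t_{n-1})) * fs.

    Defined for every recorded time point except the first one, so the flow
    series has ``T - 1`` samples aligned to t_1 .. t_{T-1}.
    """
    if v.n_samples < 2:
        raise ValueError("need at least 2 volume samples to differentiate")
    data = {roi: np.diff(series) * v.fs for roi, series in v.data.items()}
    return RegionalFlowSeries(data=data, fs=v.fs, t0=v.t0)
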