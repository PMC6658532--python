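"""MSD curves and corrected diffusion-coefficient estimation.

For 2D Brownian motion the expected mean squared displacement over a lag τ
is ⟨r²⟩ = 4Dτ. Two corrections matter for camera-based single-particle
tracking at 50-ms frames:

* localization error — each measured position carries an independent error
  of σ per axis, inflating every squared displacement by 4σ² (estimated
  from "trajectories" of emitters in fixed cells, MSD₁,fixed = 2σ²_2D);
* motion blur — continuous illumination averages the emitter position over
  the frame, contracting the apparent single-step displacement by a factor
  2/3, corrected by multiplying by 1.5.

The two single-lag estimators used throughout:

    D₁ = 1.5 · (MSD₁ − MSD₁,fixed) / (4 · 0.05 s)       (blur + error corrected)
    D₂ = (MSD₂ − MSD₁) / (4 · 0.05 s)                    (corrections cancel)

All MSD values are in μm², coordinates in nm, D in μm²/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_tables import Track

__all__ = [
    "MSDCurve",
    "DiffusionEstimate",
    "LocalizationCalibration",
    "ConfinementEstimate",
    "compute_msd",
    "calibrate_localization",
    "estimate_D1",
    "estimate_D2",
    "estimate_confinement_radius",
    "step_histogram",
    "BLUR_FACTOR",
]

#: Correction factor for motion blur under continuous acquisition.
BLUR_FACTOR = 1.5

NM2_TO_UM2 = 1e-6


@dataclass
class MSDCurve:
    """Lag-indexed ensemble MSD with SEM and interval counts."""

    lags_s: np.ndarray
    msd: np.ndarray  # μm²
    sem: np.ndarray  # μm²
    n_intervals: np.ndarray
    overlapping: bool = True
    frame_interval: float = 0.05

    def msd_at_lag(self, lag_frames: int) -> float:
        return float(self.msd[lag_frames - 1])


@dataclass
class DiffusionEstimate:
    D: float  # μm²/s
    method: str  # "single_step_D1" or "slope_D2"
    msd1_fixed_used: float = 0.0
    blur_factor: float | None = None
    sem: float | None = None
    negative: bool = False


@dataclass
class LocalizationCalibration:
    """Localization-error calibration from fixed-cell trajectories.

    MSD₁,fixed = 2σ²_2D = 4σ²_axis, with σ in nm.
    """

    msd1_fixed: float  # μm²
    n_intervals: int = 0

    @property
    def sigma_2d_nm(self) -> float:
        return float(np.sqrt(self.msd1_fixed / 2.0) * 1000.0)

    @property
    def sigma_axis_nm(self) -> float:
        return self.sigma_2d_nm / np.sqrt(2.0)


@dataclass
class ConfinementEstimate:
    plateau: float  # μm²
    r_c_nm: float
    msd1_fixed_used: float = 0.0


def _squared_displacements(track: Track, lag: int, overlapping: bool) -> np.ndarray:
    n = len(track)
    if n <= lag:
        return np.empty(0)
    # non-overlapping intervals share no localization (stride lag + 1)
    starts = np.arange(0, n - lag, 1 if overlapping else lag + 1)
    d = track.xy[starts + lag] - track.xy[starts]
    return np.sum(d**2, axis=1) * NM2_TO_UM2


def compute_msd(
    tracks: Sequence[Track],
    max_lag: int = 10,
    overlapping: bool = True,
    frame_interval: float = 0.05,
) -> MSDCurve:
    """Ensemble MSD over all occurrences of each time interval in all tracks.

    With ``overlapping`` (the default) every index pair (i, i+k) contributes
    at lag k, which yields a correlated sample; the SEM reported per lag
    ignores that correlation.
    """
    if len(tracks) == 0:
        raise ValueError("no tracks supplied")
    msd = np.full(max_lag, np.nan)
    sem = np.full(max_lag, np.nan)
    counts = np.zeros(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        vals = [v for t in tracks if (v := _squared_displacements(t, k, overlapping)).size]
        if not vals:
            continue
        allv = np.concatenate(vals)
        counts[k - 1] = allv.size
        msd[k - 1] = allv.mean()
        sem[k - 1] = allv.std(ddof=1) / np.sqrt(allv.size) if allv.size > 1 else np.nan
    if counts[max_lag - 1] == 0:
        raise ValueError("max_lag exceeds every track length (no intervals at the top lag)")
    return MSDCurve(
        lags_s=np.arange(1, max_lag + 1) * frame_interval,
        msd=msd,
        sem=sem,
        n_intervals=counts,
        overlapping=overlapping,
        frame_interval=frame_interval,
    )


def calibrate_localization(
    fixed_tracks: Sequence[Track],
    frame_interval: float = 0.05,
) -> LocalizationCalibration:
    """Estimate the localization error from stationary-emitter trajectories."""
    curve = compute_msd(fixed_tracks, max_lag=1, frame_interval=frame_interval)
    return LocalizationCalibration(
        msd1_fixed=float(curve.msd[0]), n_intervals=int(curve.n_intervals[0])
    )


def estimate_D1(
    msd1: float,
    msd1_fixed: float,
    frame_interval: float = 0.05,
    msd1_sem: float | None = None,
) -> DiffusionEstimate:
    """Single-step estimator with blur and localization-error correction."""
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    D = BLUR_FACTOR * (msd1 - msd1_fixed) / (4.0 * frame_interval)
    sem = BLUR_FACTOR * msd1_sem / (4.0 * frame_interval) if msd1_sem is not None else None
    negative = D < 0
    if negative:
        warnings.warn("negative D1 estimate (MSD1 below fixed-cell calibration); reported unclamped")
    return DiffusionEstimate(
        D=float(D),
        method="single_step_D1",
        msd1_fixed_used=float(msd1_fixed),
        blur_factor=BLUR_FACTOR,
        sem=sem,
        negative=negative,
    )


def estimate_D2(
    msd1: float,
    msd2: float,
    frame_interval: float = 0.05,
) -> DiffusionEstimate:
    """Slope estimator between the one- and two-frame MSD points.

    Localization error and motion blur contribute equally to MSD₁ and MSD₂,
    so both corrections cancel in the difference.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    D = (msd2 - msd1) / (4.0 * frame_interval)
    negative = D < 0
    if negative:
        warnings.warn("negative D2 estimate (MSD decreasing with lag); reported unclamped")
    return DiffusionEstimate(D=float(D), method="slope_D2", negative=negative)


def estimate_confinement_radius(
    plateau: "float | MSDCurve",
    calibration: LocalizationCalibration,
    window_s: tuple[float, float] = (0.4, 0.5),
) -> ConfinementEstimate:
    """Equivalent confinement radius from an MSD plateau.

    For positions uniform in a disc of radius R the long-lag limit of
    ⟨|P_i − P_j|²⟩ is R², so after subtracting the localization term the
    plateau converts directly: r_c = sqrt(plateau − MSD₁,fixed). When an
    :class:`MSDCurve` is given, the plateau is the mean MSD over the
    ``window_s`` lag window (400–500 ms by default).
    """
    if isinstance(plateau, MSDCurve):
        lo, hi = window_s
        sel = (plateau.lags_s >= lo - 1e-9) & (plateau.lags_s <= hi + 1e-9)
        if not sel.any():
            raise ValueError("MSD curve has no lags inside the plateau window")
        plateau_value = float(np.nanmean(plateau.msd[sel]))
    else:
        plateau_value = float(plateau)
    if plateau_value < 0:
        raise ValueError("plateau must be non-negative")
    diff = plateau_value - calibration.msd1_fixed
    if diff < 0:
        warnings.warn("plateau below localization calibration; confinement radius set to 0")
        diff = 0.0
    return ConfinementEstimate(
        plateau=plateau_value,
        r_c_nm=float(np.sqrt(diff) * 1000.0),
        msd1_fixed_used=calibration.msd1_fixed,
    )


def step_histogram(
    tracks: Sequence[Track],
    lag: int = 1,
    bin_width_nm: float = 20.0,
    overlapping: bool = True,
    density: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of apparent displacement lengths |Δr| at a given lag.

    Returns ``(counts, bin_edges_nm)``; the histogram total equals the
    number of intervals entering the MSD at the same lag.
    """
    if bin_width_nm <= 0:
        raise ValueError("bin width must be positive")
    sq = [v for t in tracks if (v := _squared_displacements(t, lag, overlapping)).size]
    if not sq:
        return np.zeros(0), np.zeros(1)
    r_nm = np.sqrt(np.concatenate(sq) / NM2_TO_UM2)
    n_bins = max(int(np.ceil((r_nm.max() + 1e-9) / bin_width_nm)), 1)
    edges = np.arange(n_bins + 1) * bin_width_nm
    counts, _ = np.histogram(r_nm, bins=edges, density=density)
    return counts, edges
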