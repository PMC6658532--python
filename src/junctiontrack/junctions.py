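"""Junction-referenced trajectory analysis and the two-state engagement estimator.

STIM1-marked ER-PM junctions are defined from the reference-channel
localizations after store depletion: localizations are density-filtered
(≥ 5 neighbors within 100 nm), rasterized at 10 nm, and gaps filled with a
5-pixel (50-nm) dilation. Target-channel tracks are then classed "on
junction" if their first localization falls inside the mask and "off
junction" if every localization falls outside; tracks that start outside
but enter later satisfy neither rule and are reported separately.

The STIM-engagement fraction treats junctional ORAI1 as a two-state mixture
of free channels (diffusing like the STIM-blind LSLD mutant) and
STIM1-bound channels (diffusing like STIM1 itself):

    fraction engaged = (D_LSLD − D_WT) / (D_LSLD − D_STIM1)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .diffusion import DiffusionEstimate, LocalizationCalibration, estimate_D1, NM2_TO_UM2
from .io_tables import LocalizationTable, Track
from .maps import PixelMap, binarize, density_filter, dilate_binary, render_histogram

__all__ = [
    "JunctionMask",
    "ExcursionRecord",
    "EngagementResult",
    "TrackClassification",
    "build_junction_mask",
    "classify_tracks",
    "max_excursion",
    "filter_by_steps",
    "sample_excursions",
    "onjunction_single_step_D",
    "engaged_fraction",
]


@dataclass
class JunctionMask:
    mask: PixelMap  # binary
    provenance: dict = field(default_factory=dict)

    def contains(self, xy) -> np.ndarray:
        return self.mask.contains_points(xy)


def build_junction_mask(
    stim1: LocalizationTable,
    pixel_size: float = 10.0,
    density_radius: float = 100.0,
    min_neighbors: int = 5,
    dilation_pixels: int = 5,
) -> JunctionMask:
    """Build the STIM1-marked junction mask.

    Pipeline: density filter (drop localizations lacking ``min_neighbors``
    others within ``density_radius``) → 10-nm binary raster → disc dilation
    by ``dilation_pixels`` to fill gaps inside clusters.
    """
    filtered = density_filter(stim1, radius=density_radius, min_neighbors=min_neighbors)
    if len(filtered) == 0:
        warnings.warn("no STIM1 localizations survive density filtering; junction mask is empty")
    raster = binarize(render_histogram(filtered, pixel_size=pixel_size))
    mask = dilate_binary(raster, dilation_pixels)
    return JunctionMask(
        mask=mask,
        provenance={
            "density_radius_nm": density_radius,
            "min_neighbors": min_neighbors,
            "dilation_pixels": dilation_pixels,
            "pixel_size_nm": pixel_size,
            "n_input": len(stim1),
            "n_retained": len(filtered),
        },
    )


@dataclass
class TrackClassification:
    on_junction: list
    off_junction: list
    excluded: list  # starts outside, enters later — satisfies neither rule

    def counts(self) -> dict:
        return {
            "on_junction": len(self.on_junction),
            "off_junction": len(self.off_junction),
            "excluded": len(self.excluded),
        }


def classify_tracks(tracks: Sequence[Track], mask: JunctionMask) -> TrackClassification:
    """Partition tracks by their position relative to the junction mask."""
    on, off, excl = [], [], []
    for t in tracks:
        inside = mask.contains(t.xy)
        if inside[0]:
            on.append(t)
        elif not inside.any():
            off.append(t)
        else:
            excl.append(t)
    return TrackClassification(on_junction=on, off_junction=off, excluded=excl)


@dataclass
class ExcursionRecord:
    track_id: int
    d_max_nm: float
    n_steps: int
    start_class: str = ""


def max_excursion(track: Track, start_class: str = "") -> ExcursionRecord:
    """Maximum displacement from the first localization to any later one."""
    d = track.xy[1:] - track.xy[0]
    d_max = float(np.max(np.hypot(d[:, 0], d[:, 1])))
    return ExcursionRecord(
        track_id=track.id, d_max_nm=d_max, n_steps=track.n_steps, start_class=start_class
    )


def filter_by_steps(
    tracks: Sequence[Track], min_steps: int = 6, max_steps: int = 25
) -> list[Track]:
    """Keep tracks with a step count in the excursion-analysis window."""
    return [t for t in tracks if min_steps <= t.n_steps <= max_steps]


def sample_excursions(
    records: Sequence[ExcursionRecord],
    n: int = 1500,
    seed: int = 0,
) -> tuple[list[ExcursionRecord], dict]:
    """Seeded uniform subsample (without replacement) with per-class medians."""
    records = list(records)
    if len(records) < n:
        warnings.warn(
            f"only {len(records)} excursion records available (requested {n}); using all"
        )
        subset = records
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(records), size=n, replace=False)
        subset = [records[i] for i in idx]
    summary: dict = {"n": len(subset)}
    classes = sorted({r.start_class for r in subset})
    for c in classes:
        vals = [r.d_max_nm for r in subset if r.start_class == c]
        summary[f"median_d_max_nm[{c or 'all'}]"] = float(np.median(vals))
    summary["median_d_max_nm"] = float(np.median([r.d_max_nm for r in subset]))
    return subset, summary


def onjunction_single_step_D(
    on_tracks: Sequence[Track],
    calibration: LocalizationCalibration,
    frame_interval: float = 0.05,
    exclude_r2_above: float | None = None,
) -> DiffusionEstimate:
    """Single-step D for on-junction tracks (one first step per track).

    The population-average first-step r² replaces MSD₁ in the corrected
    single-step estimator. ``exclude_r2_above`` (μm²) optionally trims
    outliers before averaging; by default no trimming is applied (outlier
    omission is a display convention, not part of the estimator).
    """
    if len(on_tracks) == 0:
        raise ValueError("no on-junction tracks supplied")
    if len(on_tracks) < 10:
        warnings.warn(f"only {len(on_tracks)} on-junction tracks; D estimate is noisy")
    r2 = np.array(
        [np.sum((t.xy[1] - t.xy[0]) ** 2) * NM2_TO_UM2 for t in on_tracks]
    )
    if exclude_r2_above is not None:
        r2 = r2[r2 <= exclude_r2_above]
        if r2.size == 0:
            raise ValueError("all first steps excluded by the r² cutoff")
    sem = float(r2.std(ddof=1) / np.sqrt(r2.size)) if r2.size > 1 else None
    return estimate_D1(
        float(r2.mean()), calibration.msd1_fixed, frame_interval=frame_interval, msd1_sem=sem
    )


@dataclass
class EngagementResult:
    fraction_engaged: float
    D_wt: float
    D_lsld: float
    D_stim1: float
    out_of_range: bool = False

    @property
    def percent(self) -> float:
        return self.fraction_engaged * 100.0


def engaged_fraction(D_wt: float, D_lsld: float, D_stim1: float) -> EngagementResult:
    """Two-state mixture estimate of the STIM-engaged fraction of ORAI1.

    ``D_wt`` is the measured junctional wildtype D, ``D_lsld`` the free-state
    reference (STIM-blind mutant at junctions) and ``D_stim1`` the bound-state
    reference (STIM1 itself). Values outside [0, 1] are flagged, not clamped.
    """
    if D_lsld <= D_stim1:
        raise ValueError(
            "two-state model violated: free-state D must exceed bound-state D"
        )
    frac = (D_lsld - D_wt) / (D_lsld - D_stim1)
    out = not (0.0 <= frac <= 1.0)
    if out:
        warnings.warn(f"engaged fraction {frac:.3f} outside [0, 1]; model assumptions suspect")
    return EngagementResult(
        fraction_engaged=float(frac), D_wt=D_wt, D_lsld=D_lsld, D_stim1=D_stim1, out_of_range=out
    )
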