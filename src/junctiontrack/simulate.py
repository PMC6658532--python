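"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here:

* two-state (free / STIM-bound) 2D Brownian trajectories with sub-frame
  motion blur and per-axis Gaussian localization error, optionally confined
  to junction discs while bound;
* stationary-emitter "fixed-cell" calibration trajectories;
* randomized clustered localization fields (disc clusters plus uniform
  pixel background) for the cluster-segmentation benchmark;
* dual-channel fields with a planted enrichment or exclusion factor for the
  colocalization statistic.

Motion blur is emulated by substep averaging: within each camera frame the
true position is propagated in ``substeps_per_frame`` Brownian substeps and
the reported position is the substep mean (continuous illumination) plus
localization noise. All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import LocalizationTable, Rect, Track
from .maps import PixelMap

__all__ = [
    "TwoStateSimConfig",
    "ClusterSimConfig",
    "ClusterFieldTruth",
    "simulate_two_state_tracks",
    "simulate_fixed_emitters",
    "simulate_cluster_field",
    "simulate_dual_channel_field",
    "tracks_to_table",
]


@dataclass
class TwoStateSimConfig:
    """Configuration for the two-state free/bound diffusion simulator.

    Defaults follow the junctional measurements this simulator emulates:
    free diffusion at 0.084 μm²/s, STIM-bound diffusion at 0.0394 μm²/s,
    46-nm per-axis localization error, 50-ms frames and 6–25 steps per
    track. ``p_bound`` sets the stationary bound fraction when the
    switching rates ``k_bind``/``k_release`` are zero (states then persist
    for the whole track).
    """

    D_free: float = 0.084  # μm²/s
    D_bound: float = 0.0394  # μm²/s
    p_bound: float = 0.0
    k_bind: float = 0.0  # 1/s, free → bound
    k_release: float = 0.0  # 1/s, bound → free
    junction_discs: tuple = ()  # ((cx, cy, radius), ...) in nm
    confine_bound: bool = True
    bound_disc_radius: float = 150.0  # nm, for bind events away from listed discs
    sigma_axis: float = 46.0  # nm
    frame_interval: float = 0.05  # s
    substeps_per_frame: int = 10
    report_blur: bool = True  # frame position = substep mean (False: last substep)
    track_length_range: tuple[int, int] = (7, 26)  # localizations (6–25 steps)
    n_tracks: int = 1500
    roi: Rect = field(default_factory=lambda: Rect(0.0, 0.0, 20000.0, 20000.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.D_free >= self.D_bound >= 0):
            raise ValueError("require D_free ≥ D_bound ≥ 0")
        if not (0.0 <= self.p_bound <= 1.0):
            raise ValueError("p_bound must lie in [0, 1]")
        if self.substeps_per_frame < 1:
            raise ValueError("substeps_per_frame must be ≥ 1")
        if self.track_length_range[0] < 3:
            raise ValueError("minimum track length is 3 localizations")
        if self.sigma_axis < 0:
            raise ValueError("sigma_axis must be ≥ 0")
        for disc in self.junction_discs:
            if disc[2] <= 0:
                raise ValueError("junction disc radius must be positive")
        if self.confine_bound and self.bound_disc_radius <= 0:
            raise ValueError("bound_disc_radius must be positive when confine_bound")


def _step_sigma_nm(D: float, dt: float) -> float:
    # per-axis Brownian substep std: Var = 2 D dt (μm²) → nm
    return float(np.sqrt(2.0 * D * dt) * 1000.0)


def simulate_two_state_tracks(
    config: TwoStateSimConfig,
) -> tuple[list[Track], pd.DataFrame]:
    """Simulate two-state trajectories; returns (tracks, ground truth).

    The ground-truth table has one row per reported localization with the
    blur-free frame-averaged position, the diffusive state at mid-frame and
    the molecule's starting state.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    S = cfg.substeps_per_frame
    dt_sub = cfg.frame_interval / S
    lo, hi = cfg.track_length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_tracks)
    L_max = int(lengths.max())
    n_sub = L_max * S
    n = cfg.n_tracks

    bound = rng.random(n) < cfg.p_bound
    start_state = bound.copy()

    pos = np.empty((n, 2))
    anchor = np.zeros((n, 2))
    radius = np.full(n, cfg.bound_disc_radius)
    # initial placement
    pos[:, 0] = rng.uniform(cfg.roi.x0, cfg.roi.x1, size=n)
    pos[:, 1] = rng.uniform(cfg.roi.y0, cfg.roi.y1, size=n)
    if cfg.junction_discs:
        discs = np.asarray(cfg.junction_discs, dtype=float)  # (m, 3)
        which = rng.integers(0, len(discs), size=n)
        theta = rng.uniform(0, 2 * np.pi, size=n)
        r = discs[which, 2] * np.sqrt(rng.random(n))
        disc_pos = discs[which, :2] + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        pos[bound] = disc_pos[bound]
        anchor[bound] = discs[which[bound], :2]
        radius[bound] = discs[which[bound], 2]
    else:
        anchor[bound] = pos[bound]

    sig_free = _step_sigma_nm(cfg.D_free, dt_sub)
    sig_bound = _step_sigma_nm(cfg.D_bound, dt_sub)
    p_release = cfg.k_release * dt_sub
    p_bind = cfg.k_bind * dt_sub

    true_sub = np.empty((n, n_sub, 2))
    state_sub = np.empty((n, n_sub), dtype=bool)
    for t in range(n_sub):
        if p_release > 0 or p_bind > 0:
            u = rng.random(n)
            release = bound & (u < p_release)
            bind = (~bound) & (u < p_bind)
            bound = bound & ~release | bind
            if bind.any():
                anchor[bind] = pos[bind]
                radius[bind] = cfg.bound_disc_radius
        sigma = np.where(bound, sig_bound, sig_free)
        pos = pos + rng.standard_normal((n, 2)) * sigma[:, None]
        if cfg.confine_bound:
            sel = bound
            if sel.any():
                rel = pos[sel] - anchor[sel]
                rr = np.hypot(rel[:, 0], rel[:, 1])
                R = radius[sel]
                over = rr > R
                if over.any():
                    scale = np.clip(2 * R[over] - rr[over], 0.0, R[over]) / rr[over]
                    rel[over] *= scale[:, None]
                    sub = pos[sel]
                    sub[over] = anchor[sel][over] + rel[over]
                    pos[sel] = sub
        true_sub[:, t] = pos
        state_sub[:, t] = bound

    tracks: list[Track] = []
    rows = []
    for i in range(n):
        L = int(lengths[i])
        if cfg.report_blur:
            frames_true = true_sub[i, : L * S].reshape(L, S, 2).mean(axis=1)
        else:
            frames_true = true_sub[i, S - 1 : L * S : S]
        frame_state = state_sub[i, : L * S].reshape(L, S).mean(axis=1) >= 0.5
        obs = frames_true + rng.standard_normal((L, 2)) * cfg.sigma_axis
        tracks.append(Track(id=i, frames=np.arange(L), xy=obs, channel="simulated"))
        for f in range(L):
            rows.append(
                (i, f, frames_true[f, 0], frames_true[f, 1],
                 "bound" if frame_state[f] else "free",
                 "bound" if start_state[i] else "free")
            )
    truth = pd.DataFrame(
        rows, columns=["track_id", "frame", "x_true", "y_true", "state", "start_state"]
    )
    return tracks, truth


def simulate_fixed_emitters(
    n_emitters: int,
    n_frames: int,
    sigma_axis: float,
    seed: int = 0,
    roi: Rect | None = None,
) -> list[Track]:
    """Stationary emitters observed with per-frame Gaussian localization error.

    The "trajectories" of these emitters calibrate the localization error:
    their single-interval MSD equals 4σ²_axis in expectation.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be ≥ 2")
    if sigma_axis < 0:
        raise ValueError("sigma_axis must be ≥ 0")
    roi = roi or Rect(0.0, 0.0, 20000.0, 20000.0)
    rng = np.random.default_rng(seed)
    true = np.column_stack(
        [
            rng.uniform(roi.x0, roi.x1, size=n_emitters),
            rng.uniform(roi.y0, roi.y1, size=n_emitters),
        ]
    )
    tracks = []
    for i in range(n_emitters):
        obs = true[i][None, :] + rng.standard_normal((n_frames, 2)) * sigma_axis
        tracks.append(Track(id=i, frames=np.arange(n_frames), xy=obs, channel="fixed"))
    return tracks


@dataclass
class ClusterSimConfig:
    """Randomized disc-cluster field (the cluster-segmentation benchmark).

    Defaults: 17 cluster centers in a 4 × 4 μm ROI, 32 localizations placed
    uniformly in a 200-nm disc around each center with 70-nm Gaussian
    localization uncertainty, and background localizations at 0.7% of the
    10-nm pixels. The 400-nm variant pairs with 100 localizations per disc.
    """

    n_clusters: int = 17
    roi: Rect = field(default_factory=lambda: Rect(0.0, 0.0, 4000.0, 4000.0))
    disc_diameter: float = 200.0  # nm
    locs_per_cluster: int = 32
    sigma_loc: float = 70.0  # nm
    background_pixel_fraction: float = 0.007
    pixel_size: float = 10.0  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_pixel_fraction < 1.0):
            raise ValueError("background_pixel_fraction must be in [0, 1)")
        if self.disc_diameter > min(self.roi.width, self.roi.height):
            raise ValueError("cluster disc does not fit inside the ROI")

    @property
    def n_background(self) -> int:
        ny = int(np.ceil(self.roi.height / self.pixel_size))
        nx = int(np.ceil(self.roi.width / self.pixel_size))
        return int(round(self.background_pixel_fraction * ny * nx))


@dataclass
class ClusterFieldTruth:
    centers: np.ndarray  # (n_clusters, 2) nm
    cluster_id: np.ndarray  # per localization; -1 for background

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def simulate_cluster_field(
    config: ClusterSimConfig,
) -> tuple[LocalizationTable, ClusterFieldTruth]:
    """Generate a clustered localization field with uniform pixel background.

    Cluster centers are uniform in the ROI inset by the disc radius (so
    every disc fits); each cluster contributes ``locs_per_cluster``
    localizations at a uniform point in the disc plus isotropic Gaussian
    uncertainty. Background is an exact count of distinct noise pixels —
    round(background_pixel_fraction × n_pixels) — with one localization at
    each chosen pixel center.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    R = cfg.disc_diameter / 2.0
    centers = np.column_stack(
        [
            rng.uniform(cfg.roi.x0 + R, cfg.roi.x1 - R, size=cfg.n_clusters),
            rng.uniform(cfg.roi.y0 + R, cfg.roi.y1 - R, size=cfg.n_clusters),
        ]
    )
    pts = []
    ids = []
    for k in range(cfg.n_clusters):
        m = cfg.locs_per_cluster
        theta = rng.uniform(0, 2 * np.pi, size=m)
        r = R * np.sqrt(rng.random(m))
        p = centers[k] + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        p += rng.standard_normal((m, 2)) * cfg.sigma_loc
        pts.append(p)
        ids.append(np.full(m, k))

    ny = int(np.ceil(cfg.roi.height / cfg.pixel_size))
    nx = int(np.ceil(cfg.roi.width / cfg.pixel_size))
    n_bg = cfg.n_background
    if n_bg > 0:
        flat = rng.choice(ny * nx, size=n_bg, replace=False)
        bg_rows, bg_cols = np.divmod(flat, nx)
        bg = np.column_stack(
            [
                cfg.roi.x0 + (bg_cols + 0.5) * cfg.pixel_size,
                cfg.roi.y0 + (bg_rows + 0.5) * cfg.pixel_size,
            ]
        )
        pts.append(bg)
        ids.append(np.full(n_bg, -1))

    xy = np.vstack(pts)
    cluster_id = np.concatenate(ids)
    # clip jittered cluster points into the ROI (strictly, so boundary
    # mirroring in the Voronoi step stays well-conditioned)
    eps = 0.5
    xy[:, 0] = np.clip(xy[:, 0], cfg.roi.x0, cfg.roi.x1 - eps)
    xy[:, 1] = np.clip(xy[:, 1], cfg.roi.y0, cfg.roi.y1 - eps)

    data = pd.DataFrame(
        {"frame": np.arange(len(xy)), "x": xy[:, 0], "y": xy[:, 1]}
    )
    table = LocalizationTable(data, roi=cfg.roi, channel="simulated")
    return table, ClusterFieldTruth(centers=centers, cluster_id=cluster_id)


def simulate_dual_channel_field(
    territory: PixelMap,
    enrichment: float,
    n_red: int,
    seed: int = 0,
) -> LocalizationTable:
    """Red-channel field with density ``enrichment``-fold higher inside a territory.

    A localization falls inside the territory with probability
    e·A_in / (e·A_in + A_out) where A_in/A_out are the territory and
    complement areas; positions are uniform within the chosen region.
    ``enrichment`` = 1 is spatially uniform, 0 excludes the territory.
    """
    if enrichment < 0:
        raise ValueError("enrichment must be ≥ 0")
    mask = territory.grid > 0
    n_in_px = int(mask.sum())
    n_out_px = int(mask.size - n_in_px)
    if n_in_px == 0 or n_out_px == 0:
        raise ValueError("territory must be non-empty and non-full")
    rng = np.random.default_rng(seed)
    a_in = n_in_px
    a_out = n_out_px
    p_in = enrichment * a_in / (enrichment * a_in + a_out)
    n_inside = int(rng.binomial(n_red, p_in))

    rows_in, cols_in = np.nonzero(mask)
    rows_out, cols_out = np.nonzero(~mask)

    def _sample(rows, cols, count):
        idx = rng.integers(0, len(rows), size=count)
        x = territory.origin[0] + (cols[idx] + rng.random(count)) * territory.pixel_size
        y = territory.origin[1] + (rows[idx] + rng.random(count)) * territory.pixel_size
        return np.column_stack([x, y])

    parts = []
    if n_inside:
        parts.append(_sample(rows_in, cols_in, n_inside))
    if n_red - n_inside:
        parts.append(_sample(rows_out, cols_out, n_red - n_inside))
    xy = np.vstack(parts) if parts else np.empty((0, 2))
    order = rng.permutation(len(xy))
    xy = xy[order]
    data = pd.DataFrame({"frame": np.arange(len(xy)), "x": xy[:, 0], "y": xy[:, 1]})
    return LocalizationTable(data, roi=territory.roi, channel="red")


def tracks_to_table(
    tracks: Sequence[Track],
    roi: Rect,
    channel: str = "unspecified",
    frame_interval: float = 0.05,
) -> tuple[LocalizationTable, np.ndarray]:
    """Flatten tracks into a localization table; returns (table, track ids)."""
    frames = np.concatenate([t.frames for t in tracks])
    xy = np.vstack([t.xy for t in tracks])
    ids = np.concatenate([np.full(len(t), t.id) for t in tracks])
    data = pd.DataFrame({"frame": frames, "x": xy[:, 0], "y": xy[:, 1]})
    table = LocalizationTable(data, roi=roi, channel=channel, frame_interval=frame_interval)
    return table, ids
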