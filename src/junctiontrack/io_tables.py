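"""Localization and track table I/O, drift correction, channel registration.

Localization tables are delimited text with one row per detected emitter per
frame. Coordinates are continuous nanometres with the origin at the lower-left
corner of the region of interest and y increasing upward. The default column
dialect follows the common SMLM export convention (``frame``, ``x [nm]``,
``y [nm]``, ``uncertainty [nm]``, ``intensity [photon]``); alternative layouts
are handled through a :class:`Dialect` mapping.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Rect",
    "Dialect",
    "LocalizationTable",
    "Track",
    "DriftModel",
    "RigidTransform",
    "read_localizations",
    "write_localizations",
    "read_tracks",
    "write_tracks",
    "estimate_and_apply_drift",
    "register_channels",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in nm (x0, y0 = lower-left corner)."""

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("Rect width and height must be positive")

    @property
    def x1(self) -> float:
        return self.x0 + self.width

    @property
    def y1(self) -> float:
        return self.y0 + self.height

    @property
    def area_nm2(self) -> float:
        return self.width * self.height

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / 1e6

    def contains(self, x, y, slack: float = 0.0) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x0 - slack)
            & (x <= self.x1 + slack)
            & (y >= self.y0 - slack)
            & (y <= self.y1 + slack)
        )


#: Default column names (SMLM export convention).
DEFAULT_COLUMNS: Mapping[str, str] = {
    "frame": "frame",
    "x": "x [nm]",
    "y": "y [nm]",
    "uncertainty": "uncertainty [nm]",
    "intensity": "intensity [photon]",
}


@dataclass(frozen=True)
class Dialect:
    """Column mapping for a localization-table file.

    ``unit_to_nm`` converts coordinate (and uncertainty) columns to nm,
    e.g. 1000.0 for files written in micrometres.
    """

    frame: str = DEFAULT_COLUMNS["frame"]
    x: str = DEFAULT_COLUMNS["x"]
    y: str = DEFAULT_COLUMNS["y"]
    uncertainty: str | None = DEFAULT_COLUMNS["uncertainty"]
    intensity: str | None = DEFAULT_COLUMNS["intensity"]
    unit_to_nm: float = 1.0


@dataclass
class LocalizationTable:
    """Per-frame point detections with a channel tag.

    ``data`` holds columns ``frame`` (int), ``x``/``y`` (nm) and optionally
    ``uncertainty`` (nm) and ``intensity``; ``roi`` is the rectangle the
    coordinates live in and ``frame_interval`` the camera frame time in
    seconds.
    """

    data: pd.DataFrame
    roi: Rect
    channel: str = "unspecified"
    frame_interval: float = 0.05

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        for col in ("frame", "x", "y"):
            if col not in self.data.columns:
                raise ValueError(f"localization table missing column {col!r}")
        frames = self.data["frame"].to_numpy()
        if len(frames) and (frames < 0).any():
            raise ValueError("frame indices must be non-negative")
        self.data = self.data.reset_index(drop=True)
        self.data["frame"] = self.data["frame"].astype(int)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def frames(self) -> np.ndarray:
        return self.data["frame"].to_numpy()

    def validate_in_roi(self, slack: float = 0.0) -> None:
        inside = self.roi.contains(self.data["x"], self.data["y"], slack=slack)
        if not bool(np.all(inside)):
            n = int((~inside).sum())
            raise ValueError(f"{n} localizations fall outside the ROI")

    def subset(self, mask) -> "LocalizationTable":
        return LocalizationTable(
            self.data.loc[np.asarray(mask)].reset_index(drop=True),
            roi=self.roi,
            channel=self.channel,
            frame_interval=self.frame_interval,
        )


@dataclass
class Track:
    """A time-ordered localization sequence (no frame gaps)."""

    id: int
    frames: np.ndarray  # (n,) int, strictly consecutive
    xy: np.ndarray  # (n, 2) float nm
    channel: str = "unspecified"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (len(self.frames), 2):
            raise ValueError("xy must have shape (n_frames, 2)")
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("track frames must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        return len(self.frames) - 1


def read_localizations(
    path,
    dialect: Dialect | None = None,
    roi: Rect | None = None,
    channel: str = "unspecified",
    frame_interval: float = 0.05,
    sep: str = ",",
) -> LocalizationTable:
    """Read a delimited localization table.

    Rows with non-numeric coordinates are dropped with a logged count; a
    missing mandatory column raises ``ValueError``. If ``roi`` is omitted it
    is taken as the bounding box of the data (expanded to positive extent).
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for attr in ("frame", "x", "y"):
        name = getattr(dialect, attr)
        if name not in raw.columns:
            raise ValueError(f"missing mandatory column {name!r} in {path}")
    out = pd.DataFrame()
    out["frame"] = pd.to_numeric(raw[dialect.frame], errors="coerce")
    out["x"] = pd.to_numeric(raw[dialect.x], errors="coerce") * dialect.unit_to_nm
    out["y"] = pd.to_numeric(raw[dialect.y], errors="coerce") * dialect.unit_to_nm
    for attr in ("uncertainty", "intensity"):
        name = getattr(dialect, attr)
        if name is not None and name in raw.columns:
            scale = dialect.unit_to_nm if attr == "uncertainty" else 1.0
            out[attr] = pd.to_numeric(raw[name], errors="coerce") * scale
    bad = out[["frame", "x", "y"]].isna().any(axis=1)
    if bad.any():
        logger.warning("dropped %d rows with non-numeric fields from %s", int(bad.sum()), path)
        out = out.loc[~bad]
    if len(out) == 0:
        warnings.warn(f"localization table {path} contains no usable rows")
    out = out.reset_index(drop=True)
    if roi is None:
        roi = _bounding_roi(out)
    return LocalizationTable(out, roi=roi, channel=channel, frame_interval=frame_interval)


def _bounding_roi(data: pd.DataFrame) -> Rect:
    if len(data) == 0:
        return Rect(0.0, 0.0, 1.0, 1.0)
    x0, y0 = float(data["x"].min()), float(data["y"].min())
    w = max(float(data["x"].max()) - x0, 1.0)
    h = max(float(data["y"].max()) - y0, 1.0)
    return Rect(x0, y0, w, h)


def write_localizations(table: LocalizationTable, path, dialect: Dialect | None = None) -> None:
    dialect = dialect or Dialect()
    out = pd.DataFrame()
    out[dialect.frame] = table.data["frame"]
    out[dialect.x] = table.data["x"] / dialect.unit_to_nm
    out[dialect.y] = table.data["y"] / dialect.unit_to_nm
    if dialect.uncertainty and "uncertainty" in table.data:
        out[dialect.uncertainty] = table.data["uncertainty"] / dialect.unit_to_nm
    if dialect.intensity and "intensity" in table.data:
        out[dialect.intensity] = table.data["intensity"]
    out.to_csv(path, index=False)


def write_tracks(tracks: Sequence[Track], path) -> None:
    """Write tracks as delimited text with columns track_id, frame, x, y."""
    rows = []
    for t in tracks:
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append((t.id, int(f), float(x), float(y)))
    pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"]).to_csv(path, index=False)


def read_tracks(path, channel: str = "unspecified") -> list[Track]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("track_id", "frame", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(int(tid), grp["frame"].to_numpy(), grp[["x", "y"]].to_numpy(), channel=channel)
        )
    return tracks


@dataclass
class DriftModel:
    """Per-frame stage-drift offsets estimated from fiducial markers.

    ``offsets[i]`` is the (dx, dy) displacement of frame ``frames[i]`` from
    the reference frame; it is subtracted from localizations to correct them.
    The offset at the reference frame is (0, 0) by construction.
    """

    frames: np.ndarray
    offsets: np.ndarray  # (n_frames, 2) nm
    source_fiducial_ids: tuple = ()
    reference_frame: int = 0

    def offset_at(self, frames) -> np.ndarray:
        frames = np.asarray(frames)
        dx = np.interp(frames, self.frames, self.offsets[:, 0])
        dy = np.interp(frames, self.frames, self.offsets[:, 1])
        return np.column_stack([dx, dy])

    def apply(self, table: LocalizationTable) -> LocalizationTable:
        corr = table.data.copy()
        off = self.offset_at(corr["frame"].to_numpy())
        corr["x"] = corr["x"] - off[:, 0]
        corr["y"] = corr["y"] - off[:, 1]
        return LocalizationTable(
            corr, roi=table.roi, channel=table.channel, frame_interval=table.frame_interval
        )


def estimate_and_apply_drift(
    table: LocalizationTable,
    fiducials: Sequence[Track],
    max_uncovered_fraction: float = 0.10,
) -> tuple[LocalizationTable, DriftModel]:
    """Estimate per-frame drift from fiducial tracks and subtract it.

    The offset of each frame is the mean fiducial displacement from the
    reference frame (the first frame of the acquisition); gaps in individual
    fiducial coverage are bridged by linear interpolation. Frames covered by
    no fiducial at all must amount to at most ``max_uncovered_fraction`` of
    the acquisition.
    """
    if len(fiducials) == 0:
        raise ValueError("at least one fiducial track is required")
    frames = np.arange(int(table.frames.min()), int(table.frames.max()) + 1) if len(table) else np.array([0])
    ref = int(frames[0])

    covered = np.zeros(len(frames), dtype=bool)
    per_fid = []
    for fid in fiducials:
        span = (frames >= fid.frames.min()) & (frames <= fid.frames.max())
        covered |= span
        dx = np.interp(frames, fid.frames, fid.xy[:, 0])
        dy = np.interp(frames, fid.frames, fid.xy[:, 1])
        per_fid.append(np.column_stack([dx, dy]))
    if np.mean(~covered) > max_uncovered_fraction:
        raise ValueError(
            f"fiducials cover only {np.mean(covered):.0%} of frames "
            f"(need ≥ {1 - max_uncovered_fraction:.0%})"
        )
    mean_pos = np.mean(per_fid, axis=0)
    offsets = mean_pos - mean_pos[frames == ref][0]
    model = DriftModel(
        frames=frames,
        offsets=offsets,
        source_fiducial_ids=tuple(f.id for f in fiducials),
        reference_frame=ref,
    )
    return model.apply(table), model


@dataclass
class RigidTransform:
    """Rigid map y ≈ R·x + t bringing channel-A coordinates onto channel B."""

    rotation: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)
    residual_rms: float = 0.0

    def apply(self, xy) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return xy @ self.rotation.T + self.translation

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.rotation[1, 0], self.rotation[0, 0])))


def register_channels(
    points_a: np.ndarray,
    points_b: np.ndarray,
    allow_rotation: bool = False,
) -> RigidTransform:
    """Least-squares rigid registration from matched fiducial pairs.

    Translation-only by default; with ``allow_rotation`` a rotation is fitted
    by the Kabsch construction (≥ 2 pairs with non-degenerate spread).
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape != b.shape or a.shape[0] < 1:
        raise ValueError("need matched point sets of equal, non-zero length")
    if not allow_rotation:
        R = np.eye(2)
        t = (b - a).mean(axis=0)
    else:
        if a.shape[0] < 2:
            raise ValueError("rotation requires at least 2 matched pairs")
        ca, cb = a.mean(axis=0), b.mean(axis=0)
        a0, b0 = a - ca, b - cb
        if np.allclose(a0, 0) or np.allclose(b0, 0):
            raise ValueError("degenerate geometry: matched points are coincident")
        H = a0.T @ b0
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, d]) @ U.T
        t = cb - R @ ca
    resid = b - (a @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1)))) if len(a) else 0.0
    return RigidTransform(rotation=R, translation=np.asarray(t, dtype=float), residual_rms=rms)
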