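"""Frame-to-frame linking of localizations into single-molecule trajectories.

Detections in consecutive frames are paired by optimal bipartite assignment
(Hungarian algorithm) on squared displacement, gated at a maximum
displacement of 480 nm (three camera pixels) per 50-ms frame. There is no
gap closing: a molecule absent in a frame terminates its track. Tracks
shorter than three localizations are discarded.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .io_tables import LocalizationTable, Track

__all__ = ["link_tracks"]

_BIG = 1e12  # cost sentinel for pairs beyond the gate


def link_tracks(
    table: LocalizationTable,
    max_disp: float = 480.0,
    min_length: int = 3,
) -> list[Track]:
    """Link a localization table into trajectories.

    Parameters
    ----------
    table:
        Localizations; rows may arrive in any order (sorted by frame here).
    max_disp:
        Maximum frame-to-frame displacement in nm (default three 160-nm
        camera pixels = 480 nm).
    min_length:
        Minimum number of localizations a reported track must have.
    """
    if len(table) == 0:
        return []
    df = table.data.sort_values("frame", kind="stable")
    frames = df["frame"].to_numpy()
    xy = df[["x", "y"]].to_numpy(dtype=float)

    frame_values = np.unique(frames)
    by_frame = {f: np.flatnonzero(frames == f) for f in frame_values}

    # Active track = growing list of row indices; keyed by its last row.
    paths: list[list[int]] = []
    active: dict[int, int] = {}  # row index of last localization -> path index

    first = frame_values[0]
    for row in by_frame[first]:
        paths.append([int(row)])
        active[int(row)] = len(paths) - 1

    for prev_f, cur_f in zip(frame_values[:-1], frame_values[1:]):
        cur_rows = by_frame[cur_f]
        if cur_f != prev_f + 1 or not active:
            # Non-consecutive frame: every active track terminates.
            active = {}
            linked_cur: set[int] = set()
        else:
            prev_rows = np.array(sorted(active.keys()))
            cost = cdist(xy[prev_rows], xy[cur_rows], "sqeuclidean")
            cost = np.where(cost <= max_disp**2, cost, _BIG)
            ri, ci = linear_sum_assignment(cost)
            new_active: dict[int, int] = {}
            linked_cur = set()
            for i, j in zip(ri, ci):
                if cost[i, j] >= _BIG:
                    continue
                prev_row = int(prev_rows[i])
                cur_row = int(cur_rows[j])
                path_idx = active[prev_row]
                paths[path_idx].append(cur_row)
                new_active[cur_row] = path_idx
                linked_cur.add(cur_row)
            active = new_active
        for row in cur_rows:
            if int(row) not in linked_cur:
                paths.append([int(row)])
                active[int(row)] = len(paths) - 1

    tracks = []
    tid = 0
    for path in paths:
        if len(path) < min_length:
            continue
        idx = np.asarray(path)
        tracks.append(
            Track(id=tid, frames=frames[idx], xy=xy[idx], channel=table.channel)
        )
        tid += 1
    return tracks
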