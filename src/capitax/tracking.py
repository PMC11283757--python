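"""Cell detection and trajectory linking for assay videos.

The stage mirrors a standard bright-field tracking workflow: a temporal-median
background is subtracted from every frame, cells are detected as connected
components of the absolute difference image, and detections are linked frame
to frame with a deterministic greedy mutual-nearest-neighbour matcher with
gap closing. Track tables round-trip through a plain CSV format
(``track_id,frame,x_um,y_um[,t_s]``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import AssayGeometry, to_assay_frame


@dataclass(frozen=True)
class Detection:
    frame: int
    x: float
    y: float
    area: int = 1


@dataclass
class Track:
    """One cell's time-ordered positions.

    ``positions`` are (n, 2) points in the assay frame (um) unless the track
    was built straight from pixel detections; ``times`` are seconds
    (frame / frame_rate).
    """

    track_id: int
    frames: np.ndarray
    positions: np.ndarray
    times: np.ndarray | None = None
    label: str | None = None  # ground-truth tag from the simulator, if any

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("a track needs at least 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def estimate_background(frames) -> np.ndarray:
    """Per-pixel temporal median of an image stack."""
    stack = np.asarray(frames)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of >= 2 equally sized frames")
    return np.median(stack, axis=0)


def detect_cells(
    frame, background, threshold: float, min_area: int = 1
) -> list[Detection]:
    """Detect cells as connected components of |frame - background|.

    Centroids are intensity-weighted means of the difference image, so a
    symmetric spot is localised to sub-pixel accuracy.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    diff = np.abs(frame - background)
    mask = diff > threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        return []
    out: list[Detection] = []
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    coms = ndimage.center_of_mass(diff, labels, index=range(1, n + 1))
    for lab in range(1, n + 1):
        area = int(areas[lab - 1])
        if area < min_area:
            continue
        cy, cx = coms[lab - 1]
        out.append(Detection(frame=-1, x=float(cx), y=float(cy), area=area))
    return out


def link_detections(
    detections: dict[int, list[Detection]] | list[list[Detection]],
    max_displacement: float,
    memory: int = 2,
    min_length: int = 2,
) -> list[Track]:
    """Link per-frame detections into tracks.

    Greedy mutual-nearest-neighbour matching: candidate (track, detection)
    pairs within ``max_displacement`` are accepted in order of increasing
    distance (ties by detection index, then track id), each endpoint at most
    once. A track missing a detection survives ``memory`` frames before it
    is closed, so short occlusions are bridged. Deterministic for a given
    input, and invariant to the ordering of detections within a frame.
    """
    if max_displacement < 0:
        raise ValueError("max_displacement must be >= 0")
    if isinstance(detections, dict):
        frames_iter = sorted(detections.items())
    else:
        frames_iter = list(enumerate(detections))

    next_id = 0
    # active track state: id -> (last_frame, last_pos, list[(frame, x, y)])
    active: dict[int, tuple[int, np.ndarray, list]] = {}
    closed: list[tuple[int, list]] = []

    for frame_idx, dets in frames_iter:
        # retire tracks that outlived the gap memory
        for tid in [t for t, (lf, _, _) in active.items() if frame_idx - lf > memory + 1]:
            closed.append((tid, active.pop(tid)[2]))
        pos = np.array([[d.x, d.y] for d in dets], dtype=float).reshape(-1, 2)
        tids = sorted(active)
        pairs = []
        for ti, tid in enumerate(tids):
            last = active[tid][1]
            dists = np.hypot(pos[:, 0] - last[0], pos[:, 1] - last[1])
            for di in np.nonzero(dists <= max_displacement)[0]:
                pairs.append((dists[di], int(di), tid))
        pairs.sort()
        used_d: set[int] = set()
        used_t: set[int] = set()
        for dist, di, tid in pairs:
            if di in used_d or tid in used_t:
                continue
            used_d.add(di)
            used_t.add(tid)
            _, _, pts = active[tid]
            pts.append((frame_idx, pos[di, 0], pos[di, 1]))
            active[tid] = (frame_idx, pos[di], pts)
        # sort new detections for id-assignment determinism
        fresh = sorted(set(range(len(dets))) - used_d)
        for di in fresh:
            active[next_id] = (frame_idx, pos[di], [(frame_idx, pos[di, 0], pos[di, 1])])
            next_id += 1
    closed.extend((tid, st[2]) for tid, st in active.items())

    tracks = []
    for tid, pts in sorted(closed):
        if len(pts) < max(min_length, 2):
            continue
        arr = np.array(pts, dtype=float)
        tracks.append(Track(tid, arr[:, 0].astype(int), arr[:, 1:3]))
    return tracks


_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


def write_tracks(tracks: list[Track], path) -> None:
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            row = {
                "track_id": tr.track_id,
                "frame": int(tr.frames[i]),
                "x_um": tr.positions[i, 0],
                "y_um": tr.positions[i, 1],
            }
            if tr.times is not None:
                row["t_s"] = tr.times[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(
    path,
    geometry: AssayGeometry | None = None,
    min_length: int = 2,
) -> list[Track]:
    """Read a track table; rows are sorted by frame within each track.

    Tables with ``x_um,y_um`` columns are taken as assay-frame um. Tables
    with ``x_px,y_px`` columns require a ``geometry`` and are converted to
    the assay frame on read. Times default to frame / frame_rate when a
    geometry is available.
    """
    df = pd.read_csv(path)
    pixel_input = "x_px" in df.columns and "y_px" in df.columns
    required = ["track_id", "frame"] + ([] if pixel_input else ["x_um", "y_um"])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    if pixel_input and geometry is None:
        raise ValueError("pixel-coordinate table requires a geometry")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"track {tid}: duplicate or non-monotone frames")
        if len(frames) < min_length:
            continue
        if pixel_input:
            pos = to_assay_frame(grp[["x_px", "y_px"]].to_numpy(float), geometry)
        else:
            pos = grp[["x_um", "y_um"]].to_numpy(float)
        if "t_s" in grp.columns:
            times = grp["t_s"].to_numpy(float)
        elif geometry is not None:
            times = frames / geometry.frame_rate
        else:
            times = None
        tracks.append(Track(int(tid), frames, pos, times))
    return tracks


def tracks_with_times(tracks: list[Track], frame_rate: float) -> list[Track]:
    """Return tracks with times filled in as frame / frame_rate."""
    out = []
    for tr in tracks:
        out.append(Track(tr.track_id, tr.frames, tr.positions, tr.frames / frame_rate, tr.label))
    return out
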