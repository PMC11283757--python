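"""Trajectory straightness, segment classification and chemokinesis.

The straightness index of a trajectory portion is

    S = D / L

with D the net start-to-end displacement in the 2D plane and L the path
length (sum of step lengths). S = 1 for a perfectly straight path and
S << 1 for a convoluted searching path; it is invariant to rotation,
translation and uniform scaling.

S is evaluated on three trajectory classes relative to the diffusing cue
patch: *ingoing* (net radial motion toward the source while crossing the
sampling corona inside the patch), *outgoing* (net motion away under the
same constraints), and *neutral* (background swimming far from the cue
early in the assay, before the patch has spread). The sampling corona is
an annulus 140 um wide (seven ~20 um body lengths) so that all classes are
scored on comparable arc lengths.

Chemokinesis — speed modulation by the cue without directional bias — is
quantified from the joint distribution of instantaneous speed and radial
distance, summarised as the ratio of median speed near the source to the
median in the remaining arena.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geometry import AssayGeometry, RegionSpec
from .tracking import Track


@dataclass
class Segment:
    """A labelled portion of a parent track."""

    parent_id: int
    label: str  # "ingoing" | "outgoing" | "neutral"
    positions: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.times = np.asarray(self.times, float)
        if len(self.positions) < 3:
            raise ValueError("a segment needs >= 3 points")


def smooth_positions(positions, window: int = 3) -> np.ndarray:
    """Centred moving-average smoothing; shrinks the window at the edges."""
    pos = np.asarray(positions, float)
    if window <= 1:
        return pos
    half = window // 2
    out = np.empty_like(pos)
    n = len(pos)
    for i in range(n):
        # shrink symmetrically at the edges so linear motion stays exact
        k = min(i, n - 1 - i, half)
        out[i] = pos[i - k : i + k + 1].mean(axis=0)
    return out


def instantaneous_speed(track: Track, smoothing_window: int = 3) -> np.ndarray:
    """Per-step speeds (um s^-1) after position smoothing.

    A 3-frame centred moving average suppresses 30-fps centroid jitter
    before differencing; pass ``smoothing_window=1`` to disable.
    """
    if track.times is None:
        raise ValueError("track has no times; fill with tracks_with_times()")
    dt = np.diff(track.times)
    if np.any(dt <= 0):
        raise ValueError("non-positive time step")
    pos = smooth_positions(track.positions, smoothing_window)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return steps / dt


def straightness(positions) -> float:
    """Net-to-gross displacement ratio S = D / L of an ordered point set."""
    pos = np.asarray(positions, float)
    if len(pos) < 2:
        raise ValueError("need >= 2 points")
    D = float(np.linalg.norm(pos[-1] - pos[0]))
    L = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
    if L == 0:
        raise ValueError("zero path length")
    return D / L


@dataclass
class StraightnessResult:
    S: np.ndarray
    D: np.ndarray
    L: np.ndarray
    labels: list[str]

    def median(self, label: str) -> float:
        vals = [s for s, l in zip(self.S, self.labels) if l == label]
        return float(np.median(vals)) if vals else np.nan

    def group_sizes(self) -> dict:
        out: dict[str, int] = {}
        for l in self.labels:
            out[l] = out.get(l, 0) + 1
        return out


def classify_segments(
    tracks: list[Track],
    geometry: AssayGeometry,
    corona: RegionSpec,
    patch_radius: float = 200.0,
    t_min: float = 60.0,
    neutral_radius: float = 400.0,
) -> list[Segment]:
    """Split tracks into ingoing / outgoing / neutral segments.

    Ingoing and outgoing segments are contiguous runs inside the sampling
    corona, fully contained in the diffusing patch (r <= ``patch_radius``)
    and observed after the patch has formed (t > ``t_min``); the label is
    the sign of the net radial displacement across the run (toward the
    source = ingoing). Neutral segments are runs at r > ``neutral_radius``
    during the first ``t_min`` seconds, before the cue can have reached
    them.
    """
    if corona.corona_outer > patch_radius:
        raise ValueError("corona extends beyond the diffusing patch")
    segments: list[Segment] = []
    for tr in tracks:
        if tr.times is None:
            raise ValueError("tracks need times; fill with tracks_with_times()")
        r = np.linalg.norm(tr.positions, axis=1)
        in_corona = (
            (r >= corona.corona_inner)
            & (r <= corona.corona_outer)
            & (r <= patch_radius)
            & (tr.times > t_min)
        )
        for lo, hi in _runs(in_corona):
            if hi - lo < 3:
                continue
            net = r[hi - 1] - r[lo]
            label = "ingoing" if net < 0 else "outgoing"
            segments.append(Segment(tr.track_id, label, tr.positions[lo:hi], tr.times[lo:hi]))
        far = (r > neutral_radius) & (tr.times < t_min)
        for lo, hi in _runs(far):
            if hi - lo < 3:
                continue
            segments.append(Segment(tr.track_id, "neutral", tr.positions[lo:hi], tr.times[lo:hi]))
    return segments


def _runs(mask: np.ndarray):
    """Yield (start, stop) of contiguous True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], np.asarray(mask, np.int8), [0]])))
    for lo, hi in zip(idx[::2], idx[1::2]):
        yield int(lo), int(hi)


def segment_straightness(segments: list[Segment]) -> StraightnessResult:
    S, D, L, labels = [], [], [], []
    for seg in segments:
        pos = seg.positions
        d = float(np.linalg.norm(pos[-1] - pos[0]))
        l = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))
        if l == 0:
            continue
        S.append(d / l)
        D.append(d)
        L.append(l)
        labels.append(seg.label)
    return StraightnessResult(np.array(S), np.array(D), np.array(L), labels)


def truncate_to_arclength(positions, arc_length: float) -> np.ndarray | None:
    """Leading portion of a polyline with total length ~arc_length.

    Returns None when the polyline is shorter than the requested length.
    """
    pos = np.asarray(positions, float)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    cum = np.cumsum(steps)
    if cum.size == 0 or cum[-1] < arc_length:
        return None
    n = int(np.searchsorted(cum, arc_length)) + 2
    return pos[:n]


def straightness_robustness(
    segments: list[Segment],
    body_length: float = 20.0,
    multipliers=range(3, 11),
    min_segments: int = 20,
    flag_shift: float = 0.10,
):
    """Median S versus standardized segment arc length (3-10 body lengths).

    Because S decreases with path length for any non-ballistic motion, the
    robustness scan truncates every segment to a common arc length before
    scoring. Lengths whose median deviates from the overall median by more
    than ``flag_shift`` (fractional) are flagged.
    """
    import pandas as pd

    rows = []
    for m in multipliers:
        target = m * body_length
        vals = []
        for seg in segments:
            trunc = truncate_to_arclength(seg.positions, target)
            if trunc is not None and len(trunc) >= 2:
                vals.append(straightness(trunc))
        if len(vals) < min_segments:
            raise ValueError(
                f"only {len(vals)} segments reach {m} body lengths (< {min_segments})"
            )
        rows.append({"body_lengths": m, "median_S": float(np.median(vals)), "n": len(vals)})
    df = pd.DataFrame(rows)
    ref = df["median_S"].median()
    df["flagged"] = np.abs(df["median_S"] - ref) > flag_shift * ref
    return df


def compare_straightness(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Pairwise two-sided Mann-Whitney tests with Holm correction.

    Input: mapping label -> array of S values (>= 3 each). Output: mapping
    (label_a, label_b) -> corrected p-value.
    """
    names = sorted(groups)
    for name in names:
        if len(groups[name]) < 3:
            raise ValueError(f"group {name!r} has < 3 values")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    raw = []
    for a, b in pairs:
        if np.ptp(np.concatenate([groups[a], groups[b]])) == 0:
            raw.append(1.0)
        else:
            raw.append(float(stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue))
    if not pairs:
        return {}
    corrected = multipletests(raw, method="holm")[1]
    return dict(zip(pairs, (float(p) for p in corrected)))


@dataclass
class SpeedProfile:
    speed_edges: np.ndarray
    radial_edges: np.ndarray
    frequencies: np.ndarray  # shape (n_speed_bins, n_radial_bins), columns sum to 1
    chemokinesis_ratio: float
    p_value: float


def speed_vs_distance(
    tracks: list[Track],
    geometry: AssayGeometry,
    speed_bins=None,
    radial_bins=None,
    near_radius: float = 200.0,
    smoothing_window: int = 3,
) -> SpeedProfile:
    """Joint speed/radial-distance distribution and chemokinesis statistic.

    The 2D histogram is normalised per radial bin (columns sum to 1 where
    populated). The chemokinesis statistic is the ratio of the median
    instantaneous speed within ``near_radius`` of the cue source to the
    median in the remaining area, with a two-sided rank-sum p-value.
    """
    speeds_all, radii_all = [], []
    for tr in tracks:
        v = instantaneous_speed(tr, smoothing_window)
        mid = 0.5 * (tr.positions[:-1] + tr.positions[1:])
        r = np.linalg.norm(mid, axis=1)
        speeds_all.append(v)
        radii_all.append(r)
    v = np.concatenate(speeds_all)
    r = np.concatenate(radii_all)
    if speed_bins is None:
        speed_bins = np.linspace(0, max(v.max(), 1.0), 31)
    if radial_bins is None:
        radial_bins = np.linspace(0, max(r.max(), 1.0), 21)
    hist, se, re_ = np.histogram2d(v, r, bins=(speed_bins, radial_bins))
    colsum = hist.sum(axis=0, keepdims=True)
    freq = np.divide(hist, colsum, out=np.zeros_like(hist), where=colsum > 0)
    near = v[r <= near_radius]
    far = v[r > near_radius]
    if near.size and far.size:
        ratio = float(np.median(near) / np.median(far)) if np.median(far) > 0 else np.inf
        p = float(stats.mannwhitneyu(near, far, alternative="two-sided").pvalue)
    else:
        ratio, p = np.nan, np.nan
    return SpeedProfile(se, re_, freq, ratio, p)
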