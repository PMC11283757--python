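"""Assay coordinate system and spatial regions.

The assay frame has its origin at the centre of the cue-capillary entrance,
with the first (axial) coordinate along the capillary axis, positive *into*
the capillary, in micrometres. Every downstream statistic — concentration
profiles, region counts, segment classification — is computed in this frame.

Image (pixel) coordinates follow the usual convention: origin top-left,
y increasing downward; the mapping to the assay frame flips y so that the
assay frame is right-handed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import yaml

RegionKind = Literal["inside_rect", "outside_semicircle", "corona", "neutral"]


@dataclass(frozen=True)
class AssayGeometry:
    """Geometry of a two-capillary chemotaxis assay.

    Parameters
    ----------
    origin_px : (2,) array-like
        Pixel coordinates of the centre of the cue-capillary entrance.
    axis_deg : float
        Direction of the capillary axis (entrance -> interior) in degrees,
        measured in the image frame (0 = +x, counter-clockwise in the
        *assay* sense, i.e. after the y-flip).
    pixel_scale : float
        Micrometres per pixel, > 0.
    frame_rate : float
        Acquisition rate in frames per second (default 30).
    capillary_inner_width : float
        Inner width of the square capillary, um (default 200).
    capillary_length : float
        Length of the capillary, um (default 50 mm).
    wall_thickness : float
        Glass wall thickness, um (default 100).
    control_origin_px, control_axis_deg
        Same quantities for the control capillary.
    """

    origin_px: tuple[float, float] = (0.0, 0.0)
    axis_deg: float = 0.0
    pixel_scale: float = 1.0
    frame_rate: float = 30.0
    capillary_inner_width: float = 200.0
    capillary_length: float = 50_000.0
    wall_thickness: float = 100.0
    control_origin_px: tuple[float, float] | None = None
    control_axis_deg: float | None = None

    def __post_init__(self) -> None:
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be > 0")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if not self.capillary_inner_width > 0:
            raise ValueError("capillary_inner_width must be > 0")

    @property
    def axis(self) -> np.ndarray:
        """Unit vector of the cue-capillary axis in the assay sense."""
        th = np.deg2rad(self.axis_deg)
        return np.array([np.cos(th), np.sin(th)])

    @classmethod
    def from_config(cls, path_or_dict) -> "AssayGeometry":
        """Build a geometry from a YAML file or an already-loaded mapping.

        Recognised keys: ``origin_px``, ``axis_deg``, ``pixel_scale_um``,
        ``frame_rate_fps``, ``capillary_width_um``, ``capillary_length_um``,
        ``wall_thickness_um``, ``control_origin_px``, ``control_axis_deg``.
        """
        if isinstance(path_or_dict, dict):
            cfg = path_or_dict
        else:
            with open(path_or_dict) as fh:
                cfg = yaml.safe_load(fh)
        kw = {}
        mapping = {
            "origin_px": "origin_px",
            "axis_deg": "axis_deg",
            "pixel_scale_um": "pixel_scale",
            "frame_rate_fps": "frame_rate",
            "capillary_width_um": "capillary_inner_width",
            "capillary_length_um": "capillary_length",
            "wall_thickness_um": "wall_thickness",
            "control_origin_px": "control_origin_px",
            "control_axis_deg": "control_axis_deg",
        }
        for key, attr in mapping.items():
            if key in cfg and cfg[key] is not None:
                val = cfg[key]
                if key.endswith("origin_px"):
                    val = tuple(float(v) for v in val)
                kw[attr] = val
        return cls(**kw)


@dataclass(frozen=True)
class RegionSpec:
    """A spatial region of the assay.

    ``inside_rect``: 0 <= axial <= depth, |transverse| <= capillary width / 2.
    ``outside_semicircle``: half-disc of the given radius in front of the
    entrance (axial < 0).
    ``corona``: annulus ``corona_inner <= r <= corona_outer`` around the
    entrance.
    ``neutral``: everything farther than ``depth_or_radius`` from the origin.
    """

    kind: RegionKind
    depth_or_radius: float = 0.0
    corona_inner: float = 0.0
    corona_outer: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "corona":
            if self.corona_inner < 0 or self.corona_outer <= self.corona_inner:
                raise ValueError("corona requires 0 <= inner < outer")
        elif self.kind not in ("inside_rect", "outside_semicircle", "neutral"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        elif self.depth_or_radius <= 0:
            raise ValueError("depth_or_radius must be > 0")

    @property
    def width(self) -> float:
        return self.corona_outer - self.corona_inner


def _rotation(axis_deg: float) -> np.ndarray:
    th = np.deg2rad(axis_deg)
    c, s = np.cos(th), np.sin(th)
    # rows project onto (axis, normal)
    return np.array([[c, s], [-s, c]])


def to_assay_frame(
    points_px, geometry: AssayGeometry, capillary: str = "cue"
) -> np.ndarray:
    """Map pixel coordinates to the assay frame (um, axial-first).

    The transform subtracts the entrance origin, converts to um, flips y
    (image y points down) and rotates so the first coordinate runs along
    the capillary axis, positive inward. Works on a single point or an
    (n, 2) array.
    """
    pts = np.asarray(points_px, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite pixel coordinates")
    if capillary == "cue":
        origin, axis_deg = geometry.origin_px, geometry.axis_deg
    elif capillary == "control":
        if geometry.control_origin_px is None or geometry.control_axis_deg is None:
            raise ValueError("geometry has no control capillary")
        origin, axis_deg = geometry.control_origin_px, geometry.control_axis_deg
    else:
        raise ValueError(f"unknown capillary {capillary!r}")
    rel = (pts - np.asarray(origin, float)) * geometry.pixel_scale
    rel = rel * np.array([1.0, -1.0])  # image y points down
    return rel @ _rotation(axis_deg).T


def from_assay_frame(
    points_um, geometry: AssayGeometry, capillary: str = "cue"
) -> np.ndarray:
    """Inverse of :func:`to_assay_frame` (assay um -> pixel coordinates)."""
    pts = np.asarray(points_um, dtype=float)
    if capillary == "cue":
        origin, axis_deg = geometry.origin_px, geometry.axis_deg
    else:
        origin, axis_deg = geometry.control_origin_px, geometry.control_axis_deg
    rel = pts @ _rotation(axis_deg)
    rel = rel * np.array([1.0, -1.0])
    return rel / geometry.pixel_scale + np.asarray(origin, float)


def in_glass(points_um, geometry: AssayGeometry) -> np.ndarray:
    """True where a point lies inside the capillary glass wall.

    Cells cannot occupy glass; such points belong to no region.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    axial, trans = pts[:, 0], np.abs(pts[:, 1])
    half = geometry.capillary_inner_width / 2
    return (
        (axial >= 0)
        & (axial <= geometry.capillary_length)
        & (trans > half)
        & (trans <= half + geometry.wall_thickness)
    )


def region_membership(
    points_um, spec: RegionSpec, geometry: AssayGeometry
) -> np.ndarray | bool:
    """Boolean membership of assay-frame points in a region.

    Vectorised: accepts a single (2,) point (returns a bool) or an (n, 2)
    array (returns a bool array). Points inside the glass wall are never
    members of any region.
    """
    pts = np.asarray(points_um, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    axial, trans = pts[:, 0], pts[:, 1]
    r = np.hypot(axial, trans)
    if spec.kind == "inside_rect":
        out = (
            (axial >= 0)
            & (axial <= spec.depth_or_radius)
            & (np.abs(trans) <= geometry.capillary_inner_width / 2)
        )
    elif spec.kind == "outside_semicircle":
        out = (axial < 0) & (r <= spec.depth_or_radius)
    elif spec.kind == "corona":
        out = (r >= spec.corona_inner) & (r <= spec.corona_outer)
    elif spec.kind == "neutral":
        out = r > spec.depth_or_radius
    else:  # pragma: no cover - guarded by RegionSpec
        raise ValueError(f"unknown region kind {spec.kind!r}")
    out = out & ~in_glass(pts, geometry)
    return bool(out[0]) if single else out


def make_corona(r_center: float, body_length: float = 20.0, multiplier: int = 7) -> RegionSpec:
    """Corona of width ``multiplier x body_length`` centred at ``r_center``.

    The assay's default corona is 140 um wide: seven times the ~20 um body
    length of the studied dinoflagellates.
    """
    if body_length <= 0 or multiplier < 1 or r_center <= 0:
        raise ValueError("r_center, body_length must be > 0 and multiplier >= 1")
    half = body_length * multiplier / 2
    if r_center - half < 0:
        raise ValueError("corona would extend past the origin; increase r_center")
    return RegionSpec("corona", corona_inner=r_center - half, corona_outer=r_center + half)
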