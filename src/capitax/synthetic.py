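"""Synthetic microcapillary assay: gradient field, swimmers, renderer.

Every analysis stage in this package is validated against data generated
here with known ground truth:

* a diffusing concentration field — the half-space continuous point source
  C(r, t) = C0 + (Q / 2 pi D r) erfc(r / sqrt(4 D t)) at the capillary
  mouth, joined to a 1D erfc profile along the capillary bore;
* agent-based swimmers with rotational diffusion, optional logarithmic
  gradient sensing (klinotaxis: turn bias at rate chi |grad C| / (C + eps)),
  optional chemokinesis (speed gain kappa saturating at K_half) and an
  optional behavioural shift to ballistic swimming after visiting the
  patch core;
* a direct rejection sampler for positions with density a exp(-x/lambda)+b
  restricted to a region, used to test the profile fits in isolation; and
* a bright-field-like frame renderer (Gaussian spots + sensor noise) for
  end-to-end tracking tests.

All randomness flows from a single seeded generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erfc

from .geometry import AssayGeometry, RegionSpec, from_assay_frame
from .tracking import Track

_UM3_PER_UM = 1e-6  # 1 uM expressed in fmol um^-3


@dataclass
class GradientModel:
    """Diffusing point-source concentration field at the capillary mouth.

    The source strength Q (fmol s^-1) defaults to the value that makes the
    steady-state concentration at the mouth equal the reservoir
    concentration filling the capillary, so the outside field and the
    inside axial profile are continuous there.

    Parameters
    ----------
    D : diffusivity, um^2 s^-1 (default 1000, a small organic solute).
    C0 : background concentration, uM.
    reservoir_concentration : cue concentration inside the capillary, uM.
    mouth_radius : effective source radius, um (capillary half-width).
    Q : source strength, fmol s^-1; derived from the reservoir if None.
    decay_time : optional source-depletion e-folding time, s (None = frozen).
    """

    D: float = 1000.0
    C0: float = 0.01
    reservoir_concentration: float = 20.0
    mouth_radius: float = 100.0
    Q: float | None = None
    decay_time: float | None = None
    source: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.D < 0 or self.C0 < 0:
            raise ValueError("D and C0 must be >= 0")
        if self.Q is None:
            dC = (self.reservoir_concentration - self.C0) * _UM3_PER_UM
            self.Q = dC * 2 * np.pi * self.D * self.mouth_radius
        if self.Q < 0:
            raise ValueError("Q must be >= 0")

    def _q_at(self, t: float) -> float:
        if self.decay_time is None:
            return self.Q
        return self.Q * np.exp(-t / self.decay_time)

    def concentration(self, points, t: float, geometry: AssayGeometry | None = None) -> np.ndarray:
        """Concentration (uM) at assay-frame points at time t (s)."""
        if t < 0:
            raise ValueError("t must be >= 0")
        pts = np.atleast_2d(np.asarray(points, float)) - np.asarray(self.source)
        axial, trans = pts[:, 0], pts[:, 1]
        half = geometry.capillary_inner_width / 2 if geometry else self.mouth_radius
        inside = (axial >= 0) & (np.abs(trans) <= half)
        r = np.maximum(np.hypot(axial, trans), self.mouth_radius)
        q = self._q_at(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            if t == 0:
                spread = np.zeros_like(r)
                spread_mouth = 0.0
            else:
                s4dt = np.sqrt(4 * self.D * t)
                spread = erfc(r / s4dt)
                spread_mouth = erfc(self.mouth_radius / s4dt)
        c_out = self.C0 + (q / (2 * np.pi * self.D * r)) / _UM3_PER_UM * spread
        c_mouth = (
            self.C0 + (q / (2 * np.pi * self.D * self.mouth_radius)) / _UM3_PER_UM * spread_mouth
        )
        # inside the bore: reservoir far in, mouth value at the entrance
        c_res = self.reservoir_concentration
        if t == 0:
            c_in = np.full_like(axial, c_res)
        else:
            c_in = c_mouth + (c_res - c_mouth) * (1 - erfc(axial / np.sqrt(4 * self.D * t)))
            # equivalently c_res - (c_res - c_mouth) * erfc(d / sqrt(4 D t));
            # erf form keeps continuity at the mouth (d = 0 -> c_mouth)
        out = np.where(inside, c_in, c_out)
        return out if np.asarray(points).ndim == 2 else out[:1].reshape(())

    def gradient(self, points, t: float, h: float = 1.0) -> np.ndarray:
        """Central-difference spatial gradient, uM um^-1, shape (n, 2)."""
        pts = np.atleast_2d(np.asarray(points, float))
        gx = (self.concentration(pts + [h, 0], t) - self.concentration(pts - [h, 0], t)) / (2 * h)
        gy = (self.concentration(pts + [0, h], t) - self.concentration(pts - [0, h], t)) / (2 * h)
        return np.column_stack([gx, gy])


@dataclass
class SwimmerConfig:
    """Parameters of the agent-based swimmer population.

    Speeds and densities mirror the assay organisms: base speed ~150
    um s^-1 (speeds up to ~300 um s^-1 near the source under chemokinesis),
    20 um body length, recorded at 30 fps. ``chi`` is the klinotaxis gain
    (um s^-1 of turn rate per unit log-gradient), ``kappa`` the fractional
    speed increase at saturating concentration.
    """

    n_cells: int = 100
    v0: float = 150.0
    rot_diffusion: float = 0.5  # rad^2 s^-1, far-field turning noise
    chi: float = 0.0
    kappa: float = 0.0
    K_half: float = 1.0  # uM, half-saturation of speed/turning modulation
    eps: float = 1e-3  # uM, regulariser in the log-sensing term
    rot_diffusion_patch: float | None = None  # turning noise at saturating C
    ballistic_after_visit: bool = False
    visit_radius: float = 120.0  # um, patch core that triggers the shift
    body_length: float = 20.0
    dt: float = 1.0 / 300.0
    duration: float = 120.0
    frame_rate: float = 30.0
    arena_radius: float = 1500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValueError("v0 must be > 0")
        if self.dt > 1.0 / self.frame_rate:
            raise ValueError("dt must not exceed the frame interval")
        if min(self.chi, self.kappa, self.rot_diffusion) < 0:
            raise ValueError("gains must be >= 0")
        if self.v0 * (1 + self.kappa) * self.dt > self.body_length:
            raise ValueError("dt too large: step would exceed one body length")


def _valid_positions(pts, geometry: AssayGeometry, arena_radius: float) -> np.ndarray:
    """Positions a swimmer may occupy: the dish minus glass, plus the bore."""
    axial, trans = pts[:, 0], pts[:, 1]
    half = geometry.capillary_inner_width / 2
    in_bore = (axial >= 0) & (axial <= geometry.capillary_length) & (np.abs(trans) <= half)
    in_glass = (
        (axial >= 0)
        & (axial <= geometry.capillary_length)
        & (np.abs(trans) > half)
        & (np.abs(trans) <= half + geometry.wall_thickness)
    )
    in_arena = np.hypot(axial, trans) <= arena_radius
    return (in_arena & ~in_glass) | in_bore


def simulate_assay(
    swim: SwimmerConfig,
    grad: GradientModel | None = None,
    geometry: AssayGeometry | None = None,
    rng: np.random.Generator | None = None,
) -> list[Track]:
    """Simulate swimmers around one capillary; returns tracks at frame rate.

    Per step the heading accumulates rotational diffusion
    (sigma = sqrt(2 Dr dt)) plus a deterministic turn toward the local
    concentration gradient at rate chi |grad C| / (C + eps); the speed is
    v0 (1 + kappa C / (C + K_half)). Moves into the dish wall or capillary
    glass are rejected and the swimmer turns back. ``grad=None`` simulates
    a cue-free (control) capillary.
    """
    if geometry is None:
        geometry = AssayGeometry()
    if rng is None:
        rng = np.random.default_rng(swim.seed)
    n = swim.n_cells
    # initial positions: uniform over valid dish area (not inside the bore)
    pos = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.uniform(-swim.arena_radius, swim.arena_radius, size=(2 * n, 2))
        ok = _valid_positions(cand, geometry, swim.arena_radius) & (cand[:, 0] < 0)
        cand = cand[ok]
        take = min(len(cand), n - filled)
        pos[filled : filled + take] = cand[:take]
        filled += take
    theta = rng.uniform(0, 2 * np.pi, size=n)
    visited = np.zeros(n, dtype=bool)

    steps_per_frame = max(int(round(1.0 / (swim.frame_rate * swim.dt))), 1)
    n_steps = int(round(swim.duration / swim.dt))
    n_frames = n_steps // steps_per_frame + 1
    out = np.empty((n_frames, n, 2))
    out[0] = pos
    sensing = grad is not None and (
        swim.chi > 0 or swim.kappa > 0 or swim.rot_diffusion_patch is not None
    )

    frame = 1
    for step in range(1, n_steps + 1):
        t = step * swim.dt
        if sensing:
            c = grad.concentration(pos, t, geometry)
            g = grad.gradient(pos, t)
            gnorm = np.linalg.norm(g, axis=1)
            sat = c / (c + swim.K_half)
            v = swim.v0 * (1 + swim.kappa * sat)
            if swim.rot_diffusion_patch is not None:
                dr = swim.rot_diffusion + (swim.rot_diffusion_patch - swim.rot_diffusion) * sat
                if swim.ballistic_after_visit:
                    dr = np.where(visited, swim.rot_diffusion, dr)
            else:
                dr = np.full(n, swim.rot_diffusion)
            if swim.chi > 0:
                rate = swim.chi * gnorm / (c + swim.eps)
                phi = np.arctan2(g[:, 1], g[:, 0])
                dtheta_det = rate * np.sin(phi - theta) * swim.dt
                if swim.ballistic_after_visit:
                    dtheta_det = np.where(visited, 0.0, dtheta_det)
            else:
                dtheta_det = 0.0
        else:
            v = np.full(n, swim.v0)
            dr = np.full(n, swim.rot_diffusion)
            dtheta_det = 0.0
        theta = theta + dtheta_det + np.sqrt(2 * dr * swim.dt) * rng.standard_normal(n)
        new = pos + (v * swim.dt)[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
        ok = _valid_positions(new, geometry, swim.arena_radius)
        pos = np.where(ok[:, None], new, pos)
        theta = np.where(ok, theta, theta + np.pi)
        if swim.ballistic_after_visit:
            visited |= np.linalg.norm(pos, axis=1) <= swim.visit_radius
        if step % steps_per_frame == 0:
            out[frame] = pos
            frame += 1

    frames = np.arange(frame)
    times = frames / swim.frame_rate
    tracks = []
    for i in range(n):
        tracks.append(Track(i, frames, out[:frame, i], times, label="swimmer"))
    return tracks


def simulate_assay_pair(
    swim: SwimmerConfig,
    grad: GradientModel,
    geometry: AssayGeometry | None = None,
) -> tuple[list[Track], list[Track]]:
    """Simulate the cue capillary and a cue-free control capillary.

    Both populations are independent and share the swimmer parameters; the
    control sees no gradient (its capillary holds plain medium). Tracks are
    each in their own capillary's assay frame, as produced by tracking.
    """
    ss = np.random.SeedSequence(swim.seed)
    rng_cue, rng_ctl = (np.random.default_rng(s) for s in ss.spawn(2))
    cue = simulate_assay(swim, grad, geometry, rng=rng_cue)
    control = simulate_assay(swim, None, geometry, rng=rng_ctl)
    return cue, control


def sample_exponential_positions(
    lam: float,
    a: float,
    b: float,
    n: int,
    region: RegionSpec,
    geometry: AssayGeometry | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw positions with areal density a exp(-x/lambda) + b in a region.

    ``x`` is the axial distance for ``inside_rect`` regions and the radius
    for ``outside_semicircle`` regions. Plain rejection sampling against a
    uniform proposal on the region; exact for any (a, b, lambda).
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if n <= 0:
        raise ValueError("n must be > 0")
    if a < 0 or b < 0 or a + b == 0:
        raise ValueError("need a, b >= 0 with a + b > 0")
    if geometry is None:
        geometry = AssayGeometry()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    fmax = a + b
    out = np.empty((n, 2))
    filled = 0
    half = geometry.capillary_inner_width / 2
    while filled < n:
        m = 4 * (n - filled) + 64
        if region.kind == "inside_rect":
            x = rng.uniform(0, region.depth_or_radius, m)
            y = rng.uniform(-half, half, m)
            dens = a * np.exp(-x / lam) + b
            pts = np.column_stack([x, y])
        elif region.kind == "outside_semicircle":
            r = region.depth_or_radius * np.sqrt(rng.uniform(0, 1, m))
            ang = rng.uniform(np.pi / 2, 3 * np.pi / 2, m)
            pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
            dens = a * np.exp(-r / lam) + b
        else:
            raise ValueError("sampler supports inside_rect and outside_semicircle")
        keep = pts[rng.uniform(0, fmax, m) < dens]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def positions_to_tracks(positions: np.ndarray, points_per_frame: int | None = None) -> list[Track]:
    """Wrap a cloud of sampled positions as stationary two-frame tracks so
    the profile code (which consumes tracks) can bin them directly."""
    n = len(positions)
    frames = np.array([0, 1])
    return [
        Track(i, frames, np.vstack([positions[i], positions[i]]), frames / 30.0)
        for i in range(n)
    ]


def render_frames(
    tracks: list[Track],
    geometry: AssayGeometry,
    shape: tuple[int, int] = (256, 256),
    cell_radius_px: float = 2.0,
    intensity: float = 120.0,
    background_level: float = 20.0,
    noise_sd: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render tracks as a synthetic bright-blob image stack.

    Cells are isotropic Gaussian spots (sigma = ``cell_radius_px``) added
    to a flat background with additive Gaussian sensor noise. Deterministic
    for a given seed. Tracks outside the canvas are clipped with a warning.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    h, w = shape
    n_frames = int(max(tr.frames[-1] for tr in tracks)) + 1
    stack = np.full((n_frames, h, w), float(background_level))
    win = int(np.ceil(4 * cell_radius_px))
    clipped = False
    for tr in tracks:
        px = from_assay_frame(tr.positions, geometry)
        for k in range(len(tr)):
            f = int(tr.frames[k])
            x, y = px[k]
            if not (0 <= x < w and 0 <= y < h):
                clipped = True
                continue
            xi, yi = int(round(x)), int(round(y))
            x0, x1 = max(xi - win, 0), min(xi + win + 1, w)
            y0, y1 = max(yi - win, 0), min(yi + win + 1, h)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            stack[f, y0:y1, x0:x1] += intensity * np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / (2 * cell_radius_px**2)
            )
    if clipped:
        warnings.warn("some track points fell outside the canvas and were clipped", stacklevel=2)
    stack += rng.normal(0, noise_sd, size=stack.shape)
    return stack
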