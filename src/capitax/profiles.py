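"""Cell-density maps, accumulation profiles and exponential-decay fits.

Accumulation around the cue capillary is summarised by two concentration
profiles: the axial profile C(d) inside the capillary and the radial profile
C(r) in the semicircular region outside the entrance. Both are fitted to a
decaying exponential

    C(x) = a * exp(-x / lambda) + b

whose decay length ``lambda`` is the typical scale of accumulation:
``lambda_in`` measures how deep cells explore the capillary, ``lambda_out``
the size of the cell patch at its mouth. Organisms that pack the first
stretch of the capillary at a constant density are better described by a
piecewise variant with a constant plateau of length L0 preceding the decay.

Fitting follows the statsmodels pattern: ``ExponentialDecayModel(profile)``
(or the plateau variant) exposes ``fit()`` returning a results object with
parameter estimates, standard errors, AICc and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import AssayGeometry, RegionSpec, region_membership
from .tracking import Track


class DegenerateProfileError(ValueError):
    """Raised when a profile carries no decaying signal to fit."""


@dataclass
class ConcentrationProfile:
    """Binned cell density versus distance.

    ``density`` is in cells um^-2 frame^-1 (a time-averaged areal
    concentration); ``counts`` are the raw per-bin track-point counts.
    """

    region: str  # "inside" or "outside"
    bin_edges: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    n_frames: int = 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"bin_center_um": self.bin_centers, "density": self.density, "count": self.counts}
        )


def _all_points(tracks: list[Track]) -> tuple[np.ndarray, int]:
    if not tracks:
        raise ValueError("no tracks")
    pts = np.vstack([tr.positions for tr in tracks])
    frames = np.concatenate([tr.frames for tr in tracks])
    n_frames = int(frames.max() - frames.min()) + 1
    return pts, n_frames


def density_map(
    tracks: list[Track], geometry: AssayGeometry, cell_size_um: float = 50.0, extent=None
):
    """Time-averaged 2D cell density on a square grid.

    Returns ``(grid, x_edges, y_edges)`` where ``grid[i, j]`` is the mean
    number of cells per unit area (um^-2) per frame in the cell. Summing
    ``grid * cell_area * n_frames`` recovers the total point count.
    """
    pts, n_frames = _all_points(tracks)
    if extent is None:
        lo = np.floor(pts.min(axis=0) / cell_size_um) * cell_size_um
        hi = np.ceil(pts.max(axis=0) / cell_size_um) * cell_size_um
        hi = np.where(hi <= lo, lo + cell_size_um, hi)
        extent = (lo[0], hi[0], lo[1], hi[1])
    x_edges = np.arange(extent[0], extent[1] + cell_size_um / 2, cell_size_um)
    y_edges = np.arange(extent[2], extent[3] + cell_size_um / 2, cell_size_um)
    hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(x_edges, y_edges))
    grid = hist / (cell_size_um**2 * n_frames)
    return grid, x_edges, y_edges


def axial_profile(
    tracks: list[Track],
    geometry: AssayGeometry,
    bin_width_um: float = 20.0,
    max_depth_um: float | None = None,
) -> ConcentrationProfile:
    """Concentration profile C(d) along the capillary axis, inside.

    Bin j holds count(d in bin j) / (bin_width * capillary_width * n_frames).
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width must be > 0")
    pts, n_frames = _all_points(tracks)
    half = geometry.capillary_inner_width / 2
    inside = (pts[:, 0] >= 0) & (np.abs(pts[:, 1]) <= half)
    d = pts[inside, 0]
    if max_depth_um is None:
        max_depth_um = max(d.max() if d.size else bin_width_um, bin_width_um)
    edges = np.arange(0, max_depth_um + bin_width_um, bin_width_um)
    counts, _ = np.histogram(d, bins=edges)
    density = counts / (bin_width_um * geometry.capillary_inner_width * n_frames)
    return ConcentrationProfile("inside", edges, density, counts, n_frames)


def radial_profile(
    tracks: list[Track],
    geometry: AssayGeometry,
    bin_width_um: float = 10.0,
    max_radius_um: float | None = None,
    normalize_area: bool = True,
) -> ConcentrationProfile:
    """Concentration profile C(r) in the outer semicircle.

    Each bin is a semi-annulus of area pi (r2^2 - r1^2) / 2; the outside
    half-plane (axial < 0) never intersects the capillary glass so no shadow
    correction is needed. ``normalize_area=False`` returns raw counts per
    frame instead of areal densities.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width must be > 0")
    pts, n_frames = _all_points(tracks)
    outside = pts[:, 0] < 0
    r = np.hypot(pts[outside, 0], pts[outside, 1])
    if max_radius_um is None:
        max_radius_um = max(r.max() if r.size else bin_width_um, bin_width_um)
    edges = np.arange(0, max_radius_um + bin_width_um, bin_width_um)
    counts, _ = np.histogram(r, bins=edges)
    if normalize_area:
        areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) / 2
        density = counts / (areas * n_frames)
    else:
        density = counts / n_frames
    return ConcentrationProfile("outside", edges, density, counts, n_frames)


# ---------------------------------------------------------------------------
# fitting


def _exp_model(x, a, b, lam):
    return a * np.exp(-x / lam) + b


def _fit_exp_ls(x, y, lam0, a0, b0, lam_max):
    def resid(p):
        a, b, lam = p
        return _exp_model(x, a, b, lam) - y

    return least_squares(
        resid,
        x0=[a0, b0, lam0],
        bounds=([0, -np.inf, 1e-9], [np.inf, np.inf, lam_max]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )


class ExponentialDecayModel:
    """Least-squares fit of C(x) = a exp(-x/lambda) + b to a profile.

    Multi-start in lambda (1/4, 1/2 and 1 times the profile extent) guards
    against the local minima typical of exponential fits; lambda is bounded
    above by 10x the profile extent, beyond which the profile is reported
    as non-decaying.

    Parameters
    ----------
    profile : ConcentrationProfile, or (x, y) arrays via ``from_xy``.
    weights : None or "poisson" — optional 1/sqrt(count) weighting.
    """

    k_params = 3

    def __init__(self, profile: ConcentrationProfile, weights: str | None = None):
        self.profile = profile
        x = profile.bin_centers
        y = np.asarray(profile.density, float)
        ok = np.isfinite(y)
        self.x, self.y = x[ok], y[ok]
        if weights == "poisson":
            w = 1.0 / np.sqrt(np.maximum(profile.counts[ok], 1.0))
            self.x, self.y = self.x, self.y  # weights applied in residual scale
            self._w = w
        else:
            self._w = None
        if self.x.size < 4:
            raise ValueError("need at least 4 finite bins")

    @classmethod
    def from_xy(cls, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        prof = ConcentrationProfile(
            "inside",
            np.concatenate([x - np.diff(x).mean() / 2, [x[-1] + np.diff(x).mean() / 2]]),
            y,
            np.zeros_like(y),
        )
        return cls(prof)

    def fit(self) -> "ExponentialDecayResults":
        x, y = self.x, self.y
        if np.ptp(y) < 1e-12 * max(abs(y).max(), 1e-30) or np.ptp(y) == 0:
            raise DegenerateProfileError("profile is constant; decay length undefined")
        extent = x.max() - x.min()
        lam_max = 10 * extent
        n_tail = max(len(y) // 4, 1)
        b0 = float(np.mean(y[-n_tail:]))
        a0 = max(float(np.mean(y[:n_tail]) - b0), 1e-12 * max(abs(y).max(), 1.0))
        best = None
        for frac in (0.25, 0.5, 1.0):
            try:
                res = _fit_exp_ls(x, y, frac * extent, a0, b0, lam_max)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("exponential fit failed to converge from all starts")
        a, b, lam = best.x
        rss = float(2 * best.cost)
        se = _se_from_jacobian(best.jac, rss, len(y))
        non_decaying = lam >= 0.999 * lam_max
        return ExponentialDecayResults(
            self, a=a, b=b, lam=lam, rss=rss, se=se, nobs=len(y), non_decaying=non_decaying
        )


def _se_from_jacobian(jac, rss, n):
    k = jac.shape[1]
    dof = max(n - k, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * rss / dof
        return np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


@dataclass
class ExponentialDecayResults:
    model: ExponentialDecayModel
    a: float
    b: float
    lam: float
    rss: float
    se: np.ndarray  # order (a, b, lam)
    nobs: int
    non_decaying: bool = False
    plateau_len: float = 0.0

    @property
    def se_lam(self) -> float:
        return float(self.se[-1])

    @property
    def k_params(self) -> int:
        return getattr(type(self.model), "k_params", 3)

    @property
    def aicc(self) -> float:
        """Small-sample-corrected AIC under Gaussian residuals."""
        n, k = self.nobs, self.k_params
        aic = n * np.log(max(self.rss, 1e-300) / n) + 2 * k
        if n - k - 1 > 0:
            aic += 2 * k * (k + 1) / (n - k - 1)
        return float(aic)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        xs = np.maximum(x - self.plateau_len, 0.0)
        return _exp_model(xs, self.a, self.b, self.lam)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "lam": self.lam,
            "plateau_len": self.plateau_len,
            "rss": self.rss,
            "se_lam": self.se_lam,
            "non_decaying": self.non_decaying,
        }

    def summary(self) -> str:
        kind = "plateau + exponential" if self.plateau_len > 0 else "exponential decay"
        lines = [
            f"{'Accumulation profile fit':^58}",
            "=" * 58,
            f"Model:            {kind}",
            f"Region:           {self.model.profile.region}",
            f"No. observations: {self.nobs}",
            f"RSS:              {self.rss:.6g}    AICc: {self.aicc:.4g}",
            "-" * 58,
            f"{'param':<14}{'estimate':>14}{'std err':>14}",
            f"{'a (amplitude)':<14}{self.a:>14.6g}{self.se[0]:>14.3g}",
            f"{'b (baseline)':<14}{self.b:>14.6g}{self.se[1]:>14.3g}",
            f"{'lambda (um)':<14}{self.lam:>14.6g}{self.se[-1]:>14.3g}",
        ]
        if self.plateau_len > 0:
            lines.append(f"{'L0 (um)':<14}{self.plateau_len:>14.6g}{'profiled':>14}")
        if self.non_decaying:
            lines.append("WARNING: lambda at bound; profile effectively non-decaying")
        lines.append("=" * 58)
        return "\n".join(lines)


class PlateauExponentialModel(ExponentialDecayModel):
    """Constant plateau of length L0 followed by an exponential decay.

    C(x) = a + b for x <= L0 and a exp(-(x - L0)/lambda) + b beyond, which
    is continuous at the breakpoint by construction. L0 is profiled over a
    grid of bin edges; (a, b, lambda) are fitted by least squares at each
    candidate and the L0 with the smallest RSS wins.
    """

    k_params = 4

    def __init__(self, profile: ConcentrationProfile, weights: str | None = None):
        super().__init__(profile, weights)
        if self.x.size < 6:
            raise ValueError("plateau fit needs at least 6 finite bins")

    def fit(self) -> ExponentialDecayResults:
        x, y = self.x, self.y
        if np.ptp(y) == 0:
            raise DegenerateProfileError("profile is constant; decay length undefined")
        extent = x.max() - x.min()
        lam_max = 10 * extent
        n_tail = max(len(y) // 4, 1)
        b0 = float(np.mean(y[-n_tail:]))
        a0 = max(float(np.mean(y[:n_tail]) - b0), 1e-12 * max(abs(y).max(), 1.0))
        # candidate breakpoints: bin edges up to where >= 4 bins remain
        edges = self.profile.bin_edges
        cands = [e for e in edges if np.sum(x > e) >= 4]
        cands = [max(e, 0.0) for e in cands if e <= x.max()]
        best, best_l0, best_res = np.inf, 0.0, None
        for l0 in cands:
            xs = np.maximum(x - l0, 0.0)
            try:
                res = min(
                    (_fit_exp_ls(xs, y, frac * extent, a0, b0, lam_max) for frac in (0.25, 0.5, 1.0)),
                    key=lambda r: r.cost,
                )
            except Exception:
                continue
            if res.cost < best:
                best, best_l0, best_res = res.cost, l0, res
        if best_res is None:
            raise RuntimeError("plateau-exponential fit failed to converge")
        a, b, lam = best_res.x
        rss = float(2 * best_res.cost)
        se = _se_from_jacobian(best_res.jac, rss, len(y))
        out = ExponentialDecayResults(
            self,
            a=a,
            b=b,
            lam=lam,
            rss=rss,
            se=se,
            nobs=len(y),
            non_decaying=lam >= 0.999 * lam_max,
            plateau_len=float(best_l0),
        )
        return out


def fit_exponential(profile: ConcentrationProfile, **kw) -> ExponentialDecayResults:
    """Convenience wrapper: fit the plain decaying exponential."""
    return ExponentialDecayModel(profile, **kw).fit()


def fit_plateau_exponential(profile: ConcentrationProfile, **kw) -> ExponentialDecayResults:
    """Convenience wrapper: fit the plateau-then-decay piecewise model."""
    return PlateauExponentialModel(profile, **kw).fit()


def select_profile_model(
    profile: ConcentrationProfile, delta_aic: float = 2.0
) -> tuple[str, ExponentialDecayResults]:
    """Choose between the plain and plateau exponential by small-sample AIC.

    The piecewise model is selected only when its AICc improves on the plain
    exponential by more than ``delta_aic`` (default 2), so the extra
    breakpoint must earn its keep.
    """
    plain = ExponentialDecayModel(profile).fit()
    try:
        pw = PlateauExponentialModel(profile).fit()
    except (ValueError, RuntimeError):
        return "exponential", plain
    if plain.aicc - pw.aicc > delta_aic and pw.plateau_len > 0:
        return "piecewise", pw
    return "exponential", plain


def mean_decay_length(fits: list[ExponentialDecayResults]) -> float:
    """Replicate-averaged decay length: the arithmetic mean of per-replicate
    lambda estimates, as reported per organism and concentration."""
    if not fits:
        raise ValueError("no fits to average")
    return float(np.mean([f.lam for f in fits]))
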