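"""Whole-assay analysis: one model object from tracks to report.

``ChemotaxisAssayModel`` bundles the full analysis of a two-capillary
assay: accumulation profiles and their exponential fits (lambda_in,
lambda_out), the gated maximum chemotactic indices, long-term accumulation
rates, and — when requested — the behavioural statistics (straightness by
segment class, chemokinesis). ``fit()`` returns a results object with the
estimates, their uncertainties and a ``summary()`` table, in the spirit of
statsmodels model/results pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import behaviour, index as index_mod, profiles as prof_mod
from .geometry import AssayGeometry, RegionSpec, make_corona
from .tracking import Track


@dataclass
class AssayConfig:
    """Analysis parameters, defaulting to the assay's standard constants:
    30 fps video, 120 s accumulation window, alpha = 0.01 gate, 200 um
    patch radius after 60 s, 400 um neutral radius, 140 um corona."""

    bin_width_inside: float = 20.0
    bin_width_outside: float = 10.0
    window_s: float = 120.0
    alpha: float = 0.01
    gate_on: str = "blocks"
    patch_radius: float = 200.0
    t_min: float = 60.0
    neutral_radius: float = 400.0
    corona_center: float = 130.0
    body_length: float = 20.0
    corona_multiplier: int = 7
    behaviour_stats: bool = True


class ChemotaxisAssayModel:
    """Full analysis of one cue/control assay from track tables."""

    def __init__(
        self,
        cue_tracks: list[Track],
        control_tracks: list[Track],
        geometry: AssayGeometry | None = None,
        config: AssayConfig | None = None,
    ):
        if not cue_tracks or not control_tracks:
            raise ValueError("need tracks for both capillaries")
        self.cue_tracks = cue_tracks
        self.control_tracks = control_tracks
        self.geometry = geometry or AssayGeometry()
        self.config = config or AssayConfig()

    def fit(self) -> "ChemotaxisAssayResults":
        cfg, geom = self.config, self.geometry
        axial = prof_mod.axial_profile(self.cue_tracks, geom, cfg.bin_width_inside)
        radial = prof_mod.radial_profile(self.cue_tracks, geom, cfg.bin_width_outside)
        kind_in, fit_in = prof_mod.select_profile_model(axial)
        kind_out, fit_out = prof_mod.select_profile_model(radial)
        lam_in, lam_out = fit_in.lam, fit_out.lam

        idx = index_mod.chemotactic_index(
            self.cue_tracks,
            self.control_tracks,
            geom,
            lam_in=lam_in,
            lam_out=lam_out,
            window_s=cfg.window_s,
            alpha=cfg.alpha,
            gate_on=cfg.gate_on,
        )
        inside = RegionSpec("inside_rect", depth_or_radius=lam_in)
        cue_series = index_mod.count_in_region(self.cue_tracks, inside, geom)
        slope, slope_se = index_mod.accumulation_rate(cue_series)

        seg_result = speed_profile = None
        if cfg.behaviour_stats:
            corona = make_corona(cfg.corona_center, cfg.body_length, cfg.corona_multiplier)
            try:
                segs = behaviour.classify_segments(
                    self.cue_tracks,
                    geom,
                    corona,
                    patch_radius=cfg.patch_radius,
                    t_min=cfg.t_min,
                    neutral_radius=cfg.neutral_radius,
                )
                seg_result = behaviour.segment_straightness(segs)
            except ValueError:
                seg_result = None
            try:
                speed_profile = behaviour.speed_vs_distance(
                    self.cue_tracks, geom, near_radius=cfg.patch_radius
                )
            except ValueError:
                speed_profile = None

        return ChemotaxisAssayResults(
            model=self,
            profile_inside=axial,
            profile_outside=radial,
            fit_inside=fit_in,
            fit_outside=fit_out,
            model_kind_inside=kind_in,
            model_kind_outside=kind_out,
            index=idx,
            accumulation_slope=slope,
            accumulation_slope_se=slope_se,
            straightness=seg_result,
            speed_profile=speed_profile,
        )


@dataclass
class ChemotaxisAssayResults:
    model: ChemotaxisAssayModel
    profile_inside: prof_mod.ConcentrationProfile
    profile_outside: prof_mod.ConcentrationProfile
    fit_inside: prof_mod.ExponentialDecayResults
    fit_outside: prof_mod.ExponentialDecayResults
    model_kind_inside: str
    model_kind_outside: str
    index: index_mod.ChemotaxisIndex
    accumulation_slope: float
    accumulation_slope_se: float
    straightness: behaviour.StraightnessResult | None = None
    speed_profile: behaviour.SpeedProfile | None = None

    @property
    def lambda_in(self) -> float:
        return self.fit_inside.lam

    @property
    def lambda_out(self) -> float:
        return self.fit_outside.lam

    def to_dict(self) -> dict:
        out = {
            "lambda_in_um": self.lambda_in,
            "lambda_out_um": self.lambda_out,
            "profile_model_inside": self.model_kind_inside,
            "profile_model_outside": self.model_kind_outside,
            "fit_inside": self.fit_inside.to_dict(),
            "fit_outside": self.fit_outside.to_dict(),
            "index": self.index.to_dict(),
            "accumulation_slope_cells_s": self.accumulation_slope,
            "accumulation_slope_se": self.accumulation_slope_se,
        }
        if self.straightness is not None:
            out["straightness_medians"] = {
                lab: self.straightness.median(lab) for lab in sorted(set(self.straightness.labels))
            }
            out["straightness_n"] = self.straightness.group_sizes()
        if self.speed_profile is not None:
            out["chemokinesis_ratio"] = self.speed_profile.chemokinesis_ratio
            out["chemokinesis_p"] = self.speed_profile.p_value
        return out

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def summary(self) -> str:
        idx = self.index
        lines = [
            f"{'Microcapillary chemotaxis assay':^60}",
            "=" * 60,
            f"Tracks (cue/control):   {len(self.model.cue_tracks)} / "
            f"{len(self.model.control_tracks)}",
            f"Profile model (in/out): {self.model_kind_inside} / {self.model_kind_outside}",
            f"lambda_in:  {self.lambda_in:9.1f} um   (SE {self.fit_inside.se_lam:.2g})",
            f"lambda_out: {self.lambda_out:9.1f} um   (SE {self.fit_outside.se_lam:.2g})",
            "-" * 60,
            f"Ic_max inside:  {idx.ic_inside:7.2f}   p = {idx.p_inside:.3g}"
            + ("   [gated]" if idx.gated_inside else ""),
            f"Ic_max outside: {idx.ic_outside:7.2f}   p = {idx.p_outside:.3g}"
            + ("   [gated]" if idx.gated_outside else ""),
            f"Accumulation rate: {self.accumulation_slope:.4g} "
            f"+/- {self.accumulation_slope_se:.2g} cells s^-1",
        ]
        if self.straightness is not None and len(self.straightness.S):
            meds = {lab: self.straightness.median(lab) for lab in ("ingoing", "outgoing", "neutral")}
            sizes = self.straightness.group_sizes()
            lines.append("-" * 60)
            lines.append("Straightness S (median [n]):")
            for lab in ("ingoing", "outgoing", "neutral"):
                if sizes.get(lab):
                    lines.append(f"  {lab:<9} {meds[lab]:.3f}  [{sizes[lab]}]")
        if self.speed_profile is not None and np.isfinite(self.speed_profile.chemokinesis_ratio):
            lines.append(
                f"Chemokinesis speed ratio (near/far): "
                f"{self.speed_profile.chemokinesis_ratio:.2f}  "
                f"(p = {self.speed_profile.p_value:.3g})"
            )
        lines.append("=" * 60)
        return "\n".join(lines)
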