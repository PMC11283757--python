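# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `capitax`, and what its synthetic-data validation
does and does not demonstrate about real assay data.

## Assay geometry and coordinates

All analysis happens in the *assay frame*: continuous µm coordinates with
the origin at the centre of the cue-capillary entrance and the first
(axial) coordinate along the capillary axis, positive inward. Image pixel
coordinates (origin top-left, y down) map to this frame by an invertible
affine transform (translation, µm scaling, y-flip, rotation); the control
capillary gets its own congruent frame via `control_origin_px` /
`control_axis_deg`. Defaults mirror the physical assay: a square
borosilicate capillary 200 µm of inner width, 50 mm long, 100 µm wall,
imaged at 30 fps.

Regions:

* `inside_rect` — 0 ≤ d ≤ depth, |transverse| ≤ 100 µm (the capillary bore);
* `outside_semicircle` — the half-disc in front of the entrance
  (axial < 0). The wording "semicircular region centred in the origin"
  does not orient the half-disc; we restrict it to the open half-plane
  because the entrance wall makes the other half unreachable, which also
  means the semicircle never intersects glass and semi-annulus areas need
  no shadow correction;
* `corona` — an annulus around the entrance (the behavioural sampling
  corona is 140 µm wide: seven 20 µm body lengths, centred by the caller);
* `neutral` — everything beyond a given radius.

Points inside the 100 µm glass wall belong to no region (cells cannot
occupy glass).

## Tracking

Background: per-pixel temporal median of the stack — valid when each cell
occupies a given pixel for less than half the recording, which swimming
speeds of order 100 µm s⁻¹ guarantee. Detection: connected components of
|frame − background| above a threshold, with intensity-weighted centroids
(sub-pixel for symmetric spots) and a minimum area.

Linking is a deliberately transparent greedy mutual-nearest-neighbour
matcher: candidate (track, detection) pairs within `max_displacement` are
accepted in order of increasing distance (ties broken by detection index,
then track id), tracks survive up to `memory = 2` missed frames, and the
result is deterministic and invariant to detection order within a frame.
The default `max_displacement` should be ≈ 1.2 × (maximum expected speed /
frame rate) — speeds up to ~300 µm s⁻¹ at 30 fps imply ≤ ~10 µm per frame.
Tests bound the greedy matcher's cost against an exhaustive bipartite
oracle; it is not a global optimiser, which at assay densities costs
nothing measurable. The default minimum track length for analysis is 15
frames (0.5 s), configurable; no published cutoff exists for this assay,
so short, uninformative fragments are simply excluded.

## Accumulation profiles and exponential fits

Densities are time-averaged areal concentrations: counts per bin divided
by bin area and by the number of recorded frames. The axial profile bins
d in 20 µm bins over the bore cross-section; the radial profile bins r in
10 µm semi-annuli (area π(r₂² − r₁²)/2), normalised by area by default
(`normalize_area=False` gives raw counts per frame). The bin widths keep
≥ 10 bins across the empirically relevant λ range (λ_out of order
84–140 µm; λ_in up to a few mm).

The decay model C(x) = a·e^(−x/λ) + b is fitted by bounded least squares
(a ≥ 0, λ > 0) on the density values, unweighted by default (a Poisson
1/√count weighting is available). Exponential fits have well-known local
minima, so the optimiser multi-starts from λ₀ ∈ {¼, ½, 1} × profile
extent with b₀ = tail mean and a₀ = head − tail. λ is capped at 10 × the
profile extent; a fit at the cap is flagged `non_decaying`. Constant
profiles raise `DegenerateProfileError` rather than returning a
meaningless λ. Standard errors come from the Gauss–Newton covariance
(rss/(n−k))·(JᵀJ)⁻¹.

The plateau variant C(x) = a + b for x ≤ L₀, a·e^(−(x−L₀)/λ) + b beyond
(continuous at L₀ by construction) profiles L₀ over the bin-edge grid,
refitting (a, b, λ) at each candidate — equivalent to exhaustive
breakpoint search at bin resolution. Model choice uses small-sample AICc
with the breakpoint counted as a parameter; the piecewise model must
improve AICc by > 2. Replicate-level λ values are combined as the
arithmetic mean of per-replicate fits.

## Chemotactic index and its significance gate

Ic_max = (mean cue-region count in the mean-maximising contiguous window,
default 120 s) / (mean control-region count over the entire assay). The
window is the *mean-maximising* window, not one centred on the peak frame
(configurable); ties resolve to the earliest window. Cue regions use the
cue capillary's own fitted λ_in/λ_out; the control uses congruent regions
at its own entrance, so count ratios equal concentration ratios. A zero
control mean yields an `inf` sentinel with an `undefined` flag, never a
silent drop. The OLS slope of counts versus time (cells s⁻¹, with its
standard error) summarises long-term accumulation.

**The gate.** Cue/control count differences are tested nonparametrically
before the ratio is reported; a nonsignificant difference (p > α = 0.01)
gates the index to 1 (neutral). Applied to raw per-frame counts the
two-group Kruskal–Wallis test is grossly anti-conservative: at 30 fps a
cell resides in a region for seconds, so 18 000 frames carry perhaps
tens of independent observations, and in simulation the per-frame gate
passed essentially no null assay. The gate decision therefore uses the
two-group rank test (Kruskal–Wallis with two groups ≡ Wilcoxon rank-sum)
applied to the means of 8 non-overlapping time blocks per series, with
the exact small-sample null (enumeration, or the permutation distribution
when block means tie). Eight blocks of a 10-minute assay are ~75 s long —
above the empirical mixing time of region occupancy — and null
simulations gate in ≈ 98% of runs at α = 0.01 while strong simulated
attraction is still detected essentially always. The per-frame p-value is
always computed and reported next to the block p; `gate_on="perframe"`
restores the raw behaviour. One boundary convention: significance is
impossible at level α ≥ 1, so α = 1 gates every index.

A caveat the block test cannot remove: region occupancy in *short* assays
(≲ 2 min) mixes too slowly for any within-assay two-sample test — a
single cell that wanders into one capillary and stays is statistically
indistinguishable from weak attraction. Calibration therefore holds at
the assay's full 10-minute duration, and short recordings should rely on
replicate-level comparison rather than the within-assay gate.

## Swimming behaviour

Positions are smoothed with a 3-frame centred moving average (edges shrink
symmetrically so linear motion is preserved) before finite-difference
speeds — 30 fps centroid jitter otherwise inflates instantaneous speed;
`smoothing_window=1` disables this.

Segments are contiguous runs of a track inside the 140 µm sampling corona,
restricted to the developed diffusing patch (r ≤ 200 µm, t > 60 s);
the run's net radial displacement decides *ingoing* versus *outgoing* —
the operational rule for a direction the assay literature leaves informal.
*Neutral* segments are runs at r > 400 µm during the first 60 s, before
the cue can have reached them. Segments need ≥ 3 points.

S = D/L per segment; group medians and sizes are reported, pairwise
differences tested by two-sided Mann–Whitney with Holm correction (the
assay literature marks significance without naming a test; this is the
standard choice for unpaired non-normal samples). Because S decreases
with path length for any non-ballistic motion, the robustness scan
truncates segments to common arc lengths of 3–10 body lengths (default
7 BL = 140 µm) and flags lengths whose median shifts by more than 10%.
Segments are pooled across replicates (not medians of medians).

Chemokinesis: the 2D histogram of instantaneous speed × radial distance,
column-normalised per radial bin, plus the ratio of median speed within
200 µm of the source to the median in the remaining area with a rank-sum
p-value.

## Uptake kinetics

Input: times (h), cell-fraction activity (dpm ml⁻¹), a killed-control
blank (series or scalar), cell density (ml⁻¹) and mean cell volume (µm³).
Normalised uptake = (activity − blank)/(density × volume), in dpm µm⁻³;
negative blank-corrected values clip to zero with a warning. Specific
activity converts spike activity to tracer concentration
(dpm ml⁻¹ ÷ dpm fmol⁻¹ ↔ pmol l⁻¹, numerically unit-preserving).

No standard estimation convention exists for the printed "initial rate"
and "satiation" of such time courses, so both natural readings are fitted
and reported: an OLS slope over t ≤ 5 h, and U(t) = U_sat(1 − e^(−t/τ))
by multi-start bounded least squares (τ₀ ∈ {0.1, 0.5, 2} × t_max), whose
plateau U_sat is the satiation level and U_sat/τ the model-based initial
slope. A τ at its upper bound flags a course that has not yet levelled
off. Plateau differences between organisms use a two-sample t on
replicate plateau estimates — fragile below n = 3 replicates, and warned
about accordingly.

## Synthetic assay

**Concentration field.** Outside the capillary, the half-space continuous
point source C(r, t) = C₀ + Q/(2πDr)·erfc(r/√(4Dt)), with r capped at the
100 µm mouth radius; inside the bore, an axial erf profile joining the
mouth value continuously to the reservoir concentration. Q defaults to
the value that makes the steady mouth concentration equal the reservoir
(20 µM), i.e. Q = ΔC·2πD·r_mouth ≈ 12.6 fmol s⁻¹ at D = 1000 µm² s⁻¹ (a
small organic solute). 1 µM = 10⁻⁶ fmol µm⁻³ throughout. A `decay_time`
option depletes the source exponentially; the default keeps it frozen,
since the in-capillary reservoir over 10 min is effectively unlimited.
The field is validated against a finite-volume radial diffusion solver
(2% at r = 100 µm, t = 60 s).

**Swimmers.** 2D agents (the assay is imaged in a thin layer at the dish
bottom) with heading θ and per-step updates:

* rotational diffusion, σ = √(2·D_rot·dt), default D_rot = 0.5 rad² s⁻¹
  (persistence ~1 s, typical of dinoflagellate swimming);
* klinotaxis: deterministic turning toward ∇C at rate χ·|∇C|/(C + ε) —
  logarithmic sensing with ε = 10⁻³ µM; χ = 200 (µm s⁻¹ of turn rate per
  unit log-gradient) produces ~2 rad s⁻¹ of bias at r = 100 µm of the
  default source, i.e. strong attraction of the magnitude the assay's
  largest indices imply;
* chemokinesis: v = v₀(1 + κ·C/(C + K_half)), v₀ = 150 µm s⁻¹,
  K_half = 1 µM, so speeds approach v₀(1 + κ) near the source (≈ 300 µm
  s⁻¹ at κ = 1, the observed ceiling);
* optionally, concentration-modulated turning noise
  (`rot_diffusion_patch`) and a behavioural shift to ballistic swimming
  after first visiting the patch core (`ballistic_after_visit`,
  `visit_radius`). The shift is deliberate: a memoryless
  concentration-modulated turning model is in/out symmetric and cannot
  produce the observed straighter *outgoing* trajectories, so the exit
  behaviour is modelled as a state change.

Moves into the dish wall (default arena radius 1500 µm ≈ a field of view)
or capillary glass are rejected and the swimmer turns back; cells may
enter the bore through the mouth. dt defaults to 1/300 s with output
decimated to 30 fps; a step larger than one body length is rejected. All
randomness flows from one seeded generator; `simulate_assay_pair` spawns
independent streams for the cue and control populations.

**Direct sampler.** `sample_exponential_positions` rejection-samples
positions from a·e^(−x/λ) + b restricted to a region (axial distance
inside, radius outside) — exact for any parameters, used to test the
profile fits in isolation from the dynamics.

**Renderer.** Gaussian spots (σ = 2 px) on a flat background with
additive Gaussian sensor noise, deterministic per seed; closes the loop
for detection/linking tests.

**What the generator does not emulate:** 3D helical swimming and its
projection artefacts, cell–cell collisions and hydrodynamic interactions,
flow disturbances during capillary placement, uneven illumination and
shading, cell division, shape change, or prey ingestion. Passing the
closure tests shows the *analysis* is correct and well-calibrated under
the generative assumptions; it does not certify the tracking against real
bright-field imagery, nor the behavioural statistics against 3D motility.

## Problem sizes used by the test suite

Simulation-based checks run at sizes chosen to make their statistical
assertions decisive while keeping the full suite around ten minutes on
one CPU: null-gate calibration uses 200 runs × 100 cells × 600 s at
dt = 1/30 s with the 120 s window (the full assay duration matters — see
the gate caveat above); index monotonicity uses χ ∈ {0, 50, 200} × 5
seeds at 40 cells × 120 s; decay-length recovery uses 100 samplings of
5000 points; the tracking closure renders 9 cells × 30 frames on a
256 px canvas; behavioural closure simulates 150 swimmers × 150 s with
the two-regime configuration.

## Known limitations

* The linker is greedy; pathological crossings that a global optimiser
  would resolve can swap identities (bounded in tests, rare at assay
  densities).
* The within-assay significance gate is calibrated for ~10-minute
  recordings; shorter series have too few independent blocks.
* The plateau length L₀ is resolved only to bin-edge resolution.
* Uptake satiation comparisons inherit the fragility of n = 2 replicate
  designs regardless of the test used.
* Areal normalisation of the outside profile assumes the full semi-disc
  is observable; assays with occluded sectors need a custom area model.
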