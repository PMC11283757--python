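# capitax

Quantitative analysis of **microcapillary chemotaxis assays** for motile
protists (dinoflagellates and other swimming microbes).

In this assay a glass microcapillary filled with a dissolved cue (e.g. the
algal osmolyte DMSP) is placed on the bottom of a dish of cell culture next
to a control capillary filled with plain medium. The cue diffuses from the
capillary mouth as from a point source, and the cells' swimming response is
video-recorded at 30 fps. `capitax` turns those videos — or any cell-track
table — into the assay's standard quantitative read-outs:

* **Accumulation profiles and decay lengths.** Time-averaged cell density
  is profiled along the capillary axis inside (distance *d*) and radially
  outside the entrance (distance *r*), and fitted to a decaying exponential

  &nbsp;&nbsp;&nbsp;&nbsp;*C*(*x*) = *a* e^(−*x*/λ) + *b*,

  giving λ_in (depth of exploration inside the capillary) and λ_out (size
  of the cell patch at the mouth). A piecewise variant with a constant
  plateau of length *L*₀ before the decay handles organisms that pack the
  first stretch of the capillary; the two models are compared by
  small-sample AIC.

* **Gated maximum chemotactic index.**

  &nbsp;&nbsp;&nbsp;&nbsp;*Ic*_max = C̄_S / C̄_C,

  the mean cell count near the cue during the best 2-minute window divided
  by the mean count in the congruent control region over the whole assay,
  reported separately inside (region depth λ_in) and outside (radius
  λ_out). A nonparametric rank-test gate sets the index to 1 (neutral)
  when cue and control counts do not differ significantly (α = 0.01);
  because per-frame counts are strongly autocorrelated, the gate is
  applied to per-block mean counts with an exact small-sample null (the
  raw per-frame p-value is reported alongside). Long-term accumulation is
  summarised by the OLS slope of counts versus time.

* **Swimming behaviour.** The straightness index

  &nbsp;&nbsp;&nbsp;&nbsp;*S* = *D*/*L*

  (net displacement over path length; 1 = ballistic, ≪ 1 = convoluted
  searching) is computed for trajectory segments classified as *ingoing*,
  *outgoing* (crossing a 140 µm sampling corona inside the diffusing
  patch) or *neutral* (far-field background swimming), with a robustness
  scan over standardized arc lengths (3–10 body lengths) and pairwise
  rank tests. Chemokinesis is quantified as the ratio of median swimming
  speed near the source to the median elsewhere.

* **Radiotracer uptake kinetics.** ³⁵S-DMSP time courses are
  blank-corrected and biovolume-normalised (dpm µm⁻³), then summarised by
  a 0–5 h linear initial rate and a saturating fit
  *U*(*t*) = *U*_sat (1 − e^(−*t*/τ)) whose plateau is the satiation level.

* **A synthetic assay simulator** — a diffusing point-source concentration
  field (half-space erfc solution) plus agent-based swimmers with
  rotational diffusion, logarithmic gradient sensing (klinotaxis gain χ)
  and concentration-dependent speed (chemokinesis gain κ) — provides
  ground truth for every stage, including a frame renderer for end-to-end
  tracking tests.

## Worked example

Simulate a chemotactic assay (80 swimmers, 2 min, strong attraction
χ = 200) with its paired control, and run the whole analysis:

```python
from capitax import (AssayConfig, ChemotaxisAssayModel, GradientModel,
                     SwimmerConfig, simulate_assay_pair)

swim = SwimmerConfig(n_cells=80, duration=120.0, dt=1/30.0, chi=200.0, seed=30)
cue, ctl = simulate_assay_pair(swim, GradientModel())
res = ChemotaxisAssayModel(cue, ctl, config=AssayConfig(window_s=30.0, t_min=30.0)).fit()
print(res.summary())
```

```
              Microcapillary chemotaxis assay
============================================================
Tracks (cue/control):   80 / 80
Profile model (in/out): piecewise / piecewise
lambda_in:      900.0 um   (SE 22)
lambda_out:      92.7 um   (SE 1.6)
------------------------------------------------------------
Ic_max inside:    50.08   p = 0.000155
Ic_max outside:   19.97   p = 0.000155
Accumulation rate: 0.1957 +/- 0.0038 cells s^-1
------------------------------------------------------------
Straightness S (median [n]):
  ingoing   0.824  [393]
  outgoing  0.740  [419]
  neutral   0.263  [121]
Chemokinesis speed ratio (near/far): 1.00  (p = 8.44e-13)
============================================================
```

Reading the output: the simulated cells formed a ~93 µm accumulation patch
at the capillary mouth (λ_out) and explored ~900 µm into it (λ_in); cue
counts beat the control by factors of 50 (inside) and 20 (outside), both
passing the significance gate (p ≪ 0.01), and counts inside grew steadily
at ~0.2 cells s⁻¹. Median straightness is higher in the corona than in the
far field — these swimmers turn sharply only very close to the source —
and the near/far speed ratio of 1.00 correctly reports the absence of
chemokinesis (κ = 0 here).

The same pipeline runs from the shell on track CSVs or TIFF stacks:

```bash
capitax simulate --config assay.yaml --out cue.csv --control-out ctl.csv
capitax track    --frames video.tif --out tracks.csv --threshold 20
capitax report   --config assay.yaml --cue-tracks cue.csv \
                 --control-tracks ctl.csv --out report.json
capitax uptake   --table uptake.csv --out fit.json
```

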