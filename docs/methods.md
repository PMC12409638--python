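# Methods

## Scope and data model

The package implements the chemometric layer of a Raman soft sensor for a
dual-stage cross-flow filtration (CFF) step: precipitant (ammonium
sulfate, AMS, mol/L) depletion and product (virus-like particle, VLP, g/L)
accumulation are inferred from on-line spectra recorded in the second
membrane stage.  Spectra live on a fixed instrument grid, 200–3300 cm⁻¹ at
1 cm⁻¹ resolution (3101 channels).  Wavenumber intervals are inclusive of
both endpoints and expressed on that grid.  A `SpectrumSet` holds spectra
on one identical axis (exact value equality; all data originate on a
single grid) plus optional per-spectrum reference concentrations.

## Preprocessing pipelines

Each calibration model owns an ordered recipe (`PipelineConfig`), executed
as: average → normalize → pre-crop → baseline → smooth → crop → scale.

- **Averaging.** Non-overlapping blocks of 50 recordings; a trailing
  partial block is dropped so every averaged spectrum carries the same
  noise level.  On-line blocks use the same size as calibration blocks to
  keep the variance structure matched.
- **Normalization (precipitant pipelines only).** Division by the OH-band
  intensity at 3299 cm⁻¹, by default the mean over the 5-point window
  3297–3301 cm⁻¹ for robustness against single-channel noise (a strict
  single-point mode is selectable).  Because intensity scales linearly
  with exposure time below saturation, normalized spectra from different
  exposure times coincide, which is what makes cross-exposure model
  transfer possible.
- **Pre-cropping (product pipelines only).** Interior removal of the
  dominant sulfate region — 920–1030 cm⁻¹ (P1) or 920–1200 cm⁻¹ (P2) —
  *before* baseline correction.  The pre-cropped vector is spliced (gap
  closed) so the baseline and smoothing filters see one concatenated
  series; per-segment filtering is available (`splice=False`) but not the
  default, because removing the huge interferent band before baseline
  estimation is the point of the step.
- **Baseline.** asPLS (adaptive smoothness penalized least squares): an
  iteratively reweighted Whittaker smoother.  Weights update as
  w = 1/(1+exp(2(r−s)/s)) with r = y−z and s the standard deviation of the
  negative residuals; the roughness penalty is scaled per point by
  α = |r|/max|r|.  Convergence is declared when the relative L2 change of
  the weight vector falls below the tolerance; `max_iter` defaults to 100
  and weights start at 1 (both unreported in typical applications; these
  follow the reference implementation conventions of the algorithm
  family).  Non-convergence is reported, not raised.  Precipitant
  pipelines use λ = 6·10⁷, second-order differences, tol 10⁻³; product
  pipelines λ = 10⁹, tol 10⁻⁴, with second-order (P1) or third-order (P2)
  differences.  The banded normal equations are solved with
  banded factorizations (symmetric positive-definite for the plain
  smoother; general banded for the mildly asymmetric adaptive system) —
  no dense n×n matrix is formed.
- **Smoothing.** Savitzky-Golay, window 11, polynomial order 2.  Edges are
  handled by refitting the edge-window polynomial (no wraparound); edge
  regions are later discarded by cropping anyway.
- **Cropping / scaling.** Models keep 980 cm⁻¹ (linear), 340–2650 cm⁻¹
  (full-spectrum PLS), VIP-derived intervals (refined PLS, scaled to unit
  variance using training statistics only), or the product intervals
  1203–1349 / 1331–1349 cm⁻¹.

## Regression models

- **Linear:** ordinary least squares of concentration on the 980 cm⁻¹
  band intensity.
- **PLS1:** NIPALS with X- and y-deflation; the coefficient vector is
  b = W(PᵀW)⁻¹q.  Component counts beyond min(n−1, p) or the informative
  rank are truncated and flagged rather than raised.
- **Component selection:** a single random 80/20 train/validation split
  (mandatory explicit seed), candidates A = 2…10, parsimony rule: the
  smallest A whose validation RMSE is within 5 % of the minimum (pure
  argmin available by flag).  The parsimony cutoff carries a tiny absolute
  floor (10⁻¹² · max|y|) so the rule stays well defined when every
  candidate fits to numerical precision.  The validation split is at least
  3 samples — for small averaged calibration sets (8–12 spectra) this
  means the split can be effectively 62/38; repeated-split mode (mean RMSE
  over k splits) is available but off by default.
- **VIP selection:** threshold 1.0 (the greater-than-one convention),
  runs separated by ≤ 5 cm⁻¹ merged, merged runs shorter than 5 points
  dropped; all three exposed as parameters.  The refined 2-interval model
  keeps the derived intervals containing the 451 and 1106 cm⁻¹ sulfate
  bands — the bands that stay below detector saturation at the high
  transfer exposure time, which is precisely why this combination survives
  transfer while intervals covering the 980 cm⁻¹ band do not.
- **Metrics:** RMSE and R² about the reference mean; R² is reported as
  missing when the reference has zero variance.  Negative concentration
  predictions are reported as-is (flagged, never truncated): transfer
  diagnostics depend on seeing raw model output.

## Quality control at transfer time

QC runs on raw averaged blocks, before any normalization.

- **Oversaturation.** A band (default 940–1020 cm⁻¹) is flagged when ≥3
  consecutive points lie within 0.5 % of the clip level, or when the band
  shows the split-peak signature (two local maxima with an interior
  minimum deeper than 5 % of the band amplitude).  Spectra whose band
  maximum stays below 90 % of the clip level are never flagged.  The three
  thresholds are heuristics calibrated on the generator (the artifact is
  only ever described qualitatively) and are exposed as parameters.  A
  saturated flag invalidates predictions of exactly those models whose
  retained wavenumbers intersect the saturated interval.
- **Defective spectra.** Robust rolling outlier test on median-normalized
  total intensity: score = |value − rolling median| / rolling MAD, flagged
  above k = 6.  The MAD is floored at 0.5 % of the local intensity level;
  without the floor, near-noiseless averaged series make the MAD collapse
  and smooth process curvature would be flagged.  Detecting a contiguous
  defective block requires a window longer than twice the block; sharp
  monotone transitions (e.g. the final ultrafiltration concentration ramp)
  can still be flagged conservatively — flagged rows are excluded from
  QC-gated metrics, never deleted from the time series.

Flags gate reporting: every prediction row carries its flag, preserving
the complete time series for plotting and diagnosis.

## Synthetic data generator

The generator emulates the statistical structure the pipelines assume; it
is a phenomenological band model, not a physical scattering model.

- **Bands.** Gaussian profiles at standard assignments: sulfate 451, 618,
  980, 1106 cm⁻¹; ammonium 1420; phenylalanine 1004; tyrosine 1206;
  backbone/Tris 1249; backbone+tryptophan 1341; amide I 1660; broad water
  OH envelope centered at 3250 cm⁻¹.  Widths and amplitudes
  (counts · concentration⁻¹ · ms⁻¹) are generator parameters.  The
  980 cm⁻¹ amplitude is fixed by the saturation condition: the band
  reaches the 16-bit full scale (65535 counts) at 0.2 M and 1,250 ms.  The
  protein:sulfate amplitude ratio is ≪ 1, reproducing the sensor's
  sensitivity asymmetry between precipitant and product.
- **Water envelope width.** σ = 650 cm⁻¹, intentionally broad: it stands
  for the composite water/probe background rather than the OH stretch
  alone, and it is chosen so the λ = 6·10⁷ Whittaker baseline can track
  the constant background essentially exactly.  That property is what
  makes the noiseless end-to-end recovery an exact identity (see below);
  with a narrow envelope the asPLS weight pattern couples nonlinearly to
  the analyte concentration through the residual scale.
- **Spectrum model.** I(ν) = t_exp·[Σ c·A·shape(ν) + drift(ν)] + noise,
  noise Gaussian with σ = 0.3 % of full scale per recording (≈√50 smaller
  after block averaging).  Drift is a broad concentration-proportional
  hump plus a buffer-composition ramp, each with a per-spectrum
  multiplicative jitter (SD 10 %) — this, together with per-level mixing
  imprecision (SD 0.02 on the wash/re-dissolution mixing fraction), gives
  the calibration data its second latent variance direction beyond the
  analyte itself.
- **Detector.** Values above the clip level L fold back as L − k(I−L)
  with k = 0.15, floored at 0.8 L and capped at L: a band driven above L
  shows two flank maxima at L and an interior minimum — the split peak.
  Purely phenomenological.
- **Calibration series.** AMS: levels over 0–1.1 M along the buffer
  mixing gradient.  VLP: 0–2.2 g/L dilution series carrying a fixed
  0.05 M residual AMS background.
- **Process simulator.** Stage-1 ideal constant-volume washout
  C₁(v) = c₀e^(−v); stage-2 balance dC₂/dv = ρ(C₁−C₂) integrated
  numerically (ρ = 1 has the closed form c₀·v·e^(−v); in general the peak
  sits at ln ρ/(ρ−1)).  ρ = 0.55 is the default process setting (stage-2
  peak ≈ 0.29 M at 1.33 DV; 980 cm⁻¹ saturated from ≈0.5 to ≈2.9 DV at
  1,250 ms).  Product release is a logistic switch as C₁ falls below a
  re-dissolution threshold (0.4 M, width 0.08 M); released product is
  fully retained in stage 2.  During ultrafiltration the retentate volume
  shrinks 25 → 10 mL, concentrating the product by the volume ratio; the
  freely membrane-permeant precipitant stays at its end-of-diafiltration
  concentration (constant-concentration UF of a permeant solute — no
  buffer inflow, hence no further washout).  Probe fouling adds a protein
  signal growing linearly with DV; injected defective windows add gross
  baseline offsets (~25 % of full scale).

**What the generator does not emulate:** turbidity/Mie scattering of
precipitates, mechanistic fluorescence, wavelength calibration drift,
non-Gaussian detector noise, and real band shapes/amplitude ratios (which
are not recoverable from calibration metrics alone).  Passing tests
therefore demonstrate that the pipeline logic is correct under the stated
noise model, not that the specific error levels would be achieved on any
particular instrument.

## Study conditions used by tests and the acceptance script

12 precipitant levels (0–1.1 M) × 50 recordings at 175 ms for
calibration, the same levels at 110 ms for testing; 8 product levels
(0–2.2 g/L) × 50 recordings at 1,250 ms with an equally sized held-out
test series; the transfer study uses a 7-DV process at 0.1 DV steps with
50 recordings per step at 1,250 ms.  These sizes mirror the calibration
design the pipelines are intended for while keeping a full run on a single
CPU in the order of a minute per study.  The cross-validated component
count is reported as the consensus (mode) over three CV splits: single
3-sample validation splits occasionally prefer a larger A by more than the
parsimony margin, and the consensus is the meaningful summary of the
selection.

## Numerical choices and degenerate inputs

- asPLS declares convergence immediately when the negative-residual scale
  underflows (flat or exactly reproduced input).
- `whittaker_solve` with λ = 0 returns the input (given positive weights);
  all-zero weights raise.
- The λ→∞ limit equals the degree-(d−1) polynomial fit; numerically this
  is only observable while 1 + 16λ stays well inside float64 conditioning,
  which the tests respect by using short grids.
- Zero-variance wavenumbers make scaling fail loudly (listing the
  wavenumbers); zero-variance references make R² missing, not 0/0.
- Pipeline determinism: reruns with identical inputs, configs and seeds
  are bit-identical; manifests record steps, derived intervals, CV tables
  and model hashes.

## Known limitations

- The defect detector is a univariate total-intensity test; defects that
  preserve total intensity (shape-only artifacts) are invisible to it.
- Saturation QC assumes the affected band is known a priori (the
  980 cm⁻¹ sulfate band); it does not scan for arbitrary clipped bands.
- The CLI's semi-continuous mode models sampling windows around integer
  DV points and the UF end; arbitrary sampling schedules require driving
  the library directly.
- Model transfer assumes the process spectra share the calibration grid
  exactly; no wavelength re-interpolation is provided.
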