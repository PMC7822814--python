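# Methods

## Signal model and calibration

A perfluoro-15-crown-5-ether (PFCE) emulsion injected i.v. gives a single
strong ¹⁹F resonance with no biological background.  Under a saturation-
recovery acquisition at repetition times TR, the voxel signal follows

    S(TR) = S0 · (1 − exp(−TR / T1))

with S₀ proportional to local ¹⁹F concentration.  Dissolved oxygen
paramagnetically shortens T₁; for PFCE the relationship between R₁ = 1/T₁
and the oxygen partial pressure is linear, so

    PO2 [mmHg] = 470.81 / T1 [s] − 200.14

with constants from an in vitro calibration at 7 T, taken as fixed inputs
(no temperature or field-strength correction).  The conversion is never
clipped: PO₂ < 0 or > 760 mmHg is physically impossible but can arise from
noise propagation, and such values are retained with a QC flag so that
group statistics see the same data a non-censoring analysis would.

## Preprocessing

Magnitude MRI noise is Rician; at the SNR of T₁-weighted ¹⁹F images
(short-TR SNR ≈ 1–3 in vivo) the naive estimate SIₘ/σ is badly biased.
The chain is, in fixed order:

1. σₘ = sample SD of the magnitude in a signal-free ROI (≥ 10 voxels);
   σ_g = σₘ / √(2 − π/2), inverting the Rayleigh SD.  σ is estimated once
   per session from the longest-TR image and reused across TRs (identical
   receiver settings within a series); a per-TR option exists.
2. Voxel-wise corrected SNR = √(SIₘ² − σ_g²)/σ_g.  Where SIₘ < σ_g the
   radicand is negative and SNR is clamped to 0: those voxels are below
   the noise floor and the later threshold removes them anyway.
3. Cubic-spline interpolation to the anatomical grid.  Both stacks share
   field of view, centre and orientation; slice gaps are carried in the
   affine's slice spacing (thickness + gap), and resampling goes through
   world coordinates.  SNR maps are interpolated up to the anatomical
   resolution; ROI masks are never down-sampled (nearest-neighbour
   transport exists for QC overlays only).
4. In-plane Gaussian smoothing, SD 3 anatomical pixels per slice.  The
   width parameter follows the convention of the interactive tool
   historically used for this step (its blur parameter is the Gaussian
   SD); smoothing is 2-D because slices are thick (2 mm) and gapped; both
   the SD and a 3-D option are config knobs.
5. Exclusion of all voxels with smoothed SNR < 5 on the TR = 5 s image
   from all further analysis (≥ 5 is kept).

## Fitting

Per-placenta mean SNR over (ROI ∩ validity mask) at each TR is fitted by
trust-region least squares with bounds S₀ > 0, T₁ ∈ (0.05, 30] s and
initialisation S₀ = SNR(TR_max), T₁ = 1.5 s; ordinary (unweighted) least
squares by default with an optional per-TR weighting knob.  Fits are
ROI-mean based: voxel-wise PO₂ is dominated by error propagation.  Failures
(all-zero curve, optimizer breakdown) return flagged records, not
exceptions, so one bad placenta cannot abort a study.  A multi-exponential
variant fits Σ_c S₀c(1 − exp(−TR/T₁c)) for compartment models (maternal /
fetal / trophoblast pools, literature volume fractions 64.4/23.7/11.9%);
with only four TRs it is non-identifiable, which its residual-bootstrap CIs
are designed to expose rather than hide.

## Statistics

Placentas are nested in mothers and mothers are the independent unit.
Each outcome (PO₂, T₁, SNR(TR₁..₄), S₀) is modelled independently, with no
cross-outcome multiplicity correction:

* full model — fixed genotype + oxygen + genotype×oxygen; random intercepts
  for mother and placenta-within-mother; REML (statsmodels MixedLM).
* post-hoc model at one oxygen level — fixed genotype, random mother
  intercept.

Terms are tested with Wald F statistics on type-III-style contrasts
(differences of cell means weighted equally over the other factor).
Denominator df use the Satterthwaite approximation, computed from a small
REML engine for this nested covariance structure: the statsmodels estimate
is polished to the exact REML optimum (L-BFGS-B), variance components on
the boundary are dropped from the free parameter set, and the observed
information and contrast-variance gradients are obtained by central finite
differences.  Multi-df contrasts combine per-eigencontrast dfs in the
standard repeated-measures way.  This reproduces R lmerTest's Satterthwaite
genotype test to |Δp| < 5e-4 on simulated studies (cross-checked in the
test suite); a containment (between/within) df is the recorded fallback
when the approximation degenerates.  Degenerate inputs are handled
explicitly: a constant outcome returns a diagnostic rather than a fit, zero
within-group variance returns exact group means, and with one placenta per
mother the model collapses to the two-sample t-test, as it should.

The random-effects structure (mother + placenta-within-mother intercepts)
is the covariance assumption this package makes where the nesting statement
alone does not pin one down; it is recorded in each result's metadata.
Unpaired two-tailed t-tests are available as a supplementary column, never
the primary inference.  α = 0.05 throughout.

## Synthetic phantom

The generator emulates the study conditions: WT 3 mothers/19 placentas, KO
4 mothers/17 placentas (totals split as evenly as possible across mothers;
a per-mother sampling-range mode exists), oxygen conditions 30/60/100% with
baseline PO₂ (100, 150, 250) mmHg and a KO deficit of (−64, 0, 0) mmHg —
the 30%-only deficit matching the published wildtype–knockout gap.  PO₂
heterogeneity is Normal at three levels: mother SD 10 mmHg, placenta SD
20 mmHg, condition residual SD 15 mmHg.  The placenta SD follows the
package's reading of the visible between-placenta spread; the mother and
residual SDs are free choices fixed once at values that give the nested
model realistic variance at every stratum.  True T₁ derives from true PO₂
through the exact calibration inverse.

Geometry copies the acquisition: ¹H 196×256, 20 slices of 1 mm + 0.2 mm
gap; ¹⁹F 64×84, 8 slices of 2 mm + 0.4 mm gap; shared 39.2 × 51.2 mm FOV
and stack centre.  Placentas are non-overlapping ellipsoids (semi-axes
~1.8–2.8 mm, ~20–80 ¹⁹F voxels) rasterized on both grids; the signal-free
noise ROI is a corner box rasterized on both grids as its own label.
Magnitude noise is Rician, |S + n₁ + i·n₂| with n₁, n₂ ~ N(0, σ_g),
σ_g = 1 by default with S₀ ~ U(8, 16) in σ_g units — matching the reported
in vivo SNR regime (TR₁ SNR ≈ 1.3–2.6, TR₄ SNR ≈ 7–15).  An optional
three-pool mixing mode drives the maternal pool at the placenta's true T₁
with fixed fetal/trophoblast T₁s.  Every generator path is deterministic
under the config seed.

What the phantom does **not** emulate: motion, B₀/B₁ inhomogeneity,
chemical-shift or isoflurane artefacts, within-placenta PO₂ texture
(placentas are homogeneous per condition), partial-volume structure beyond
voxel-centre rasterization, and k-space acquisition.  Passing tests on
phantoms therefore validate the estimation chain, not robustness to those
real-data effects.

## Known limitations

* **Noise-floor PO₂ bias.**  With noise off, the complete chain recovers
  PO₂ exactly (verified in the test suite): geometry, interpolation,
  smoothing and thresholding introduce no systematic error, because ROI
  edge dilution is multiplicative and cancels in the T₁ ratio.  With
  realistic noise, the corrected SNR of pure-background voxels retains a
  residual Rayleigh "haze" (mean ≈ 0.76 SNR units at every TR); smoothing
  mixes it into ROI edges, raising short-TR SNR relative to long-TR and
  biasing T₁ down / PO₂ up.  At the default study conditions this inflates
  condition-mean PO₂ by roughly +15–20 mmHg (reported by the acceptance
  script as `endtoend_mean_po2_bias_mmhg`).  This is a property of the
  published estimator at in-vivo SNR — consistent with error propagation
  producing physically impossible PO₂ values in real data — not of this
  implementation.
* **Few TRs.**  Four TRs barely constrain a 2-parameter fit when T₁
  approaches the longest TR; T₁ ≫ 5 s fits are ill-conditioned (tested).
* **Denominator df** are an approximation; estimated marginal means,
  effect directions and significance are the replication surface, not
  exact df values.
* Real-data mode expects NIfTI-converted volumes and a study YAML; raw
  scanner-format conversion and ¹H↔¹⁹F registration are out of scope (the
  acquisition prescribes identical stack geometry).

## Problem sizes

Monte-Carlo checks use 500 null replicates for test calibration, 200
replicates for power, 200 simulated curves for fit recovery, 1e5 voxels
per SNR level for noise-correction bias, and one full default study
(21 sessions, 108 records) for the end-to-end run — sizes at which each
quantity's Monte-Carlo error is well inside the decision margins.
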