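# Methods

`flowmet` implements a multiparametric early-response analysis for
tumors imaged with dynamic contrast-enhanced CT and static FDG-PET,
with CD31 histology as the microvascular reference: perfusion kinetics
(BF, BV, PS), SUV volumetrics (SUVmax, SUVmean, TV, TLG), local GLCM
texture (entropy, homogeneity), the flow-metabolic ratio
FMR = BF/SUVmax, and hot-spot microvessel density (MVD). Because no
image data of this kind are publicly deposited, every stage is
validated by parameter recovery on synthetic phantoms whose ground
truth is known exactly; this note records the models, the defaults and
why, and what the phantom does and does not establish about real data.

## Forward tissue model

A tissue voxel's enhancement is modeled as intravascular transit plus
unidirectional leakage:

    C_t(t) = f * ∫_{t−MTT}^{t} C_a(τ) dτ  +  k * ∫_0^t C_a(τ) dτ

with `f = BF/6000` and `k = PS/6000` in 1/s (BF and PS quoted per
100 mL per minute), and a boxcar vascular residue of width MTT. The
model ties `BV = BF·MTT/60`; when a parameter set specifies both BF
and BV, MTT is derived from them (giving transit times of roughly
27–47 s for the reference values — long, because these hypervascular
tumors carry large vascular fractions), and `MTT = 8 s` is the
fallback when only BF is given.

This model was chosen because both estimators in the analysis chain
are *exact* on it in their validity regimes, which makes recovery
tests sharp rather than approximate:

* for `PS = 0` and an arterial peak arriving within one transit time
  of onset, the peak tissue slope is exactly `f · max(C_a)`, so the
  maximum slope method returns BF;
* once the arterial input has equilibrated at a plateau and `t − MTT`
  has cleared the bolus, the Patlak plot is exactly linear with slope
  `k` and intercept `BV/100`.

Known caveat (by construction): with `PS > 0` the early tissue slope
is `(f + k)·C_a`, so maximum-slope BF is biased upward by up to
`PS/BF` relative. This is a property of the unidirectional-leakage
model, not an implementation defect; BF recovery is therefore asserted
at `PS = 0`, and reported BF values on leaky phantoms carry that bias.

## Arterial input

The AIF is a normalized gamma-variate bolus plus an equilibrium
component:

    C_a(t) = A · (u/α)^α · e^{α−u} + r·A·(1 − e^{−(t−t0)/αβ}),
    u = (t − t0)/β

so the bolus peak is exactly `A` and the curve settles at a plateau of
`r·A` (the blood-pool steady state after the injected contrast has
mixed). The plateau — rather than a decaying recirculation copy — is
what makes the Patlak intercept identity above hold: with a decaying
input the intravascular term `f·∫_{t−MTT}^t C_a / C_a(t)` diverges
from `BV/100` by the factor by which the input decays over one transit
time, which for transit times of ~40 s would be large.

Defaults: `A = 200` HU, onset `t0 = 6` s, shape `α = 3`, scale
`β = 2.5` s, plateau fraction `r = 0.35`, blood baseline 40 HU. The
amplitude keeps the aortic raw peak (~284 HU) inside the vendor-style
arterial acceptance window [0, 300] HU. The shape/scale pair was fixed
once by a joint calibration on the 40-frame schedule: a sharper bolus
sharpens the Patlak window but makes the 1.5-s frame spacing
undersample the peak slope (biasing maximum-slope BF low), while a
broader bolus does the opposite. At these defaults, noiseless
whole-VOI recovery achieves BF within 2% at `PS = 0` and BV/PS within
1% across all reference parameter cells, which are the tolerances the
test suite asserts.

## Acquisition protocol

The dynamic schedule is 40 frames — 20 at 1.5 s, 10 at 3 s, 10 at
6 s — with the first frame 2 s after injection. Total duration is
defined as Σ count·interval = 120 s, the conventional quote for such
protocols; note the last frame then lands at 120.5 s because the first
frame sits at the 2-s offset. Contrast is a dual-phase injection (3 mL
at 0.5 mL/s, 3.5 mL at 0.1 mL/s; 1.5 mL saline flush), total contrast
6.5 mL, recorded as protocol metadata.

## Perfusion estimation

Analysis is *curve-first*: the VOI-mean raw curve is baseline-corrected
(mean of the first 3 frames, all pre-onset) and both estimators run on
that single curve. This matches reporting of whole-tumor averages and
is far more noise-robust than averaging voxel-wise maps; a voxel-wise
map mode exists (`parameter_maps`) but is not the default.

* VOI refinement keeps drawn voxels with baseline HU in the closed
  interval [−50, 150]; arterial candidates are kept when their peak
  raw HU lies in the window center ± width/2 (default [0, 300] HU).
  The vendor-style "relative threshold inside/outside" percentages are
  accepted for interface parity but are inert — their semantics are
  not recoverable from any public description.
* Maximum slope: sliding 3-frame least-squares slopes (robust to
  single-frame noise; window configurable), divided by the AIF peak,
  × 6000.
* Patlak: OLS of `y = C_t/C_a` on `x = ∫C_a/C_a` (trapezoid on the
  frame grid) over frames at or after the window start. `patlak_fit`
  defaults its window to the AIF peak time — the textbook choice —
  but the VOI/cohort pipeline passes `78 s` (well inside the final
  6-s phase): with vascular transit times of 27–47 s implied by the
  reference BF/BV values, the plot is not yet linear at the arterial
  peak, and fitting from the peak would corrupt both slope and
  intercept. 78 s leaves 8 frames, enough for a stable line whose
  R² ≈ 1 diagnostic is reported. Negative fitted BV/PS are clamped to
  zero and flagged rather than returned negative.

## PET, texture, FMR

SUV is body-weight normalized with unit tissue density; no decay
correction beyond what the activity map encodes. TV is voxel count ×
voxel volume (cm³); TLG = TV·SUVmean is stored as a derived property
so the identity is exact for every record. Texture quantizes the
masked SUV range onto 128 levels via min-max resampling onto the
integer band {128, …, 255} (floor, top value clipped); the band's
constant offset is immaterial because both indices depend only on
level differences. The GLCM accumulates ordered pairs over the 13
unique 3D nearest-neighbor directions (voxel units, distance 1, both
voxels in-mask), symmetrizes, and normalizes once; a per-direction
average mode is provided. Entropy uses log₂ (bits). A flat VOI maps to
one level: entropy 0, homogeneity 1, no division by zero.

FMR is computed per tumor from that tumor's BF and SUVmax; cohort
means are means of per-tumor ratios, never ratios of means.

## Histology

Sections are binary CD31 masks. The section is tiled into
non-overlapping high-power fields (field size is a required
parameter — it depends on optics); candidate fields are ranked by
stained-area fraction on a 5× downsampled rendering (emulating
hot-spot selection at low magnification), ties broken in raster order;
the top 4 are counted at full resolution as 8-connected components
with ≥ 5 pixels (small floor: any clearly separate stained cluster
counts). MVD is the mean of the four counts, hence quarter-granular.

## Phantoms and cohort simulation

* Dynamic CT: ellipsoidal tumor in a uniform 40-HU background on a
  12×20×20 grid of 2-mm voxels; each tumor voxel carries the forward
  model curve for its kinetic parameters (optionally two equal-volume
  kinetic slabs); a 2×2 voxel aortic column carries the raw arterial
  curve; optional i.i.d. Gaussian HU noise, seeded.
* PET: same grid; a smooth radial profile plus seeded Gaussian
  heterogeneity, affinely rescaled so the masked max and mean hit the
  SUVmax/SUVmean targets to float precision; background ≈ 0.2 SUV.
* Histology: per-field planted non-overlapping disks (radius 3–5 px);
  the generator verifies that designated hot-spot fields are strictly
  denser than every background field and errors otherwise.
* Cohort: two arms × 6 rabbits × 2 tumors × days {0, 3, 7, 14} by
  default. Per tumor-day, ground truth is drawn from the embedded
  reference table of group/day means and SDs (truncated normals:
  BF, BV ≥ 1, PS ≥ 0, SUV ≥ 0.1; tumor volume in [0.05, 3] cm³, the
  upper bound keeping the sphere inside the grid); `fixed` mode pins
  every tumor at its cell mean. The tumor sphere is sized so its
  analytic volume equals the drawn volume (voxelization makes the
  *measured* TV approximate at 2-mm spacing).

Problem sizes throughout (grid, dense 0.02-s AIF sampling, cohort
sizes, 100 trend replicates, 20-seed texture ladders) were chosen as
the smallest at which the discretization effects under test are
negligible relative to the asserted tolerances.

What the phantom does **not** emulate: scanner physics (beam
hardening, partial volume), respiratory motion, PET reconstruction
and attenuation, venous outflow or backflux, stain chemistry. Passing
recovery tests therefore demonstrates correctness of the estimators on
data satisfying their model assumptions — not robustness to the
physics the phantom omits.

## Numerical and statistical choices

* Integrals: cumulative trapezoid (dense grid ≤ 0.1 s for simulation;
  the estimator uses the coarse frame grid, as a real analysis must).
* Group summaries: sample SD (n−1); single-record cells report SD 0
  with n = 1; empty cells are missing values, not errors.
* Group contrasts: the repeated-measures mixed-effect analysis of the
  original study design is out of scope; a rabbit-level permutation
  test substitutes for it, permuting whole rabbits so both tumors of
  an animal travel together (exact enumeration when the assignment
  space is small, otherwise seeded Monte Carlo with the +1
  correction).
* Correlations: Pearson or Spearman (average ranks on ties), refusing
  zero-variance input.
* Entropy saturation: a GLCM built from N in-mask pairs cannot exceed
  log₂(2N) bits, so small phantoms saturate entropy well below the
  128-level ceiling; the monotone heterogeneity-response test runs on
  a pre-saturation amplitude ladder (0–0.02).

## Known limitations

* Maximum-slope BF inherits the `(f+k)/f` upward bias on leaky tissue
  (see above).
* The equilibrium-window Patlak default (78 s) assumes the 120-s
  protocol; other schedules need an explicit `patlak_window_start`.
* Measured TV on the 2-mm grid carries voxelization error of order
  10–20% for sub-cm³ tumors; SUV statistics are unaffected (targets
  are enforced on the voxelized mask).
* The cohort simulator draws parameters independently per tumor-day;
  it does not model within-rabbit correlation or longitudinal
  autocorrelation, so the permutation test's clustering robustness is
  exercised structurally, not distributionally.
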