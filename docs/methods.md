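# Methods

## The strain model

The Bone Strain Index treats each lumbar vertebral body in a DXA scan as a
2D linear-elastic problem.  The assumptions, in decreasing order of
physical weight:

* **Plane stress, uniform thickness.**  Areal BMD carries no depth
  information, so the vertebra is modelled as a thin slab of uniform
  anteroposterior thickness (default 30 mm, a vertebral-body depth
  surrogate).  The thickness only rescales all strains by a constant, so it
  does not affect relative comparisons; it matters only through the BSI
  scale factor (below).
* **Constant-strain triangles.**  The mesh uses 3-node linear elements —
  the minimal element consistent with "small triangular elements".  The
  element stiffness is `k_e = t · A · Bᵀ D B` with the plane-stress
  elasticity matrix D.
* **Density–modulus power law.**  `E = max(floor, E_ref (BMD/BMD_ref)^γ)`
  with defaults E_ref = 8000 MPa at 1 g/cm², γ = 2, ν = 0.3,
  floor = 10 MPa.  Density-modulus exponents near 2 are typical for
  trabecular bone; since the commercial mapping is unpublished, the whole
  law is configurable and these defaults are stated assumptions rather than
  a reproduction of any specific calibration.  The floor keeps near-void
  partial-volume elements positive definite.
* **Boundary conditions.**  The patient-specific compressive load acts as a
  uniform *vertical pressure* over the upper band of the boundary
  (band fraction 0.08 of the vertical extent): every boundary edge
  contributes the sub-segment inside the band, weighted by its horizontal
  projection and lumped consistently onto the edge nodes.  The projection
  weighting is what makes a uniform uniaxial state exactly representable
  (the patch test) and makes the applied load independent of the mesh; the
  band, rather than a node set, keeps the loaded geometry identical across
  refinements.  The lower band is fixed in both components by default; a
  frictionless "roller" variant (vertical support plus one lateral anchor)
  is available and is what the patch test uses.
* **Equivalent strain.**  The per-element scalar is the von Mises
  equivalent strain of the full 3D tensor implied by plane stress
  (ε_zz = −ν/(1−ν)(ε_xx+ε_yy)).  The commercial score's strain scalar is
  unpublished; a mean-type scalar is chosen over a peak because the score
  is then linear in the load and robust to mesh density.

### Load model

`F = a_level · W · g · m_level · (h/170 cm)`, with trunk-mass fractions
a = 0.45/0.47/0.50/0.53 for L1–L4 and lever multiplier m = 1.3.  This
coefficient table is a documented stand-in with the right structure
(caudally increasing load, linear in weight, height-adjusted): the original
regression equations are not printed in the sources available here, so the
table is fully overridable via JSON (`--load-table`).  For a 70 kg, 170 cm
patient it yields 402–473 N across L1–L4.

### Meshing

Segmentation is marching-squares iso-contouring of the BMD field at
0.30 g/cm² (configurable).  Meshing is a constrained Delaunay triangulation
with Ruppert-style refinement built on incremental re-triangulation: the
contour is first coarsened by Douglas–Peucker at a tolerance that keeps the
polygon area within 0.1%, chords are split to the target edge length
(default 3 × pixel spacing), the interior is pre-seeded with a hexagonal
lattice, and then encroached boundary chords are split at their midpoints
and circumcenters of the worst remaining triangle are inserted one at a
time until every triangle has minimum angle ≥ 20° and longest edge ≤ 1.5 ×
target.  Because all boundary chords are preserved, the summed element area
equals the polygon area to machine precision.

Element BMD is the mean of the bilinearly interpolated field over the
element, estimated with an equal-weight midpoint rule over k² congruent
subtriangles, k chosen per element so subcells are at most one pixel
(single-centroid sampling for sub-pixel elements).  Sampling at
pixel resolution regardless of element size is what makes the material
field — and hence the mean equivalent strain — stable under mesh
refinement (measured change 0.35% when the default edge length is halved).

### Score scale

`BSI = k_BSI × (area-weighted mean ε_eq)` per vertebra; the lumbar score is
the area-weighted mean over vertebrae, mirroring how lumbar BMD aggregates
L1–L4.  The absolute scale of the commercial score is unpublished, so
k_BSI was calibrated **once** on the default phantom population (100
subjects, seed 1234): the population mean equivalent strain of 7.7 × 10⁻⁵
is mapped to the reported lumbar mean score of ≈ 5, giving
k_BSI = 65 000.  With this scale the population summary is
5.0 ± 1.4 (range ≈ 2.7–9.1), matching the reported 5.0–5.3 ± 1.3–1.4
(range 2.46–9.44).  k_BSI is a pure display scale: every comparison the
package makes (linearity, monotonicity, hazard modelling) is invariant
to it.

## The synthetic data

**Images.**  Vertebral bodies are superellipses of exponent 4
(34 × 26 mm, realistically flat endplates) stacked with 6 mm disc gaps at
1 mm pixel spacing; pixel values are base BMD (default 0.76 g/cm²) plus an
optional caudal gradient and Gaussian noise (default SD 0.02 g/cm²), with
4 × 4 supersampled partial-volume edges so iso-contour segmentation
recovers the analytic outline (area error ≲ 2%).  Optional features: an
elliptical low-BMD lesion (for strain-concentration tests) and wedge /
biconcave / crush height deformities (for SDI grading).  What the phantom
does **not** emulate: trabecular texture, cortical shells, projection
overlap of posterior elements, scanner-specific noise spectra, or real
vertebral shape variation.  Tests passing on phantoms therefore validate
the numerics and the pipeline's contracts, not clinical accuracy.

**Phantom population.**  Between-subject variation enters through the
scan-mean BMD (0.76 ± 0.09 g/cm², truncated at 0.35) and sex-specific
weight/stature (85% female).  The BMD spread is deliberately narrower than
the reported cohort SD of 0.15: under the γ = 2 modulus law, image BMD
drives strain roughly as BMD⁻², and the observed score dispersion also
absorbs geometric and microstructural variation the phantom does not model.
With the reported BMD SD the synthetic score range would be implausibly
wide; with 0.09 the resulting score coefficient of variation (≈ 0.27)
matches the reported one.

**Cohorts.**  Baseline covariates (BSI, BMD, TBS) are multivariate normal —
truncated to positive values — with the pooled reported means and SDs and a
mild dependence structure (BSI–BMD −0.4, BSI–TBS −0.2, BMD–TBS +0.3).
Event times are exponential with hazard `h₀ · exp(Σ βᵢ(xᵢ − μᵢ))`
(covariates centred so h₀ keeps its marginal meaning); censoring is
administrative, uniform over the reported follow-up window 320–3214 days.
The default h₀ = 3.3698 × 10⁻⁴ /day was calibrated by root-finding on the
closed-form expected event fraction so that a null-effect cohort of 143
yields 61 expected events, the observed refracture count.  Default
covariate effects are null; parameter-recovery tests switch on
β_BSI = ln 1.35.  The real study's censoring mechanism and
covariate-outcome structure are unknown; the generator's role is
calibration and contract testing, not emulation of the clinical result.

## Statistical choices

* **Cox ties:** Breslow by default (the default of the mainframe software
  generation the analysis tradition comes from); Efron available.  Both
  coincide without ties — asserted to 10⁻⁶.
* **Convergence:** Newton–Raphson with step-halving; relative log-partial-
  likelihood change < 10⁻⁹; coefficients beyond |β| > 50 on centred
  covariates flag a monotone likelihood (separation).
* **KM confidence intervals:** linear Greenwood, clipped to [0, 1] —
  this is the convention that produces printed upper bounds of exactly
  1.000.  Log-log intervals are not the default but trivially derivable
  from the stored standard errors.
* **Reliability flag:** estimates computed when fewer than 20% of the
  starting sample remain at risk are marked unreliable and shaded in the
  plot.
* **Proportionality test:** Grambsch–Therneau, correlating scaled
  Schoenfeld residuals with the **rank** of event time by default.  With
  the identity transform the chi-square approximation is measurably
  conservative for skewed event-time distributions (null p-value mean 0.54
  in 1000-replicate simulations); the rank transform is well calibrated
  (KS uniformity p ≈ 0.65) and is also the default in current survival
  software.  Identity and log transforms remain available.
* **Power:** Schoenfeld's formula `Φ(√(D σ² ln²HR) − z_{1−α/2})` — the
  number of *events* D, not the sample size, carries the information.  The
  covariate SD must be supplied explicitly; the headline computation uses
  the pooled baseline BSI SD of 1.35.
* **LSC:** 2.77 × precision error (95%, two-visit convention); linear, so a
  precision error three times larger yields an LSC three times larger.

## Numerical notes and degenerate inputs

* The reduced stiffness system is symmetric positive definite and solved
  directly; the residual must satisfy ‖Ku − f‖ ≤ 10⁻⁸‖f‖ or a solver error
  naming a probable rigid-body mode is raised.
* Zero load returns exactly zero displacement; rigid translations produce
  zero strain to machine precision.
* Degenerate ROIs (self-intersecting or near-zero area) are rejected before
  meshing; collinear slivers from the Delaunay kernel are filtered by a
  relative area threshold.
* Grade thresholds in SDI grading carry a 10⁻⁹ tolerance so height ratios
  that are exact in decimal land on their intended grade.
* A uniform strain field renders as the midpoint colour of the
  blue–green–yellow–red ramp; rendering is byte-deterministic for identical
  inputs.

## Problem sizes used in the test suite

Default phantom meshes have ≈ 230 elements per vertebra (3 mm target edge);
refinement tests run one halving step (≈ 870 elements).  Calibration checks
use 60–100 phantom subjects; parameter recovery uses 20 cohorts of
n = 5000; proportionality-test calibration uses 1000 cohorts of n = 300.
These sizes give Monte-Carlo error comfortably below the tested tolerances
while keeping the full suite under a minute on one core.

## Known limitations

* 2D plane stress cannot capture endplate curvature effects, posterior
  element load sharing, or out-of-plane buckling; the score is a projected-
  geometry surrogate.
* The partial-volume rim (one pixel of blended BMD at the contour) forms a
  thin soft layer; its local strains sharpen under aggressive refinement
  even though its area contribution vanishes.  At the default and one
  halving the mean score is stable to < 1%; far finer meshes shift the mean
  by a few percent and would need an explicit rim-exclusion rule.
* Fidelity targets are the published *descriptive* statistics; the
  commercial score for a given scan is not reproduced and the clinical
  hazard ratios are not re-estimable from synthetic data.
* The refracture event uses the visit date of first SDI worsening;
  interval-censoring of the true fracture onset is ignored, as in the
  clinical convention it mirrors.
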