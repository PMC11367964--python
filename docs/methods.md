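# Methods

`replanar` is a synthetic verification pipeline for a clinical question in
nuclear cardiology: can a *reprojected* planar image — synthesized from a
SPECT reconstruction and its CT-derived attenuation map — replace the
conventional anterior planar acquisition when grading myocardial uptake of
bone-seeking tracers in transthyretin (ATTR) cardiac amyloidosis?
Ring-configured CZT SPECT systems cannot acquire planar scintigraphy at
all, so the reprojection operator is what makes the established planar
reading criteria (Perugini-style visual grades, the heart-to-contralateral
ratio with its 1.5 cutoff) usable on such systems.  Patient data for this
question are not public; the package therefore verifies the *computational
chain* on digital phantoms with known ground truth.

## Digital thorax phantoms

Each subject is an analytic phantom on an isotropic voxel grid (default
64³ at 4.92 mm, a ~315-mm field matching a 128³ grid of 2.46-mm voxels
coarsened twofold; 2.46 mm is the clinical reconstruction voxel).  Organs
are axis-aligned ellipsoids and elliptic cylinders painted in a fixed
precedence order (body < lungs < spine < sternum < ribs < kidneys < blood
pool < myocardial shell).  Activity concentrations are arbitrary units;
attenuation values at 140 keV are 0.0154/mm (soft tissue/water), 0.004/mm
(inflated lung) and 0.025/mm (a mixed trabecular/cortical bone surrogate —
pure cortical bone would be ≈0.030/mm; ribs and vertebrae are a mixture).

The clinically meaningful dial is the myocardial-to-rib concentration
ratio, mapped to Perugini-like classes: 0 ⇔ ratio 0; 1 ⇔ ratio < 0.8;
2 ⇔ 0.8–1.3; 3 ⇔ ratio > 1.3, with class-3 phantoms painted with rib
uptake halved (strong myocardial uptake with mild rib uptake).  Cohort
generation samples ratios uniformly inside per-class bands (class 1:
0.3–0.7; class 2: 0.85–1.25; class 3: 1.5–2.5) and applies anatomical
jitter (heart translation ±10 mm, size ±10%) from per-subject seeds all
derived from one master seed.  The default cohort is 30 subjects with
class mix {0: 10, 1: 5, 2: 5, 3: 10}.

What the generator does *not* emulate: realistic voxel anatomy
(XCAT-style), respiratory/cardiac motion, scatter and septal penetration,
energy spectra, or renal clearance kinetics.  Passing tests therefore
demonstrate the correctness and internal consistency of the computational
chain under Poisson statistics and attenuation — not the perceptual image
quality questions that require human readers and real anatomy.

## Forward models

The anterior planar model assigns pixel (z, x) the value
`sensitivity · Δ · Σ_y a(z,y,x) · exp(−Δ·(Σ_{y'<y} μ(z,y',x) + μ(z,y,x)/2))`,
i.e. each voxel's activity weighted by the photon survival probability
along the −y ray to the anterior grid face.  The half-step self term is a
midpoint rule: second-order accurate and symmetric.  An optional Gaussian
PSF with FWHM = 4 mm + 0.04·(distance) approximates a low-energy
high-resolution collimator; it is applied per depth slab before the y
summation.  Poisson noise replaces each pixel by a seeded draw with the
noiseless mean.

SPECT is a parallel-beam abstraction of a ring acquisition: N evenly
spaced azimuths (default 60 over 360°), each obtained by rotating the
volume about z and applying the same attenuated slab kernel.  The axial
rotation is implemented as a cached sparse matrix of bilinear
interpolation weights, so its exact adjoint is the transpose; projector
and back-projector are a truly matched pair (`⟨Px, y⟩ = ⟨x, Pᵀy⟩` to
rounding error), the property EM-type algorithms assume.  Simulation and
reconstruction share this one system model.

CT numbers convert to 140-keV attenuation by the standard bilinear rule:
`μ = μ_water(1 + HU/1000)` for HU ≤ 0 and `μ = μ_water + k_bone·HU`
above, with `k_bone` defaulting so +1000 HU maps to the bone surrogate.

## Reconstruction

MLEM is the classic multiplicative EM update; OSEM cycles it over
interleaved angle subsets (subset k takes every n-th angle).  BSREM
performs the relaxed additive block update

    f ← max(f + α_n · (f / s_b) · [Pᵀ_b(y_b / P_b f) − s_b − (β/B)∇U(f)], ε)

with subset sensitivity `s_b = Pᵀ_b(1)`, relaxation `α_n = α₀/(1+λn)`
(defaults α₀ = 1, λ = 0: constant unit relaxation, under which the β = 0
update reduces *algebraically* to OSEM — the suite checks the two
independent code paths agree iterate-for-iterate), and the relative
difference prior over unordered 6-neighbour pairs with unit weights

    U(f) = Σ (f_j − f_k)² / (f_j + f_k + γ|f_j − f_k| + ε).

The study reconstruction freezes β = 0.4 and γ = 4 (the regularization
choice applied to all subjects), with 20 iterations × 6 subsets as the
package's default problem size.  The vendor's adaptive-beta scheme is
proprietary and is replaced by the fixed scalar β; the clinical
optimization that motivated these values found identical visual scoring
for β anywhere in 0.2–0.8, so nothing downstream hinges on the exact
value.  Scatter correction is not modelled; "resolution recovery"
corresponds to enabling the depth-dependent PSF inside the system model.

Numerical guards: ratios y/ŷ are zeroed where ŷ = 0 (a voxel with positive
activity always projects positively through the strictly positive survival
factors, so the EM fixed point at the truth is exact); subsetized updates
are floored at ε = 1e−12; MLEM applies no floor so that exact zeros are
preserved.

## Reprojection

The central operator: pixel (z, x) = `scale · Δ · Σ_y f(z,y,x) ·
exp(−line integral of μ to the anterior face)` applied to the
*reconstructed* volume.  "Edge of the object" is the anterior grid face —
equivalent for any object surrounded by air (μ ≈ 0) and unambiguous.  The
output stays on the reconstruction pixel grid (no resampling; the H/CL
step works in metric units) and no PSF is applied at reprojection time.
With the true activity substituted for the reconstruction this operator
is *identical* to the noiseless conventional forward model — the suite
asserts pixel-for-pixel equality, which anchors the whole comparison.

## H/CL quantification

A 70-mm-diameter circular ROI is placed over the heart — automatically, at
the pixel-centre position maximizing mean counts among discs fully inside
the patient-left half (ties break to smallest z then smallest x); a
`center` override mirrors the manual clinical workflow.  The contralateral
ROI is the mirror image across the mid-sagittal line (configurable for
off-centre patients); if mirroring would leave the image the ROI shifts
minimally inward and is flagged.  Pixel membership is
centre-inside-circle, no partial-area weighting.  H/CL = heart mean counts
per pixel / contralateral mean; ratio ≥ 1.5 (boundary inclusive) reads
positive.

## Agreement statistics

Percent agreement (reported rounded to the nearest integer, half up),
Cohen's kappa with expected agreement from marginal products, Fleiss's
kappa in the standard per-subject/per-category formulation, least-squares
regression with Pearson r and the t-based two-sided p-value, and
Bland–Altman bias ± 1.96·SD limits (differences are reprojected −
conventional).  Confidence intervals use a seeded percentile bootstrap
over subjects (2000 resamples) for both kappa flavours — uniform and
honest at n = 30, where large-sample formulas are shaky; the percentile
interval is widened, if degenerate resampling requires it, to contain the
point estimate.  Degenerate marginals (both raters constant and equal)
define kappa as 1 with a warning.  Weighted kappa variants are
deliberately out of scope.

Simulated readers replace human scoring: each reader/modality reports the
true class independently perturbed by ±1 with probability p (default
0.05), clipped to 0–3.  This models inter-reader noise only — not the
systematic reprojected-image quality shift real readers perceive.

## Study runner and problem sizes

`run_study` chains phantom → calibrated noisy planar + SPECT → BSREM-RDP →
reprojection → H/CL both pathways → pooled statistics, all seeded from one
master seed via named seed-sequence derivations; a rerun with the same
config is bit-identical.  Count levels are calibrated per subject so the
conventional planar image totals 2×10⁶ expected counts and the SPECT
acquisition the same total across all angles — a deliberate scale-down
from a clinical 8-min, ~590-MBq acquisition chosen for desk-scale noise
realism (relative Poisson noise at this level leaves H/CL ratios stable to
a few parts in a thousand).  The default study (30 subjects, 64³ grid,
60 angles, 20×6 BSREM updates) runs in minutes on one CPU; tests use 16³
grids and 12 angles where full scale adds nothing.

## Known limitations

- The parallel-beam, PSF-optional system model is shared between
  simulation and reconstruction; there is no model mismatch, so the
  pipeline quantifies chain consistency, not robustness to an imperfect
  system model.
- No scatter; CZT spectral tailing and scatter-correction residuals —
  a suspected source of the clinically observed high-ratio bias — are
  outside the model.
- Analytic organs make ROI placement easier than in dressed clinical
  images; the automatic placement is a stand-in for expert placement,
  not a validated detection algorithm.
- Bootstrap CIs are percentile-type; they are reported for completeness,
  not compared against any external reference.
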