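# Methods

## Spatial model

All computation happens on a single regular voxel lattice: the absorbed
dose (Gy) as a float field, anatomy as boolean masks.  Axis convention is
(x, y, z) = (left→right, posterior→anterior, inferior→superior) with
voxel-centre origins.  Masks must be pre-resampled to the dose lattice —
mixing lattices raises a `GeometryError` rather than resampling silently,
because contouring is assumed to have been done on the dose grid itself.
No sub-voxel partial-volume weighting of contours is applied.  On disk,
grids and masks are NIfTI-1 volumes; a JSON sidecar manifest groups one
case's structures.  Normal liver tissue (NLT) is liver minus the union of
all segmented lesions, regardless of boost eligibility.

## Dose metrics

Scalar metrics are voxel-exact; the binned DVH (default width 0.1 Gy) is
for reporting only.  Conventions that matter:

* **Dxx quantile** — with N voxels, D(f) is the ⌈f·N⌉-th largest voxel
  dose, so at least a fraction f of the volume provably receives ≥ D(f);
  D(1.0) is the minimum voxel dose.
* **Cold volume CVx** — strict inequality (dose < x), in absolute cc.
* **Recovery coefficients** — partial-volume correction divides a
  PET-measured lesion *mean* dose by a volume-interpolated coefficient
  (piecewise linear, clamped at the table ends).  The shipped 4-point
  default is a plausible sphere-phantom shape, configurable and not
  clinically calibrated; D90 is never corrected, since the correction is
  only meaningful for means.

## Response and selection models

Lesion response (complete/partial by mRECIST) versus a SIRT dose metric is
logistic.  The clinical models are known only through their 50%-TCP doses,
so the package ships threshold-calibrated stubs — `from_threshold(d50,
slope)` with `tcp(d50) = 0.5` exactly — and the selection pipeline consumes
the thresholds, not the curve shapes: 292 Gy corrected mean dose at the
lesion stage, 70 Gy uncorrected D90 at the voxel stage.  Boundary
semantics: a lesion at exactly 292 Gy is excluded (predicted responder);
voxels at exactly 70 Gy are excluded from the boost subvolume.  Lesions of
2 cc or less are non-evaluable (PET resolution floor).  Boost subvolumes
get no connectivity or minimum-size filter; disconnected components travel
as one target.

`fit_logit` is Newton scoring (IRLS) to the Bernoulli likelihood,
converged when the largest coefficient step < 1e-8, capped at 100
iterations.  Univariate complete separation is detected exactly (class
dose ranges do not overlap) and flagged; the optional Firth penalty
(Jeffreys prior, off by default) yields finite estimates under separation.
The delta method on the observed information gives a standard error for
the fitted 50%-TCP dose.

## PTV expansion

Margins are anisotropic and per-direction: (left, right, anterior,
posterior, superior, inferior) = (5, 5, 5, 5, 8, 8) mm by default.  A
voxel joins the PTV iff its displacement from some target voxel satisfies
the scaled-ellipsoid rule Σ(Δ/m_signed)² ≤ 1, with the margin chosen per
displacement sign — Euclidean margin semantics rather than box dilation,
implemented as binary dilation with a precomputed offset footprint and
verified against an exhaustive neighbourhood scan.  Expansion clips at the
grid boundary only; no clipping to the body or liver surface, and no
ITV/motion margin.

## NTCP

gEUD uses exponent a = 1/n over fractional volumes; zero-dose voxels
inside the mask contribute zero.  The Lyman probit is evaluated through
the exact error function.  Physical dose only: no EQD2/BED conversion and
no combination of SIRT and SBRT dose, because no validated complication
model exists for the combination.  Consequently clinical NTCP values
computed by treatment-planning systems with additional (unstated)
conventions are not reproducible from these parameters plus physical mean
dose, and the package treats NTCP as a property-checked model (midpoint at
TD₅₀, monotone in dose, permutation-invariant), not a numeric target.

## Synthetic cases

The phantom generator emulates the inputs the pipeline normally receives
from PET/CT dosimetry and a treatment-planning system:

* **Geometry** — ellipsoidal liver, spherical lesion GTVs; default lattice
  2 mm isotropic.  Default liver semi-axes (80, 60, 55) mm give ≈ 1.1 l.
* **SIRT dose** — intra-lesion dose is log-normal with log-sd σ (default
  0.8, emulating the large heterogeneity of microsphere deposition in
  underdosed lesions), realized as a spatially correlated log-Gaussian
  field: white noise smoothed at the PET-resolution surrogate scale
  (default 4 mm) and renormalized to unit variance before exponentiation.
  The blur thus sets the spatial texture without shrinking the dose
  spread, keeping mean and D90 controllable; a post-hoc convolution of the
  composed map would average voxel-independent noise away and collapse the
  heterogeneity the analysis is about.  Each lesion is rescaled
  multiplicatively so its realized mean matches the target exactly;
  background liver dose is low (default 5 Gy) with 10% noise on the same
  field, zero outside the liver.  σ = 0 gives an exactly uniform lesion
  (D90 = mean).  Everything is reproducible from the config seed.
* **SBRT dose** — flat prescription (36 Gy in 3 fractions) inside the PTV
  union, exponential falloff exp(−d/ℓ) with anisotropy-aware Euclidean
  distance d and scale ℓ = 8 mm outside, chosen as the simplest monotone
  surrogate for a VMAT penumbra.  It is a declared stand-in for a dose
  engine, isolated behind `simulate_sbrt_dose` so a real one can replace
  it.  Shrinking the PTV union can only lower dose everywhere, which makes
  the debulking benefit provable at property level.
* **Responses** — Bernoulli draws from a logistic TCP model, for testing
  the fitting chain end to end.

What passing synthetic tests do *not* show: real arc-delivery penumbra
shapes and optimizer trade-offs, respiratory motion, registration error,
or anatomical change between therapies.  The generator's dose statistics
are calibrated to be qualitatively realistic, not patient-matched.

## Plan evaluation and cohort statistics

Per-plan metrics are mean NLT dose, RILD NTCP (percent), CV15Gy (cc) and
the volume of the union of targeted PTVs.  Constraints are strict: MLD
< 9 Gy, CV15Gy > 700 cc.  Paired deltas are oriented so positive favours
the boost plan; relative PTV reduction is 100·(alone − boost)/alone.
Reported ± values use the sample standard deviation (ddof = 1,
configurable).  Report rounding follows clinical style: Gy to one
decimal, cc and percent to integers.

The packaged reference table stores per-plan metrics as printed, with
non-eligible cases as NA.  Aggregates that the original planning study
computed from unrounded data (mean paired deltas ≈ 2.09 Gy / 109 cc /
86 cc) recompute from the printed values as 2.17 Gy / 150 cc / 102 cc;
these are therefore checked for sign and magnitude only, while counts and
the relative-reduction statistics (39% ± 21%, min 0%, max 77%) reproduce
exactly.  The "14 eligible patients" averages include the case with
identical plans (zero deltas).

## Problem sizes

Tests and the reproduction script use 48×48×40 to 96×96×80 voxel phantoms
at 2 mm, 100 random ≤ 1000-voxel grids for oracle comparisons, 20
replicates of 500 simulated responses for estimator recovery, and 10
seeded synthetic cases for the end-to-end property — sizes at which every
check is exact or statistically stable while the whole suite runs in
seconds.
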