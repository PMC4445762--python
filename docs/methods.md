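# Methods

## Model

Tumor cell density c(r, t) obeys the proliferation–invasion
(Fisher–KPP-type) equation ∂c/∂t = ∇·(D∇c) + ρc(1 − c/K) under spherical
symmetry. D (mm²/year) is the net invasion rate, ρ (1/year) the net
proliferation rate, K (cells/mm³) the carrying capacity. The model's two
observable signatures are the asymptotic radial velocity v = 2√(Dρ) and the
front e-folding length λ = √(D/ρ). Imaging enters through cell-density
level sets: the lesion edge on T1Gd MRI is taken at c/K = 0.80, on T2 at
c/K = 0.16 (both configurable); these defaults follow the established
calibration convention for this model family. Most downstream quantities
are K-independent; where a value is needed (cohort synthesis) we default to
K = 1e5 cells/mm³, a standard order of magnitude for packed glioma tissue.

Spatially varying D(x) is accepted structurally (the solver operates on a
per-node diffusivity internally) but defaults to uniform D: no
tissue-specific values are part of this package's scope.

## Numerics

Finite-volume discretization on a uniform radial grid with faces at node
midpoints and zero-flux boundaries at r = 0 and r = r_max. This form
conserves the volume-weighted cell count Σ Vᵢcᵢ exactly under pure
diffusion (verified to ~1e-13 in tests), and the origin control volume
reproduces the symmetric limit 3·∂²c/∂r² of the spherical Laplacian
exactly.

Time stepping is Strang splitting: a half-step of the logistic reaction
using its exact solution map, a diffusion step, and a second reaction
half-step. Consequences: the D → 0 limit is exact (matches the closed-form
logistic solution to machine precision at any dt), and densities remain in
[0, K] by construction — the logistic map preserves the interval and the
backward-Euler diffusion matrix is an M-matrix. Bound violations beyond
1e-9·K are raised as errors, never clipped; sub-roundoff excursions are
snapped to the interval.

Schemes: `implicit` (default) uses backward Euler for diffusion via a
banded solve — unconditionally stable, first order in time; `explicit` uses
forward Euler with a hard precondition dt ≤ dr²/(6·D_day), the stability
bound implied by the origin cell's stencil weight 6D/dr² (stricter than the
planar textbook bound dr²/(2·D_day)). `SolverSettings.auto` picks
dr ≈ λ/8 (clamped to [0.05, 0.5] mm) and dt ≈ 0.05/ρ_day (clamped to
[0.1, 1] day); at these resolutions planar front speeds are accurate to
<0.5% and spherical runs are dominated by genuine curvature effects, not
discretization. Internal units are mm and days (clinical scan cadence);
the public API speaks mm²/year and 1/year with 365.25 days/year.

Radiation fractions and resections are instantaneous events applied between
steps at the nearest step boundary; with no events the treated and
untreated code paths are bit-identical.

Snapshot radii are the outermost linear-interpolated crossing of the
threshold level set; a field everywhere below threshold has radius 0, and a
field still above threshold at r_max reports r_max (upstream code sizes
domains so this indicates boundary contamination, which `wavefront_speed`
rejects).

## Traveling-wave machinery

The minimal-speed wave profile U(ξ) (units of λ) solving
U'' + 2U' + U(1−U) = 0 is integrated once off the unstable manifold of
U = 1 and cached. It serves two purposes:

1. **Initial conditions.** `front_profile(shape="wave")` seeds a developed
   tumor with the exact front shape at a prescribed lesion radius.
   Seeding with a crude saturated-core/exponential-tail sketch instead
   leaves a months-long shape transient (the T1Gd radius of a diffuse
   tumor can even shrink while the profile reorganizes), which would
   contaminate any synthetic observation series; the wave-shaped seed
   settles essentially immediately.
2. **Calibration inversion.** The distance between the c/K = 0.80 and
   0.16 level sets of the true profile is 6.106·λ — not ln(0.80/0.16) =
   1.609·λ as the pure exponential-tail picture suggests, because the
   0.80 level sits well behind the leading tail where the profile decays
   at the slower rate √2 − 1. The default λ inverter therefore divides
   the observed T2−T1Gd gap by the exact level-set distance
   (`lambda_method="profile"`); the textbook `exp_tail` formula is kept as
   an option but overestimates λ roughly 3.8-fold at these thresholds.

## Calibration

Velocity is the ordinary least-squares slope of the serial T1Gd radii
(negative slopes are reported, not errors). λ is averaged over all
timepoints with paired T1Gd/T2 radii. A spherical-curvature correction (on
by default) divides the fitted slope by (1 − λ/R̄), R̄ the mean T1Gd radius
in the fit window, because a spherical front of radius R advances at
approximately v(1 − λ/R); at clinical radii (15–30 mm) this is a 5–15%
effect and is the difference between recovering D within 10% or not. The
correction factor is floored at 0.5 to keep tiny-lesion input from
exploding the estimate. Then D = vλ/2 and ρ = v/(2λ). Calibration is
undefined (raised as `CalibrationError`) for non-growing series and
zero-gap (perfectly sharp) fronts.

Measured on noise-free synthetic patients over D ∈ {6, 15, 40} mm²/yr ×
ρ ∈ {4, 8, 12} /yr (D/ρ from 0.5 to 10 mm²), recovery error is ≤ ~9%
(worst at the most diffuse corner, where residual curvature and transient
effects are largest); with 1 mm radius noise on 4 scan pairs the median
absolute error is ~10–12% per parameter.

## Days Gained

The untreated virtual control anchors at the last pre-treatment scan
(configurable) and either runs the solver from a wave-matched profile
(`simulated`) or extrapolates r(t) = r₀ + v·(t − t₀) (`linear`); the two
agree within a few percent over six months for developed fronts. The score
is the time-axis distance: dg = t_post − t*, with t* the earliest
(interpolated) time the UVC reaches the post-treatment radius. A radius
below the anchor saturates t* at the anchor time (dg = elapsed time,
flagged); a radius beyond the horizon extrapolates with the final slope and
yields a negative score (flagged). Negative scores (hyper-progression) are
reported as-is. The responder cutoff is a required argument — no clinical
default is encoded.

## Radiotherapy (PIRT)

Each fraction of dose d kills instantaneously with linear-quadratic
survival S = exp(−αd − βd²), β = α/(α/β), α/β defaulting to 10 Gy (the
conventional tumor value). The kill is density-modulated,
c → c − (1−S)·c·(1 − c/K), so saturated regions respond less — an
event-based stand-in for proliferation-linked radiosensitivity chosen for
testability; a continuous loss-term coupling would be the natural
extension. `standard_plan` builds the standard-of-care 30 × 2 Gy weekday
schedule over 6 weeks (60 Gy).

## Resection and survival surrogates

GTR removes the density inside the current T1Gd radius, STR inside 0.75 of
it (configurable), biopsy nothing; a configurable residual fraction
supports sensitivity analyses. Removed cell counts are exact ball integrals
of the piecewise-linear density profile (they agree with independent
quadrature to ~1e-6). Survival is surrogated by the first time the T1Gd
radius reaches a uniform fatal size, default 35 mm equivalent spherical
radius (configurable; the uniform-fatal-size assumption is standard in this
model family, the specific number is a package default), censored at the
simulation horizon.

**Limitation worth stating plainly:** in this model the front is *pulled* —
its position is governed by the leading low-density tail, which any
margin-at-the-visible-lesion resection leaves intact. Removing everything
behind the margin therefore delays the fatal-radius clock by less than a
couple of days regardless of extent, and the small transient benefit that
does exist scales with λ/v, i.e. favors diffuse tumors. What varies
strongly and systematically with ρ/D is the *fraction of all tumor cells
the resection removes* (and equivalently how far the 99%-removal margin
extends beyond the visible lesion): nodular tumors are mostly contained in
their imaging margin, diffuse ones mostly are not. The package exposes both
quantities; users should not expect extent-of-resection survival contrasts
from the radius-clock surrogate alone, because the biology that produces
them clinically is not in this minimal model.

## Stratification

ρ/D (1/mm²) is invariant to joint unit changes. Threshold fitting is an
exhaustive scan over midpoints of sorted unique values (plus open ends)
maximizing Youden's J, ties broken toward the lower threshold; the positive
class is assumed on the low-ρ/D side unless the data prefer the opposite
orientation. Tests verify exact equivalence with a brute-force oracle and
with an independent ROC implementation. Default strata cutpoints are cohort
tertiles; stratum boundaries are half-open ([c1, c2) = moderate).

## Virtual cohorts

(D, ρ) are independent log-normals parameterized by median and coefficient
of variation — positive and right-skewed like published clinical spreads.
The defaults (median 10 mm²/yr and 10 /yr, CV 1.0) are placeholders spanning
the diffuse-to-nodular range, not population estimates. Observation
synthesis simulates each patient from a wave-matched profile detected at a
15 mm T1Gd radius, lets the front settle for 120 days, then reads both
modality radii at the scan schedule (default 0/60/120/180 days) and adds
zero-truncated Gaussian noise (default 1 mm), resampling draws that violate
T2 ≥ T1Gd. Kaplan–Meier estimation and the log-rank test are delegated to
lifelines. Virtual trials use a matched design — every sampled patient
passes through every arm — isolating therapy effects from kinetic spread;
a single seed makes the whole pipeline byte-reproducible.

## What the synthetic data do and do not establish

Synthetic cohorts share the generating model with the estimators, so
passing tests demonstrate internal consistency — that the calibration,
response and survival machinery recover what the model put in, at realistic
noise levels — not clinical validity. Real imaging adds segmentation error,
non-spherical lesions, registration drift, treatment-induced signal change
(pseudoprogression), and model misspecification, none of which are
emulated. Published cohort-level results in this model family (correlation
of α with ρ, IDH1 classification operating points, subgroup survival
benefits) depend on patient data that are not reproducible here and are
out of scope.

## Problem sizes

Default test and acceptance runs use radial domains of 40–100 mm at
dr ≈ λ/8, horizons of 0.5–10 years at dt ≤ 1 day, 9-point (D, ρ) grids,
200 noise replicates per grid point, 20-patient iceberg cohorts and
4–8-patient trials — sizes chosen so the full suite exercises every
pipeline end-to-end in well under half an hour on one core.
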