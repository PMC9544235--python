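# Methods

`lungdce` implements a quantitative DCE-MRI measurement of pulmonary
interstitial fluid: voxel-wise T1/S0 relaxometry, extended Tofts
pharmacokinetic modeling with a hematocrit-corrected pulmonary-artery input
function, muscle-normalized lung-water indices, regional endpoint
extraction, and the repeated-measures statistics used to compare groups and
quantify scan-rescan repeatability. Every stage is validated against a
synthetic digital lung phantom with known ground truth.

## Signal model and relaxometry

All acquisitions are modeled as spoiled gradient echo (SPGR) steady states,

    S(α) = S0 · sin α · (1 − E1) / (1 − E1 cos α),   E1 = exp(−TR/T1),

with the default whole-chest protocol TR/TE = 2.03/0.83 ms, variable flip
angles 4°/2°/7°/10° (10 repeated volumes per angle, averaged before
fitting), and a dynamic series of 170 volumes at 2.5 s/volume acquired at
10° with the contrast bolus at the start of the 15th dynamic (dynamics 1–14
form the baseline).

T1 and S0 are estimated per voxel by the DESPOT1 linearization (regression
of S/sin α on S/tan α) whose slope is E1, followed by bounded nonlinear
least squares on the untransformed signals with an analytic Jacobian; T1 is
constrained to [50, 10000] ms. The refinement is the maximum-likelihood
estimate under additive Gaussian noise and removes the noise bias of the
linearized estimator at low flip angles. Voxels that are all-zero,
non-finite, non-convergent, or that finish on a T1 bound keep their estimate
but are flagged invalid, and invalid voxels are excluded from every
downstream summary.

qS0 divides lung S0 by a skeletal-muscle reference. The default is per-slice
normalization along the anterior–posterior (coronal-slice) axis using the
median valid muscle S0 within each slice; a global whole-ROI median is
available as a fallback when the muscle ROI does not span all lung-bearing
slices. The median was chosen over the mean for robustness to ROI edge
voxels. qS0 is a ratio index: it deliberately inherits T2*/coil-sensitivity
weighting and no B1 correction is applied, so it is comparable within a
protocol, not an absolute water fraction. The product qS0·ve indexes the
extravascular extracellular water content relative to muscle.

## Kinetic model

Tissue concentration follows the extended Tofts model

    Ct(t) = vp·Cp(t) + Ktrans ∫₀ᵗ Cp(τ) exp(−Ktrans(t−τ)/ve) dτ,

with Ktrans in min⁻¹ and ve, vp volume fractions. The convolution is
evaluated with the exact recursion for a piecewise-linear Cp: over each
sampling interval the integral of (a + bu)·exp(−λ(Δ−u)) has a closed form,
so the scheme is exact for piecewise-linear inputs rather than a quadrature
approximation, and series limits are substituted when λΔ < 1e−8 to avoid
cancellation. Tests verify agreement with an independent refined-grid
trapezoidal convolution to better than 1e−4 mM and with the closed-form
constant-input solution (plateau vp + ve).

Signal→concentration uses the full SPGR inversion, not the low-concentration
linearization: each voxel's dynamic series is rescaled so its baseline mean
matches the SPGR prediction at the fitted (S0, T10) — absorbing scanner
scaling between the VFA and dynamic acquisitions — then inverted for T1(t),
and C(t) = (1/r1)(1/T1(t) − 1/T10). The full inversion is the safer choice
at half-dose peak concentrations where the linearization would bias the
first pass. Samples whose implied E1 leaves (0, 1) are flagged invalid
rather than raised; concentrations below a −0.5 mM floor are clipped and
flagged.

The plasma input is the per-dynamic median whole-blood concentration over
the pulmonary-artery ROI divided by (1 − Hct). Blood concentration is
computed assuming the native blood T1 (default 1440 ms at 1.5 T) with S0
derived self-consistently from the baseline signal, because the VFA fit is
unreliable in flowing blood; a flag allows the voxel-wise fit instead.
Defaults: relaxivity r1 = 5.0 L·mmol⁻¹·s⁻¹ (gadobutrol at 1.5 T, literature
value, config-overridable), hematocrit 0.42 when no per-subject value is
given.

Voxel fits are bounded nonlinear least squares (Ktrans ∈ [0, 5] min⁻¹,
ve ∈ [1e−4, 1], vp ∈ [0, 1]) seeded from a fixed 3×3×3 multi-start grid
(log-spaced in Ktrans) scored vectorized per voxel; the best start is
refined with a trust-region solver under uniform time weighting. Solutions
on an upper bound, or at the ve floor with nonzero Ktrans, keep their
estimate with the validity flag cleared; Ktrans = 0 / vp = 0 are legitimate
null-signal solutions and stay valid. No per-voxel bolus-arrival time is
fitted: dynamic k maps to time (k−1)·dt and the injection dynamic defines
the input's onset.

## Regions and endpoints

Each lung is split into apical and basal segments at the midpoint between
its apex and its most inferior extent along the foot–head direction,
computed on voxel-center physical coordinates (mm) resolved from the NIfTI
affine — robust to anisotropic voxels; voxels exactly at the midpoint are
assigned apical. Endpoints are summarized over valid voxels only: medians
for Ktrans, ve, T1, qS0 and qS0·ve per region (total, left, right, four
subregions); means for vp, where the left/right/total values average the
constituent subregion means (the alternative plain voxel mean is available
behind `vp_mode="voxels"` because the aggregation convention is genuinely
ambiguous). Regions with no valid voxels are omitted with a logged warning.

## Statistics

Each endpoint×region is analyzed with a linear model with fixed effects
group, session and group×session and a per-subject random intercept
(statsmodels MixedLM, REML), read here as the mixed-model realization of an
ANOVA with participant as the block of the repeat factor. Reported
contrasts are group differences at each session (patient minus control) and
session differences within each group, with t-based 95% intervals using
between-within (containment) degrees of freedom: between-subject contrasts
use n_subjects − n_groups, within-subject contrasts the residual within-df.
This choice calibrates the type-I error of the between-group test at the
study's size (verified by simulation at 17 + 12 subjects × 3 sessions).
Missing cells are handled by likelihood, so subjects with a missing session
are retained. P-values are descriptive; no multiplicity adjustment.

Scan–rescan repeatability between sessions 1 and 2 is the within-subject
coefficient of variation CV% = 100·√(exp(MSE) − 1), with MSE the residual
variance of the same random-intercept model fitted on log-transformed
values. The log transform is mandatory: the back-transform is exact only
for log-normal within-subject error, so nonpositive endpoint values are
rejected with the offending rows listed. The CV estimator carries a small
downward Jensen bias from the square-root transform (≈1–2% of the CV at
n = 17 pairs), visible in the simulation checks.

The age association uses the plain Pearson correlation with its two-sided
t-based p-value.

## Phantom

The phantom places two ellipsoidal lungs, a chest-wall muscle slab spanning
all coronal slices, and a pulmonary-artery-like vessel cylinder on a
configurable grid (minimum 16×16×8; default voxels 4×4×8 mm, RAS affine).
Lung voxels draw Ktrans log-normally and ve, vp, T1 normally around regime
medians, clipped so ve + vp ≤ 1:

| regime | ve | Ktrans (min⁻¹) | vp | T1 (ms) | S0/muscle |
|--------|------|------|------|------|------|
| HV-like | 0.33 | 0.25 | 0.45 | 790 | 0.26 |
| HF-like | 0.49 | 0.20 | 0.48 | 760 | 0.27 |

These medians sit at the magnitudes the measurement is designed to separate
in healthy versus congested lungs. Muscle gets T1 ≈ 1000 ms and the
reference S0; the vessel carries blood T1 = 1440 ms and the whole-blood
concentration Cp·(1 − Hct), so the measurement chain must re-apply the
hematocrit correction to recover the plasma curve. The generative plasma
input is a Parker-type population curve (two Gaussian passes plus a
sigmoid-gated exponential washout), scaled linearly by dose from the
0.1 mmol/kg reference; the study-default dose is 0.05 mmol/kg. The measured
input in a real exam would differ in shape; the population curve is a
generative stand-in, which is why the tests emphasize round-trip recovery
rather than curve shape.

Noise is Rician (magnitude MRI), with Gaussian available for analytic
checks; the default scale sets baseline lung SNR 50. The phantom is
motion-free and has no coil-sensitivity or k-space effects, so passing
tests demonstrate correctness of the measurement chain, not robustness to
breathing motion or anatomy — motion correction and segmentation are
upstream inputs, out of scope here.

## Numerical and design choices

- Noiseless self-consistency: simulate → measure recovers T1, S0, Ktrans,
  ve, vp to machine precision (tested at 1% tolerance, observed ~1e−11).
- Flip-angle order is irrelevant after per-angle averaging; angles are kept
  in printed acquisition order.
- Convolution rate λ = Ktrans/ve uses a series limit for λΔ < 1e−8;
  ve = 0 with Ktrans > 0 is rejected as an undefined kernel.
- All simulations take explicit integer seeds; per-subject/session seeds
  derive from the run seed via `SeedSequence`, so a config + seed reproduce
  outputs bit-for-bit.
- Problem sizes in the shipped tests and acceptance script (e.g. 20–24
  voxel grids, 3 + 3 subjects × 3 sessions end-to-end, 500–1000 simulation
  replicates) were chosen as the smallest sizes at which the Monte-Carlo
  checks are stable.

## Known limitations

- The AIF onset is assumed at the injection dynamic; no per-voxel
  bolus-arrival fitting, which would bias Ktrans in tissues with long
  transit delays.
- qS0 does not correct for T2/T2*, B1 or coil sensitivity.
- No model selection: the extended Tofts model is assumed, not tested
  against alternatives (Patlak, two-compartment exchange).
- The mixed model assumes Gaussian errors on the analysis scale; endpoints
  are medians over many voxels, which makes this mild in practice.
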