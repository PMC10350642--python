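# Methods

## Kinetic model

Tissue activity follows the irreversible two-tissue-compartment model
(free pool C1, phosphorylated pool C2):

    dC1/dt = K1·Cp(t) − (k2 + k3)·C1,   dC2/dt = k3·C1,   Ct = C1 + C2

Dephosphorylation is negligible on the simulated horizon, so k4 = 0.
With α = k2 + k3 and Ki = K1·k3/α this is evaluated in integral form,

    Ct(t) = Ki·∫₀ᵗ Cp + (K1·k2/α)·∫₀ᵗ e^{−α(t−s)} Cp(s) ds .

The plasma input is a Feng-style tri-exponential bolus,
Cp(t) = (A1·t − A2 − A3)e^{λ1 t} + A2 e^{λ2 t} + A3 e^{λ3 t}, with
defaults A1 = 851.1 kBq·mL⁻¹·min⁻¹, A2 = 21.9, A3 = 20.8 kBq·mL⁻¹,
λ = (−4.134, −0.1191, −0.0104) min⁻¹ — generic literature-style bolus
values, configurable, and not fitted to any particular patient. For
this input both integrals have exact closed forms (sums of ∫ eλs and
∫ s·eλs terms, with series fallbacks as λ→0), which the implementation
uses directly: it is exact, fast enough for replicate studies, and
carries no integration tolerance. Tabulated inputs (linear
interpolation, zero outside the samples) are integrated by adaptive
quadrature (absolute tolerance 10⁻⁶ kBq/mL). An independent ODE
integration (`scipy.integrate.solve_ivp`) serves as the oracle in the
tests, never as the implementation; agreement is ~10⁻¹² relative.

Default gray-matter rates are K1 = 0.102 mL·min⁻¹·g⁻¹, k2 = 0.130,
k3 = 0.062 min⁻¹ — typical published human FDG values, again not
patient-derived. Tissue density is taken as 1 g/mL so per-gram rate
constants match per-mL image units. Simulated activities are
decay-corrected to injection time (standard scanner convention), which
is why SUV rises between the two scans. SUV = activity[kBq/mL] ×
weight[g] / dose[kBq]; the kg/MBq factors of 1000 cancel.

The epileptogenic region is hypometabolic through multiplicative
factors K1 × 0.92 and k3 × 0.75. Both hemispheres share everything
else, so the early asymmetry is mostly the K1 deficit while the late
asymmetry approaches the (larger) Ki deficit — the asymmetry index
therefore grows monotonically with scan delay, the mechanism the
pipeline exists to quantify. A time-constant k3 is assumed; possible
time dependence of phosphorylation is out of scope.

## Phantom and cohort

The phantom is a parcellated ellipsoid, not an anatomical template: a
64×64×48 grid at 3 mm isotropic, RAS affine with the world origin at
the grid center, mid-sagittal plane x = 0, and 8 wedge-shaped regions
per hemisphere (angular bins in the y–z plane) named `lh_region_*` /
`rh_region_*` with an explicit pairing table. Using an even grid
dimension along x makes the index flip an exact mirror, so paired
regions have identical voxel counts and, with identical kinetics,
asymmetry exactly zero. Regions under 20 voxels are rejected.

Noise is Gaussian on SUV with per-region σ = 5% of the regional mean
(draws clipped at ±5σ); reconstruction (Poisson-like) noise and
partial-volume effects are not modeled. Rigid motion is applied by
resampling on the original grid (trilinear, zero fill), for testing
quantification under a known misalignment; transform *estimation* is
out of scope.

A default cohort has n = 52 patients: early delay ~ N(43.44, 18.04²)
min truncated to [20, 90]; delayed ~ N(160.46, 28.70²) truncated to
[120, 200]; weight ~ N(65, 12²) kg truncated to [30, 110] (weights are
a modeling device — only the per-kg dose rule of 3.7 MBq/kg is given);
P(MRI-positive) = 34/52; EZ side left or right with probability 0.5;
per-patient lognormal multipliers (σ_log = 0.1) on K1, k2, k3. All
randomness flows from a master seed through `numpy.random.SeedSequence`
spawns, so cohorts are bitwise reproducible.

`simulate_cohort_regional` is an exact region-level shortcut: since a
region's voxels are i.i.d. Normal around the kinetic prediction, its
SUVmean is Normal(μ, (σμ)²/n_vox), which is sampled directly. The
voxelwise and regional routes agree exactly in the noise-free case
(tested); replicate studies (200 cohorts) use the regional route,
single-cohort analyses the voxelwise one.

## Quantification conventions

Labels are resampled to the PET grid (nearest neighbor through world
coordinates; half-voxel ties resolve toward the lower index), never PET
to the label grid, so intensities are not interpolated before
averaging. SUVmean is the arithmetic voxel mean; background (label 0)
never contributes. An EZ spanning several regions is a voxel-weighted
union, not a mean of means. Regional means conserve total image mass
and are invariant under aligned downsampling of piecewise-constant
images (both exact, tested).

## Statistics

AI = 200·(SUVc − SUVez)/(SUVc + SUVez), positive when the EZ side is
hypometabolic; records whose PET lateralization opposes the designated
EZ side yield negative AI and are retained. Useful identities (all
property-tested): scale invariance AI(ca, cb) = AI(a, b); antisymmetry
AI(a, b) = −AI(b, a); under a proportional deficit SUVez = (1−a)·SUVc,
AI = 200a/(2−a) exactly.

Banding: AI < 10 sub-threshold, [10, 15] suggestive (closed interval —
boundary behavior is a convention and is documented as such), > 15
diagnostic. The paired t uses the sample (n−1) SD and a two-sided
p-value via the regularized incomplete beta function; differences whose
SD vanishes to floating-point rounding are treated as degenerate
(surfaced, not silently tested). Cohen's kappa bands are half-open
[lo, hi) with "very good" closed at 1.00. ΔAI = 0 ties form their own
category in cohort counts; percentages are recomputed from counts.
Strata with n < 2 report means but flag dispersion and tests as
unavailable rather than fabricating them. p-values are reported to 4
significant figures; "p = 0.000"-style output is never produced.

The simulated observers rate each patient from ΔAI plus independent
N(0, sd²) perception noise against a ±threshold band (defaults sd =
1.5, threshold = 1 AI unit). Under the default cohort nearly all
patients clear the threshold, so both observers rate almost everything
`delayed_better`: raw agreement is high but the contingency table is
dominated by one category, and kappa collapses toward zero — the
well-known kappa paradox under skewed prevalence. The implementation
reports exactly this; matching any particular published kappa value is
not attempted.

## What the phantom does and does not show

The generator reproduces the *mechanism* (asymmetry growth with scan
delay under reduced EZ k3/Ki, scan-time variability, regional noise,
MRI-status mixture) but not patient anatomy, registration error,
partial-volume effects, bilateral hypometabolism, or the absolute AI
level of any real cohort — the default phantom's AI1 ≈ 22 and ΔAI ≈ 5
are properties of the chosen kinetic factors, not reproductions of
clinical values (no per-patient images or SUVs exist to reproduce).
Passing tests therefore certify the pipeline's arithmetic, conventions
and statistical behavior, and the direction and robustness of the
dual-time-point effect, not clinical performance.

## Problem sizes

Defaults were chosen at desk scale: 64×64×48 voxel volumes, 8 regions
per hemisphere (a full cortical parcellation has ~100+), 52-patient
cohorts, 200-replicate studies, 2000-replicate type-I calibration. The
full default pipeline runs in seconds on one CPU.
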