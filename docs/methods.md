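# Methods

`wmquant` re-implements, as a single tested pipeline, a multi-parametric
quantitative-MRI assessment of white-matter microstructure: diffusion
tensor imaging (DTI), constrained diffusion kurtosis imaging (DKI), the
NODDI three-compartment neurite model, myelin-water-fraction (MWF)
relaxometry with extended-phase-graph (EPG) stimulated-echo correction,
magnetization-transfer-ratio (MTR) and R2\* mapping,
fibre-orientation-dependence regressions, and region-of-interest (ROI)
comparison statistics.  Because no raw cohort data are available, every
stage is validated by parameter recovery from a synthetic phantom whose
ground truth defaults to normative adult white-matter values for three
region archetypes: frontal WM, the cortico-spinal tract at the centrum
semiovale (CST-CS), and at the posterior limb of the internal capsule
(CST-PLIC).

## The synthetic phantom

The phantom is a flat slab: one slice of shape
`(voxels_per_region, n_regions, 1)`, one rectangular block per region.
Spatial realism is a non-goal — the phantom exists to make every fitter
verifiable against known truth, so noise-free voxels within a region are
identical by construction, and a fixed master seed reproduces the dataset
bit for bit (per-modality noise streams are spawned from the master seed).

Per region the ground truth holds: tensor eigenvalues (um^2/ms) with a
principal orientation, a direction-independent apparent kurtosis K,
NODDI fractions (ICVF, ODI, ISO), T2 components (value, fraction), T1,
the true refocusing flip angle, MTR (percent), R2\* (1/s) and S0.
Defaults are normative adult means; the CST-PLIC MWF (0.150) is a
synthetic assumption because the single-slice CPMG acquisition those
norms derive from did not cover the PLIC.

Emitted acquisitions (all writable as NIfTI-1 plus FSL `bvals`/`bvecs`):

* **DWI**, two shells (30 directions at b = 700 s/mm^2, 64 at b = 2000,
  plus b = 0; directions are spherical-Fibonacci points).  Three forward
  channels are written — tensor, kurtosis, and NODDI — sharing the one
  gradient table, so each fitter is tested against its own generating
  model rather than confounded by model mismatch.  The kurtosis channel
  uses an isotropic tensor at the region MD: with the region's full
  anisotropic tensor, the PLIC truth (axial d = 1.611, K = 1.392) would
  violate the fitter's own kurtosis cap K <= 3/(b_max d) along axial
  directions and no constrained fit could recover it.
* **CPMG**: 32 echoes, TE = 10...320 ms in 10 ms steps, simulated by EPG
  (below) with a two-component T2 spectrum, plus a unit B1 map.
* **MT pair**: non-MT = S0 and MT = S0 (1 - MTR/100).
* **Gradient echo**: 8 magnitudes at TE = 4.5/10/15/21/27/33/39/46 ms,
  mono-exponential in R2\*.

Noise, when requested, is Rician: sqrt((s+n1)^2 + n2^2) with Gaussian
n1, n2 — the magnitude-MRI noise model.  The default is noise-free; the
acquisitions state no SNR, and when a noisy phantom is wanted a sigma of
S0/50 (SNR ~ 50 at b = 0) is a reasonable choice for 3 T protocols of
this kind.

What the phantom does **not** emulate: spatially varying anatomy, partial
volume, crossing-fibre geometry per voxel (dispersion enters only through
the Watson distribution), k-space artefacts, phase images (so no
susceptibility inversion), or B1 inhomogeneity beyond a scalar map.
Passing recovery tests therefore demonstrates correctness of the
estimators under their own forward models, not robustness to the many
real-data effects (motion, misalignment, model mismatch) that a scanner
study faces.

## Diffusion models

**DTI** is the standard log-linear ordinary least-squares tensor fit
(design columns 1 and -b g_i g_j), restricted to b = 0 plus the b = 700
shell for comparability with classic DTI studies.  Ordinary (unweighted)
LS is used deliberately.  Eigenvalues are sorted descending; FA uses the
normalised eigenvalue-dispersion formula, with FA of an all-zero tensor
defined as 0.  Non-positive signals flag the voxel (NaN in maps) rather
than raising.

**DKI** fits the cumulant expansion
ln S = ln S0 - b d(n) + (1/6) b^2 V(n), where d(n) is the quadratic form
of the diffusion tensor and V(n) = MD^2 W(n) the quartic kurtosis form
(15 unique coefficients with multinomial multiplicities).  Constraints
per acquired direction: d(n) >= 0.1 um^2/ms (lower diffusivities are
implausible and would defeat the kurtosis cap), K_app(n) >= 0 and
K_app(n) <= 3/(b_max d(n)).  In the (ln S0, D, V) parametrisation all
three are *linear* in the unknowns — the cap becomes
V(n) <= (3/b_max) d(n) — so the problem is a quadratic program with
linear inequalities and is solved exactly (SLSQP with analytic
gradients); no linearisation pass is needed.  The unconstrained
least-squares solution is accepted directly when feasible, which is the
typical high-SNR case; solver failure falls back to the unconstrained
estimate with the voxel flagged.  MK is the mean of K_app over 10,000
spherical-Fibonacci directions, RK a 256-point great-circle average
perpendicular to the principal axis, AK the principal-axis K_app; the
closed-form elliptic-integral expressions are intentionally out of scope
and the numerical averages are the oracle-checked contract.  A free
intercept (ln S0) is fitted.

**NODDI** uses the canonical three-compartment forward model:

S/S0 = (1-ISO) [ ICVF A_ic + (1-ICVF) A_ec ] + ISO exp(-b d_iso)

with Watson-dispersed sticks A_ic = E_W[exp(-b d_par (g.n)^2)],
ODI = (2/pi) arctan(1/kappa), an extra-neurite zeppelin with tortuosity
d_perp = d_par (1-ICVF) dispersed by the same Watson distribution (its
mean tensor uses tau = E_W[(n.mu)^2]), and fixed diffusivities
d_par = 1.7 um^2/ms, d_iso = 3.0 um^2/ms — the model's canonical
defaults, configurable.  The Watson integrals reduce, via the rank-2
quadratic form kappa mu mu^T - b d g g^T, to one-dimensional polar
integrals (azimuth integrates to a Bessel I0 factor) evaluated with a
201-point Gauss-Legendre rule in log space; this resolves concentrations
up to kappa ~ 1e4 and agrees with dense 2-D quadrature to ~1e-12 and with
10^6-sample Monte-Carlo to sampling error.  ODI = 0 switches to the
parallel-stick closed form, so there is no division by zero.  Fitting:
S0 from the mean b = 0 signal; orientation initialised from the principal
eigenvector of a quick tensor fit; a coarse grid over
(ICVF, ODI, ISO) selects the start; bounded trust-region least squares
(ftol/xtol/gtol 1e-12) refines all five parameters.  Non-convergence
returns best-so-far, flagged.

## Relaxometry

**EPG engine.**  CPMG echo amplitudes are computed with the extended
phase graph: ideal 90-degree excitation about x, refocusing pulses of
flip alpha about y (CPMG condition), one configuration-order shift per
half echo spacing, T2 decay on transverse states and T1 decay on
longitudinal states.  Longitudinal *regrowth* is omitted: the fitted
quantity is the decay of the initially excited magnetization, and the
train (320 ms) is short relative to TR (3 s).  At alpha = 180 the engine
reduces to exp(-TE/T2) at machine precision; at lower flips it matches a
brute-force isochromat (Bloch rotation) simulation to 1e-10, which is the
independent oracle in the test suite.

**T2 spectrum / MWF.**  Non-negative least squares of the echo train
against the EPG basis on 32 log-spaced T2 values from 10 ms to 2 s (the
count is the protocol's; the range follows common multi-component-T2
practice and is configurable).  Regularisation is minimum-energy
(identity Tikhonov) with the weight set by bisection so that the achieved
misfit equals `chi2_factor` (default 1.01) times the unregularised
minimum, to 0.05% relative — the chi-square-ratio convention.  The
penalty *form* is a declared design choice; the ratio contract is exact.
MWF = spectral amplitude below 30 ms over the total (40 ms is also seen
in the literature; the cutoff is configurable).  Note the basis T2 grid
extends beyond the nominal T1 of 1000 ms; the EPG recursion is well
defined there and the long tail keeps CSF-like components representable.

**Two-step flip handling.**  Step 1 fits every voxel with the flip free
(golden-section search on [90, 180] degrees, 0.1-degree tolerance, on the
unregularised misfit).  Step 2 fixes each voxel's flip to B1(voxel) x c,
with the single scalar c chosen so that the median of these flips equals
the step-1 median, then refits with the regularised spectrum.  "Scaled to
match the median" is read as matching the median of B1 x c to the step-1
median flip (rather than voxel-wise replacement); this anchoring makes
the result exactly invariant to a global multiplicative miscalibration of
the B1 map, which the suite verifies.  Fewer than 3 voxels skip the
rescaling and keep step-1 flips, flagged.

**MTR** = 100 (non-MT - MT)/non-MT percent; non-positive reference voxels
are missing (NaN).

**R2\*** is fitted by Levenberg-Marquardt on the *squared* model
(S0 exp(-R2\* TE))^2 against the squared magnitudes — squaring
de-emphasises low-signal late echoes — initialised from a two-point
log-linear estimate.  TE is converted to seconds internally; R2\* is
reported in 1/s.  On noise-free data the squared fit agrees with the
plain (unsquared) nonlinear fit to better than 1e-6.

## Orientation dependence

Myelinated fibres act as anisotropic cylindrical compartments (the
generalized Lorentzian tensor picture): the frequency shift varies as
sin^2 and R2\* as sin^4 of the angle theta between the fibre axis and B0.
theta comes from the voxel's principal diffusion direction, folded to
[0, 90] degrees (fibre orientation is axial), with B0 along the image
+z axis by default (configurable — axis conventions differ between
scanners).  Fixed-exponent fits are exact linear regressions on
sin^n(theta) with the amplitude tested against zero by its standard error
(two-sided t); the free exponent is bounded to [1, 8] to avoid the
degeneracy at vanishing amplitude and multi-started at n = 2 and 4.
Fits require at least 5 samples spanning at least 45 degrees.  Only the
functional forms are reproducible — the original per-subject effect sizes
were not published.

## ROI statistics

Maps are summarised per ROI as mean/SD over in-mask, non-missing voxels;
left/right hemisphere sub-labels are averaged into one value per subject
*before* group statistics.  Regions are compared by two-sided paired
t-tests across subjects (t = mean(d)/(sd(d)/sqrt(n)), df = n-1); the unit
of analysis is the per-subject region mean, and one phantom realisation
plays the role of one subject.  p-values are deliberately not corrected
for multiple comparisons (the analysis is descriptive); stars follow
\*p<0.05, \*\*p<0.01, \*\*\*p<0.001.  Zero-variance differences with a
non-zero mean would give an infinite t; a capped sentinel (1e12) with
p = 0 and a degenerate flag is reported instead.  The exact t-scores of
the original cohort require its unpublished per-subject values; only the
structure and the *sign* of every between-region difference is testable,
and the end-to-end suite checks exactly that on the noise-free phantom.

## Problem sizes and numerical defaults

Desk-scale defaults keep a full end-to-end run around a few seconds per
subject: 3-10 voxels per region, 2-3 subjects, 95 diffusion measurements,
32 echoes.  NODDI costs ~0.25 s per voxel (grid + ~10^2 forward
evaluations, each a 95 x 201 quadrature); MWF ~0.05 s per voxel
(~17 golden-section NNLS solves plus the bisection).  Tolerances:
Watson quadrature ~1e-12 against dense quadrature; NODDI optimiser tols
1e-12; chi^2-ratio bisection 5e-4 relative; flip search 0.1 degree; DKI
constraint slack 1e-10.  Ties in eigenvalue sorting are broken by a
stable descending sort.

## Known limitations

* Gaussian least squares throughout; no Rician-likelihood fitting, so
  estimates are biased at very low SNR.
* The DKI kurtosis cap makes strongly anisotropic, high-kurtosis ground
  truths (b_max d K > 3) unrepresentable by design — a property of the
  constrained estimator itself, reflected in the phantom's isotropic
  kurtosis channel.
* NODDI inherits its fixed-diffusivity assumption; recovered ICVF is a
  model parameter, not a direct water fraction.
* No motion/eddy/EPI-distortion correction, registration, tractography,
  susceptibility inversion (QSM), MR spectroscopy quantification, or
  quantitative MT — those stages belong to external tools and are out of
  scope here.
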