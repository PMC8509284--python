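# Methods

## Phantom model

The phantom is a single oblique-coronal 2D slice (matrix 128×128, FOV
35×35 mm², so ~0.27 mm in-plane voxels; the data model carries a slice
axis of length 1 so real 3D stacks are not precluded). Geometry is three
concentric elliptical bands oriented along the long axis: cortex outermost,
then the outer stripe (OSOM), then the inner stripe (ISOM) of the outer
medulla at the core. Default band borders (normalized elliptical radii
0.72 and 0.45, outer semi-axes 0.81/0.47 of the half grid) give roughly
2350 cortex, 1550 OSOM and 990 ISOM voxels at 128×128 — every compartment
comfortably above the ≥100-voxel floor that keeps region means stable.
Compartment means, CMD and histogram metrics depend only on voxel
populations, not on the silhouette, so an anatomically realistic outline
would exercise nothing additional; that is the deliberate trade.

Per-compartment ground truth (T1, T2 in ms; ADC in 10⁻³ mm²/s) comes from
preset tables of published group means for healthy controls, isogenic
grafts and allogenic (rejecting) grafts at weeks 3 and 6. The ISOM and
OSOM share the outer-medulla ADC value because the two stripes are not
separable on diffusion maps.

### Heterogeneity model

Rejecting grafts show areas of high and low ADC side by side. The phantom
reproduces this with a balanced two-class mixture: a Gaussian random field
smoothed to correlation length `patch_scale_vox` (default 4 voxels ≈ 1 mm;
no quantitative spatial statistics are published, so this is a free,
config-exposed parameter) is thresholded at zero, splitting tissue into
two spatially coherent classes of expected weight 1/2. Class ADC means sit
at base ± δ with within-class SD σ; values are clipped below at
0.1×10⁻³ mm²/s.

Closed forms for the balanced mixture drive calibration: variance
δ² + σ², and quantiles from the CDF ½Φ((x−δ)/σ) + ½Φ((x+δ)/σ). Two facts
matter:

* along the constraint δ² + σ² = SD², the IQR grows monotonically from the
  Gaussian value 1.349·SD (δ = 0) toward 2δ (well-separated classes);
* at strong separation (δ/σ ≳ 3) the quartiles sit essentially at the
  class means, so IQR ≈ 2δ — *not* 1.349·SD.

Consequently SD and IQR jointly identify (δ, σ): `calibrate_mixture`
solves the 1D root problem by bisection. For the week-3 allograft targets
(SD 0.33, IQR 0.45) this gives δ ≈ 0.148, σ ≈ 0.295 — a mildly bimodal
field. For week 6 (SD 0.32, IQR 0.43) the target IQR is marginally below
the Gaussian 1.349·SD = 0.432, which a symmetric mixture cannot reach;
calibration then degenerates to a single Gaussian (δ = 0), matching the
IQR to within 0.5%.

### Measured-domain calibration

The published histogram descriptors describe *fitted maps*, which carry a
predictable estimator noise floor on top of true tissue dispersion. For
the weighted log-linear ADC estimator the delta-method floor is

  sd(ADC) = 1 / sqrt(Σᵢ wᵢ (bᵢ − b̄_w)²),  wᵢ = (sᵢ·SNR/S0)²,

about 0.07×10⁻³ mm²/s at SNR 40 with the default b grid. Generator presets
therefore target truth dispersion equal to the printed dispersion
deconvolved by this floor, so the *pipeline output* lands on the printed
values. The same logic gives isogenic grafts a smooth within-compartment
ADC texture (standardized to its target SD exactly, removing draw-to-draw
calibration jitter) that tops up the between-compartment spread; controls
remain piecewise-constant, as no control histogram values are published.
The patch mixture is reserved for the allogenic group; the smooth texture
models ordinary biological variation in any transplanted kidney.

## Acquisition model

Signal equations (magnitude):

* inversion recovery: |M0·(1 − (1+η)·e^(−TI/T1) + e^(−TR/T1))| with
  inversion efficiency η = 1 by default (ideal non-selective pulse,
  parameter exposed) and TR = 18 000 ms, so the finite-TR term is < 10⁻³
  even at T1 = 2300 ms;
* spin echo: M0·e^(−TE/T2), no offset term;
* diffusion: S0·e^(−b·ADC).

Default axes: the 13 printed TIs (30–8000 ms); TE 11–77 ms taken as the
arithmetic progression with step 11 (only the range is published); b in
{0, 100, 200, 300, 400, 600, 800} s/mm² (only "7 b-values, 0–800" is
published). Both spacings are config-overridable, and the noiseless
round-trip is exact for any grid, so results are insensitive to the
choice.

Noise is Rician — each voxel becomes √((s+n₁)² + n₂²) with n₁, n₂ ~
N(0, σ²), σ = S0/SNR — because all fitted data are magnitude images.
Default SNR 40 (at S0) puts recovered group means within the published
SEMs at the published group sizes. Known magnitude-bias consequences at
this SNR, documented rather than corrected: T2 is overestimated by
~1.5–2% (late echoes approach the noise floor), ADC is underestimated by
<1%, and the T1 Monte-Carlo bias stays below 0.5%.

## Estimators

**T1 (magnitude IR).** Three-parameter model |a − b·e^(−TI/T1)| with
polarity restoration: the magnitude minimum locates the zero crossing to
within one sample, so candidate null indices in a ±1 window around the
per-voxel argmin are tried; for each candidate the pre-null points are
sign-flipped and the signed model fitted, and the smallest-residual
candidate wins. For fixed T1 the amplitudes (a, b) are linear (variable
projection), so the 1D profiled residual is minimized by a deterministic
96-point log grid over [200, 5000] ms followed by 40 golden-section
iterations — convergent to ~10⁻⁹ relative, no random restarts, fully
vectorized across voxels. Reported T1 is the exponential rate constant
itself (single-shot readout; no Look-Locker correction). Per-voxel
standard errors come from the linearized Jacobian at the optimum.

**T2 and ADC.** Weighted log-linear least squares with weights = signal²,
the first-order inverse-variance weighting for log-transformed magnitude
data; non-positive signals are excluded, and fewer than 3 (T2) / 2 (ADC,
which must include b = 0) usable points masks the voxel. A per-voxel
Levenberg–Marquardt refinement of the untransformed model is available
behind `nls_refine`; on noiseless data the two routes agree to 10⁻¹⁰,
so downstream results do not hinge on the estimator choice.

**Masks.** A voxel enters a map's validity mask only if the fit is finite,
R² ≥ 0.9 (config-exposed) and the estimate lies strictly inside the
plausibility bounds: T1 ∈ [200, 5000] ms, T2 ∈ [5, 500] ms (non-decaying
voxels are clipped at 500 and masked), ADC ∈ [0.05, 4.0]×10⁻³ mm²/s (a
zero-ADC voxel is flagged by the lower bound). Voxels whose peak signal is
below 5% of the image's 99th-percentile peak are skipped outright —
all-zero voxels mask out rather than raise. Bounds are package defaults,
not published values.

## ROI statistics

Region means are arithmetic means over unmasked voxels of cortex, OSOM,
ISOM, OM (= OSOM ∪ ISOM) and whole kidney; empty regions yield an explicit
missing value (never 0). CMD = ISOM mean − cortex mean, computed per
subject and then averaged across subjects, matching per-animal reporting.
Whole-compartment means stand in for manually placed ROIs; since the
phantom truth is constant (or statistically homogeneous) within a
compartment, a compact sub-ROI would estimate the same quantity with more
variance.

## Histogram metrics

Moments and the IQR are computed from raw voxel values (SD with n−1;
kurtosis is Pearson m₄/m₂², normal = 3, chosen because published
near-unimodal values cluster around 3; IQR by linear interpolation).
The KDE uses a Gaussian kernel with Silverman's rule bandwidth on a fixed
128-point grid spanning [0, 3.5]×10⁻³ mm²/s; entropy is
−Σ pᵢ ln pᵢ / ln 128 with pᵢ the grid-normalized density, hence in [0, 1].
This entropy is a declared convention: the original analysis's entropy
definition and KDE grid are not recoverable, so entropy is validated as a
monotone heterogeneity index (allograft > isograft in every simulated
replicate), never against numeric published values. A `relative_grid`
flag rescales the grid with the data, making entropy exactly
scale-invariant; under the fixed default grid, invariance holds to KDE
discretization error. Fewer than 50 voxels is an error (unstable KDE).

## Group statistics

Three-group designs use one-way ANOVA with Tukey's HSD on all pairs
(pairwise p-values are always reported, flagged when the omnibus F is not
significant at 0.05); two-group designs use the unpaired t-test with
equal variances (the conventional default; Welch available via a flag —
whether the original analysis used it is unstated); longitudinal
contrasts use the paired t-test. Shapiro–Wilk normality screening is
reported but never blocks the pipeline. Summary tables show mean ± SEM
(SEM = sd/√n) with stars at p < 0.05/0.01/0.001.

## Reproducibility and problem sizes

Every stochastic step is driven by numpy Generators seeded from a single
master seed through a stable per-subject scheme (CRC of the cohort
identity XOR a multiplied master seed, < 2³¹), so re-running a
configuration is bit-identical and adding a cohort does not perturb
existing subjects. The acceptance script simulates the full published
group sizes (control n = 22, allograft w3 n = 5) at 128×128. The
replicated significance-pattern check runs 200 independent studies at
64×64 — the smallest grid the phantom geometry accepts — which preserves
all group-level effects while keeping the run desk-scale; per-voxel fit
noise is larger there, but the tested contrasts are many standard errors
wide.

## What the phantom does and does not show

Passing recovery tests demonstrates that the estimators, ROI logic,
histogram metrics and statistics are correct and unbiased at realistic
SNR, and that the published group-level signature (T1 elevation, CMD
loss, dispersion increase with preserved mean ADC) is reproduced when the
tissue truth matches the published means. The phantom does not emulate
between-animal biological variability (all subjects in a cohort share one
truth; group scatter comes from measurement noise only), partial-volume
effects at compartment borders, motion/respiratory artifacts, EPI
distortion, fat signal, T2* decay, or multi-compartment diffusion (IVIM,
DTI). Conclusions about real-data robustness to those effects are out of
scope.
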