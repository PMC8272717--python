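# Methods

## Reliability model

For n subjects measured in k = 2 sessions, a voxel's parameter values are
modeled with the two-way mixed-effects decomposition underlying ICC(3,1):
subject effects are random, session effects fixed, and the estimator

    ICC(3,1) = (BMS − EMS) / (BMS + (k−1)·EMS)

is the Shrout–Fleiss consistency form for a single measurement. Additive
session effects (global drift between visits, scanner recalibration) do not
reduce it; negative estimates are reported as-is rather than floored at
zero, because systematic negative values are diagnostic (they indicate that
within-subject variance exceeds between-subject variance, as happens for
parameters that are pure noise). Other ICC classes — (1,1), (2,1), absolute
agreement — are not implemented; the decomposition dataclass exposes the
mean squares needed to add them.

Before the voxelwise ICC, values are Windsorized across participants,
per session and per voxel: Tukey's median-inclusive fold hinges H1, H2 are
computed (hinge depth (⌊(n+1)/2⌋+1)/2, half-integer depths averaging
adjacent order statistics — not interpolated quartiles), and values beyond
1.5 H-spreads outside the hinges are clipped to the nearer fence. Clipping,
not trimming, preserves n. Windsorizing is applied per session; applying it
once to the pooled sessions would let one session's outliers move the other
session's fences. Subjects missing a voxel's estimate are dropped listwise
at that voxel; below 3 complete subjects the voxel is NaN.

Covariate-adjusted reliability uses the semi-partial correlation of the
session-1 value in `post ~ intercept + covariates + pre`:
sr = sign(β_pre)·√(R²_full − R²_without_pre), which reduces exactly to the
Pearson correlation when no covariates are given. Missing covariates are
imputed deterministically by OLS regression of each covariate on the
covariates observed for that subject, fit on complete cases. Model AICs use
the Gaussian likelihood with the ML variance estimate and
k = predictors + intercept + variance, so with/without-covariate comparisons
are on a fixed, documented convention.

## BOLD reactivity models

The canonical regressor is a boxcar event train convolved with a
double-gamma HRF (positive lobe Gamma(6,1) peaking at 5 s, undershoot
Gamma(16,1) peaking at 15 s, ratio 1/6), peak-normalized to 1 so the GLM
beta is in signal units. Drift is modeled with Legendre polynomials on
[−1, 1] (numerically stable against raw powers); all GLMs are ordinary
least squares, vectorized across voxels.

The FIR model places one delta regressor per post-onset lag (8 lags for the
event design, block-length/TR lags for 40-s blocks) and requires the
inter-onset interval to be at least the FIR window — the slow-event-related
condition under which the deconvolution is unbiased. Peak amplitude is the
signed maximum over the response lags (exactly-zero betas are treated as
no-response lags, so a purely negative response has a negative peak); AUC
is the signed sum.

The gamma-variate model g(t) = h·(r(t−δ)/α)^α·exp(α−r(t−δ)) has fixed shape
α = 6 so that exactly the three named parameters — onset-delay δ (s, bounded
to [0, t_max/2]), rise–decay rate r (1/s, bounded to [0.05, 10]) and height
h (signal units, unbounded, so inverted responses fit with h < 0) — are
free; with 8 FIR points a free shape would not be identifiable. The fit is
bounded trust-region least squares with three onset starts {0, Δt, 2Δt},
tie-broken by SSE. It targets the FIR curve (or the block-averaged feedback
trace), not the raw series: a two-stage fit is far cheaper and inherits the
GLM's drift handling. The generative HRF of real data is unknown and is not
claimed to match either form; in the simulator the generating double gamma
and the fitted gamma variate are deliberately different families, so
parameter recovery is a genuine estimation problem.

Degenerate-fit rule: a curve is flagged degenerate (parameters 0, no
optimization) when its peak magnitude is at most twice a robust noise scale
estimated from first differences (1.4826·MAD(Δ)/√2), or when it has no
range at all (constant curves). Optimizer failure also yields a degenerate
flag, never an exception; degenerate-fit counts are logged. On noise-only
voxels this rule produces the characteristic mass-degenerate rise–decay
maps (all zeros with zero variance).

## Synthetic data generator

The generator emulates two designs: a slow event-related task (default 30
trials, 12 s ISI, 1 s events, TR 1.5 s — the ISI equals the 8-TR FIR
window) and a 40-s rest/regulate/count block neurofeedback protocol
(4 cycles, TR 2 s), both over 2 sessions.

Every in-mask voxel belongs to an amplitude class with mean μ and variance
components (σ_b, σ_w); subject i's true amplitude in session j is
μ + b_i + e_ij with b ~ N(0, σ_b²), e ~ N(0, σ_w²), so the class's
population reliability is σ_b²/(σ_b²+σ_w²) — the quantity the pipeline
should recover. Defaults: a reliable class at true ICC 0.75 and an
unreliable class at 0.10 (spanning the range reported for task fMRI), mean
amplitude 2 with total amplitude SD 1, plus a null class with no response.
The time series is amplitude × canonical response, plus random Legendre
drift (degree 2, coefficient SD 0.5) and noise built as spatially smoothed
(FWHM 6 mm on 3 mm voxels, variance-renormalized by the exact kernel ℓ2
norm) AR(1) Gaussian noise (ρ = 0.3, started in its stationary
distribution), SD 0.5. At these settings the GLM amplitude SE is ≈ 0.07 —
small against the amplitude SD of 1 — so estimated voxelwise ICCs are
attenuated by only ~1–2% from their generative values; reliability
recovery experiments measure the pipeline, not a noise-floor artifact.

Session-2 amplitudes can be shifted by covariate effects (per-covariate
coefficients on z-scored clinical scales) and by a random per-subject
"training" shift. The training shift SD of 1.5 used in the neurofeedback
experiments makes training-response heterogeneity comparable to the
between-subject spread — the regime consistent with reliable signals
becoming unreliable after training. Covariates (BDI pre/post, state/trait
anxiety, rumination, sleepiness, scanner, group) are drawn at plausible
clinical-scale means/SDs; the patient fraction defaults to 57/92.

Each subject consumes an RNG stream spawned from the master seed keyed by
subject index, so growing the cohort never reshuffles existing subjects,
and fixed seeds give bit-identical datasets.

What the simulator does **not** emulate: motion and its interaction with
smoothing, physiological noise structure beyond AR(1), field inhomogeneity,
inter-subject anatomical variability (data are generated registered), or
the true (unknown) hemodynamics of clinical populations. Passing recovery
tests therefore demonstrates correctness of the estimators and calibration
procedures under the stated generative model, not expected effect sizes in
real cohorts.

## Preprocessing streams

Two post-hoc streams operate on registered data: a real-time-style stream
(4 mm FWHM Gaussian smoothing, then a separate fourth-order Legendre
detrend pass — whether real-time packages detrend inside or outside the GLM
is not fully specified, and the separate pass is the simpler documented
choice) and a standard stream (4 mm smoothing, then a nuisance GLM with
motion parameters and their backward-difference derivatives, white-matter
and CSF series, and five polynomial drift terms). Collinear nuisance
columns are pruned with a logged warning, never silently. Both drift steps
are idempotent, and the streams coincide exactly when the nuisance set is
restricted to the matching polynomials. Motion correction, despiking and
slice timing are out of scope: inputs are assumed registered, which is true
by construction for the synthetic data.

## Ranking the 12 conditions

The ranked value is the ICC for no-covariate conditions and |sr| for
covariate conditions, placing both reliability indices on a common
higher-is-better footing. Within each voxel the 12 conditions get average
ranks (rank 12 = most reliable); a Kolmogorov–Smirnov check against a
normal with the sample moments (anti-conservative in the Lilliefors sense —
used only to justify going nonparametric) precedes a tie-corrected
Kruskal–Wallis omnibus test, and per-condition CIs are mean rank ±
t(1−α/(2m), N−m)·√(MSE/n_voxels) from the one-way ANOVA on ranks with
Bonferroni's m = 12. Disjoint CIs are read as significant differences.
Voxels are treated as independent observations; spatial correlation makes
these tests anti-conservative, which is documented rather than corrected
(a spatially aware mixed model is out of scope). Condition subsets can be
re-run (e.g. dropping uniformly degenerate parameterizations) via
`ConditionGrid.drop_conditions`.

## Cluster-extent calibration

Under the voxel null of zero true ICC, F = BMS/EMS ~ F(n−1, (n−1)(k−1)),
so an ICC threshold θ maps to p = P(F ≥ (1+(k−1)θ)/(1−θ)); the inverse map
is solved by root-finding on the forward map itself because F quantile
functions lose precision at very small p.

Spatial smoothness is estimated by the distance-binned pairwise-product
method: FFT autocorrelation of demeaned, mask-zeroed volumes normalized by
the mask-overlap count, binned in 1-voxel shells to 20 mm (each shell
represented by its weighted mean pair distance — using bin centers biases
the fit because a shell mixes axial and diagonal offsets), then a weighted
least-squares fit of ACF(r) = a·exp(−r²/2b²) + (1−a)·exp(−r/c), with a
single-Gaussian fallback on fit failure.

Null fields matching a fitted ACF are generated spectrally: the model ACF
evaluated on the wraparound lag grid is Fourier-transformed to a power
spectrum (negative values from ACF truncation clipped), and white noise is
filtered by its square root with an exact unit-variance normalization.

Minimum cluster extent: the smallest s such that the fraction of null
iterations whose largest supra-threshold cluster reaches s is ≤ α.
Two null models are provided. The fast Gaussian mode thresholds single
fields at the p-quantile; it is exact only if the Gaussianized ICC map is
itself a Gaussian field with the supplied ACF, and measurement shows the
approximation is second-order only — with the residual-map ACF it is far
too conservative (ICC maps are spatially rougher than the amplitude maps
they derive from), and even with the ACF of the Gaussianized ICC map the
realized familywise error runs slightly below nominal, because the
excursion sets of the ICC statistic field are smaller than Gaussian-field
excursions at matched second-order structure. The exact mode therefore
draws n×k ACF-matched amplitude fields per iteration — amplitude estimates
genuinely are Gaussian under the null — and computes the actual ICC map;
it costs a factor n·k more FFTs and is the default in the pipeline and
the validation experiments, where it calibrates to FWE ≈ 0.05. Default
connectivity is face adjacency (6; 18/26 configurable); small-volume
correction is simulation within the ROI mask itself.

## Neurofeedback signal

The feedback trace is the regulate-block signal at each TR minus the mean
of the immediately preceding rest block — absolute difference by default
(a percent-signal-change option divides by the rest mean), making the
trace invariant to constant offsets in the series. Count blocks never
enter the computation. Traces are averaged pointwise across regulate
blocks and summarized per visit by the mean or a gamma-variate fit; both
the ROI-route (summarize, then ICC across subjects) and the voxelwise
route (parameter maps, then ICC maps) are supported, and they coincide for
a one-voxel ROI. Visits are paired by subject ID; unpaired subjects are
dropped with a log entry.

## Problem sizes and numerical choices in the validation experiments

Reliability recovery runs 100 subjects × 300 voxels per true-ICC level;
ranking power, 50 subjects × 300 voxels × 100 replicates at the amplitude
level (the ranking procedure consumes reliability values, so simulating
time series adds nothing to that check); cluster calibration, 20 subjects
on a 20×20×12 grid with 2000 calibration and 2000 validation iterations —
validation draws fresh amplitude maps directly from the smoothed-noise law,
which under the null is exactly the distribution of the GLM amplitude
estimates; the subregion demonstration, 60 subjects on 500 voxels with a
20%-volume reliable cuboid; the neurofeedback contrast, 100 replicate
pairs of 16 untrained / 18 trained subjects. These sizes keep the full
validation run to a few minutes on one CPU while leaving Monte-Carlo error
well inside each tolerance.

## Known limitations

- Real-data preprocessing (motion, slice timing, normalization) is out of
  scope; inputs must be registered.
- The canonical regressor is exactly the double-gamma model documented
  above; no bit-compatibility with other packages' canonical bases (e.g.
  AFNI's BLOCK family) is claimed.
- The ranking stage's independence assumption over voxels is
  anti-conservative under spatial correlation.
- ICC classes other than (3,1) and dispersion/derivative HRF bases are not
  implemented.
- The cluster-null machinery addresses the reliability-map use case; it is
  not a general replacement for task-activation cluster inference.
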