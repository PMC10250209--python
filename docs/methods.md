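# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Residence times and the CRTD

Dwell times of a protein on DNA are modeled as exponential with rate
k_eff. Facilitated dissociation enters through the rate law
k_eff = k_intrinsic + k_fd · [competitor]: a bound protein leaves either
spontaneously or because a competitor displaces it, at a rate proportional
to competitor concentration. This linear rate law is the simplest
mechanistic stand-in consistent with a concentration-dependent acceleration
of departure; it guarantees (and the test suite asserts) that mean dwell
time decreases monotonically with competitor concentration.

The cumulative residence time distribution is S(t) = P(T ≥ t). Because
movies last a finite observation window (default 300 s), particles bound at
the movie end are right-censored: their recorded duration (equal to the
window) is a lower bound, and the censored flag is data — never silently
dropped. Two CRTD constructions are exposed:

* **censored (default):** a product-limit (Kaplan–Meier) estimator
  evaluated with the ≥ convention, S(t) = Π_{s<t} (1 − d_s/n_s), where
  censored particles stay in the at-risk denominator n_s up to their
  censoring time but never count as events d_s. With no censoring this
  reduces to simple counting, S(t) = #{T ≥ t}/n.
* **naive:** censored records are dropped before counting. This estimator
  is deliberately retained because it corresponds to analyzing "only the
  particles seen to dissociate"; on a simulated 4950 s half-life observed
  through a 300 s window it underestimates the half-life by more than
  5-fold, while the censored-aware estimator recovers it to within ~25 %
  (asserted in the tests).

The fit is least squares of S(t) against e^(−kt) with S(0) = 1 fixed (no
free amplitude), k parameterized on the log scale to enforce positivity,
and requires at least five support points with S < 1. The half-life is
ln 2 / k. On uncensored samples of n = 1000 the median relative half-life
error is under 5 % (200-seed simulation in the tests).

## Trajectory simulation: fractional Brownian motion

No generative model of the motile phases is implied by the experiments
themselves; fractional Brownian motion (fBm) is the standard
single-particle-tracking choice for motion with a power-law MSD and is used
here as an explicit stand-in. Trajectories are generated with exact
covariance via Davies–Harte circulant embedding of fractional Gaussian
noise (O(n log n)); if the embedding is not nonnegative definite (possible
at very small n with Hurst exponents near 1) the code falls back to a
Cholesky factorization of the exact covariance matrix. Increments are
scaled so the true MSD is 2 D t^α with t in seconds: for α = 1, D is the
ordinary diffusion coefficient in μm²/s; for α ≠ 1 it is the generalized
coefficient in μm²/s^α. Independent Gaussian localization noise of sd
0.04 μm (typical for quantum-dot tracking) is added per frame;
configurable, and zero for exact round-trip tests.

Defaults mirror the imaging conditions: 0.08 s frame interval (12.5 fps;
the experiments ran at ~11–12.5 fps), 300 s observation window, positions
carried in both μm and kb with 1 bp = 0.34 nm (2941 bp/μm).

What the generator does **not** emulate: quantum-dot blinking and
photophysics, flow-cell geometry and tightrope mechanics, focus drift, and
any lesion-specific pausing structure. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
model, not robustness to every artifact of real movies.

## MSD estimation and fitting

`compute_msd` implements the overlapping-pair time-averaged MSD,
MSD(nΔt) = 1/(N−n) Σ_{i=1}^{N−n} (x_{i+n} − x_i)², for all lags (a
`max_lag` cap is available because the computation is quadratic and the
large-lag tail is statistically useless). A property test pins it to an
independent O(N²) brute-force double loop on every trajectory up to 200
frames.

The diffusion coefficient comes from ordinary least squares of
MSD on lag time over the first 25 % of lags (configurable), with lags
averaged over fewer than 3 pairs excluded — the variance of the MSD
estimator explodes at large lag. D = slope/2; the intercept absorbs static
localization noise (≈ 2σ², asserted on noise-on vs noise-off ensembles).
Fits with R² < 0.8 or using < 10 % of the MSD plot are flagged
`accepted=False`; the flags are pure functions of (R², fraction used) and
are recorded on every fit object, never applied silently.

The anomalous exponent α is the slope of log MSD vs log lag time over the
same window (the estimation method and lag range are free choices here;
log–log regression over the first quarter of lags is standard
single-particle-tracking practice and both knobs are recorded). The
intercept gives the generalized coefficient D_α = e^intercept/2.

Two estimator-level facts drive how group recovery is done:

1. Per-trajectory log–log fits are biased low (Jensen's inequality acting
   on the noisy large-lag MSD), so group-level recovery uses the
   **ensemble-averaged** time-averaged MSD — average the curves over
   trajectories, then fit once.
2. With 0.04 μm localization noise, the noise floor 2σ² = 3.2×10⁻³ μm²
   exceeds the true MSD at the first one or two lags for the measured
   diffusivities (e.g. 2·0.0265·0.08^1.36 ≈ 1.7×10⁻³ μm²), biasing α
   toward 0 there; ensemble fits on noisy data therefore exclude the
   first two lags (`min_lag=3`).

With these choices, 120-trajectory ensembles of 500 frames at the two
measured operating points, (α = 1.36, D = 2.65×10⁻²) and (α = 1.37,
D = 2.17×10⁻²), are recovered within 0.1 in α and 15 % in D — with
realistic noise on; noise-free recovery is within ~0.02 and ~2 %.

For the linear-fit D at α = 1 the per-trajectory estimates are unbiased
and their ensemble mean recovers the truth within a few percent, so no
special handling is needed there.

## Kymograph extraction and phase segmentation

Rendering (synthetic): one column per frame, a Gaussian spot of width
`psf_sigma_px` (default 1.5 px at 0.1 μm/px) on a constant background,
with Poisson, Gaussian, or no noise.

Extraction: per column the background is the median, the noise a robust
MAD estimate, and the spot either the background-subtracted intensity
centroid or a 1D Gaussian fit seeded from it (falling back to the centroid
if the fit diverges). Columns below `min_snr` (default 3) are gaps: runs of
up to 2 missing columns are linearly interpolated (quantum dots rarely go
dark for long), and a run of 3 or more ends the trajectory and flags it as
a dissociation candidate — sustained signal loss is treated as
dissociation, and the flag travels with the trajectory so downstream
analyses can distinguish it from movie end. Noise-free round trips recover
positions to < 0.05 px; at SNR 10 the Gaussian method's RMS error is below
psf_sigma/5 (Monte-Carlo over 100 seeded columns).

Segmentation into stationary/motile phases is the one genuinely
under-specified step in this kind of analysis, so it is a single explicit
knob: a sliding-window (default 10-frame) position standard deviation is
compared with a motion threshold defaulting to 3× the localization
precision — supplied directly, or estimated from the quietest windows
(10th percentile of the rolling sd) when the trajectory has a stationary
stretch. A particle that never pauses has no quiet window, so for
population work the precision should be passed in from stationary control
particles or the imaging configuration. Runs shorter than the window are
merged into their neighbors; trajectories shorter than the window get one
global label. A particle is classified motile iff it has at least one
motile phase.

## Tight-binding isotherms

At 8 nM DNA the free-protein approximation fails, so percent bound follows
the quadratic (ligand-depletion) solution of mass action:
100 · ((D+P+K_d) − √((D+P+K_d)² − 4DP)) / (2D). The fit floats only Kd
(log-parameterized for positivity; initial guess = the concentration
nearest half-maximal binding), with the DNA concentration fixed at its
known value and the plateau at 100 %. Replicates enter jointly rather than
being averaged first, preserving the error structure. The model reduces to
the hyperbola P/(P+Kd) within 0.2 percentage points when D ≤ Kd/1000
(property-tested), and parameter recovery at 5 % noise has < 10 % median
error across Kd ∈ [0.4, 125] nM when the titration spans the transition
(the synthetic titrations place 10 log-spaced concentrations from
max(Kd, D)/16 to 16(Kd + D), which is how a practitioner designs an EMSA
ladder).

Specificity folds are computed from unrounded Kds and reported to one
decimal. Native-PAGE band fractions subtract a per-lane background from
both the bound sum and the lane total (an explicit background value is
required per lane; which gel region it comes from is an acquisition
decision outside this package).

## Excision kinetics

Percent product per lane is 100(P−bg)/((P−bg)+(S−bg)) with bands floored
at background; the quantity is invariant to uniform lane rescaling.
Complete NaOH nicking at abasic sites is assumed (quantification, not
chemistry, is modeled). Time courses are fit to A(1 − e^(−k_obs t));
when k_obs·t_max < 0.2 the amplitude and rate are not separately
identifiable and the fit falls back to a through-origin initial-rate slope
with the amplitude flagged.

Fold stimulation defaults to the endpoint basis — the ratio of percent
product at a stated reference time, matching how per-time-point gel
comparisons are made — with an initial-rate basis available. For the rate
basis the default estimator fits the two curves jointly with a **shared**
rate constant (both conditions probe the same enzyme and substrate), which
removes the (A, k) trade-off that makes independent initial-rate ratios
noisy on shallow curves; independent fits remain available via
`shared_rate=False`. In the linear regime both bases agree within 5 %
(asserted on synthetic data). The concentration-response summary reports
the argmax concentration (all ties), the step pattern, and whether the
profile is rise-then-fall — the biphasic signature of an optimal
accessory-protein concentration.

## Co-localization and behavior tables

Two-color pairing is greedy nearest-neighbor under a distance threshold
(default 0.5 μm ≈ 1.5 kb, about the scale at which two quantum-dot point
spread functions overlap; no threshold is dictated by the experiments) and
a temporal-overlap requirement (default 10 frames). Each particle joins at
most one pair; the co-localized fraction is pairs/(A-only + B-only +
pairs). On the synthetic lesion-array generator, whose 2 kb spacing is at
least twice the pairing radius, precision and recall are exactly 1.

Behavior tables cross motile/stationary with persistent/dissociating
(dissociating iff the particle's visible span (last_frame+1)·Δt is shorter
than the observation window). Condition comparisons use the Pearson
chi-square on the dissociating-vs-persistent × condition table without
continuity correction (the large-sample convention); a zero expected cell
raises an error suggesting an exact test. Under a simulated null the
type-I error at α = 0.05 is calibrated within [0.03, 0.07].

## Problem sizes and determinism

Simulation-backed checks use sizes chosen to make estimator bias visible
while keeping each check to seconds: 1,000 dwell times per CRTD recovery,
200 seeds for unbiasedness sweeps, 120 trajectories of 500 frames for
(α, D) recovery, 20-trajectory ensembles of 10⁴ frames for the fBm scaling
property. Every stochastic operation takes an explicit seed; identical
parameters and seed give bit-identical outputs, and the pipeline embeds a
hash of its resolved configuration (excluding the output directory) in
every report it writes.

## Known limitations

* The fBm generator is a modeling choice, not an inference about the true
  motion mechanism; α and D recovered from real kymographs inherit the
  estimator choices (lag window, min_lag) recorded on the fit objects.
* The censored-aware CRTD still extrapolates a single exponential from the
  observed window; when the window is much shorter than the half-life the
  extrapolation is honest but wide (the 4950 s recovery through a 300 s
  window is ~25 %, not 5 %).
* Two-exponential or heterogeneous dwell models, HMM diffusive-state
  segmentation, cooperative binding, and gel densitometry are out of
  scope; intensities and dwell tables arrive as data.
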