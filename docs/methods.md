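# Methods

`gridsep` asks whether a grid cell's position tuning and velocity tuning are
separable: can the firing rate over the 4D behaviour space
b = (x, y, vx, vy) be written as a product f_pos(x, y) · f_vel(vx, vy), with
velocity acting as a pure gain on one invariant spatial map?  The package
fits both an unconstrained 4D tuning-curve model (Gaussian-process
regression) and the factorized alternative to the same binned data, and
quantifies non-separability per cell with two statistics: the
cross-validated difference in explained variance (ΔFVE) and the standard
deviation of cosine similarities across velocity bins (SDCS), calibrated
against a velocity-independent null model.

## Binning

Positions in a 1.5 m × 1.5 m arena (origin at the centre) are binned at
5 cm, velocities at 10 cm/s over ±25 cm/s: 30 × 30 × 5 × 5 = 22,500 bins.
Velocity is the finite difference of the Gaussian-smoothed trajectory
(σ = 50 ms at 10-ms resolution, reflected boundaries; the smoothing width
suppresses tracker-style jitter without blurring turns).  Samples with
|vx| or |vy| > 50 cm/s are treated as artifacts and dropped; samples with
25 < |v| ≤ 50 cm/s survive that filter but fall outside the binning range
and contribute to nothing.  A bin's rate is total spikes over total
occupancy seconds; unvisited bins are NaN, never zero (silence is data,
absence is not).  Bins with ≥ 10 visits (100 ms of occupancy) form the
"high-occupancy" set used for model fitting and scoring.  Velocity bin
edges are −25, −15, −5, +5, +15, +25 cm/s so the middle bin is centred on
zero velocity; position edges are −75, −70, …, +75 cm; all bins are
half-open [lo, hi) with the final bin closed.

## The GP tuning-curve model

The rate over the 4D space is modelled as a GP with constant mean (the
training-target mean), a Matérn ν = 5/2 kernel with one lengthscale per
dimension (automatic-relevance form, a single 4D kernel rather than a
product of 1D kernels), and a Gaussian likelihood.  Hyperparameters are
initialised at lengthscale 10 (cm or cm/s) per dimension and signal
variance 0.3 Hz², and optimised by maximising the log marginal likelihood
with L-BFGS-B on log parameters (analytic gradients, gradient-norm
tolerance 1e-5, iteration cap 200 by default).  A jitter of 1e-6 × signal
variance is added to the kernel diagonal before factorisation.

Four numerical choices matter and are deliberate:

- **Heteroscedastic noise.**  The likelihood noise of each training bin is
  scaled by 1/(occupancy seconds), normalised to unit mean.  A binned rate
  c/t has sampling variance ≈ r/t, so bins near the 10-visit threshold are
  ~an order of magnitude noisier than well-visited bins.  With a single
  shared noise variance the GP over-trusts barely-visited bins and
  "hallucinates" velocity structure from their noise; the null-model SDCS
  distribution (below) then grows a heavy right tail and real effects
  cannot clear it.  The 1/t scaling is the Gaussian approximation to the
  binned-Poisson noise and removes that failure mode.
- **Lengthscale bounds.**  During optimisation each lengthscale is bounded
  below by its dimension's bin width (5 cm, 10 cm/s) and above by 20× the
  dimension's range.  On binned inputs a sub-bin lengthscale is
  unidentifiable; without the bound the optimiser frequently falls into a
  degenerate mode (position lengthscales of 0.2–3 cm) that reproduces
  per-bin noise exactly.
- **Multi-start.**  The marginal likelihood is multimodal on noisy rates.
  Optimisation runs from two inits — the standard one and a
  "velocity-smooth" variant with velocity lengthscales at twice the
  velocity range — and the better optimum is kept.
- **Two-stage fitting.**  Optimising hyperparameters costs O(n³) per
  optimiser step; conditioning the posterior costs one O(n³)
  factorisation.  Hyperparameters are therefore optimised on a random
  subset of at most `hyper_train_bins` (default 1000) training bins and
  the posterior is conditioned on up to `max_train_bins` (default 3000)
  bins, subsampled uniformly at random when the training set is larger.
  When the training set fits the hyper budget the fit is a plain exact GP.
  Oversized training sets are reduced by keeping the most-visited bins
  (seeded random tie-breaking), i.e. the bins whose rates are least
  noisy; uniform random subsampling is available as an option and can be
  preferable at small posterior budgets where occupancy ranking would
  concentrate training too narrowly on low-speed bins.

Predictions (mean and standard deviation) are the latent, noise-free GP
posterior at all 22,500 bin centres, including unvisited bins; negative
predicted means are reported as-is, not clipped.  Predictive standard
deviation reverts to the prior (√signal-variance) far from data, so edges
and corners of the behaviour space show the largest uncertainty.

### Cross-validation and FVE

High-occupancy bins are split into k = 5 disjoint validation folds
(seeded); each fold's model trains on the other 80%.  Performance is the
fraction of variance explained on the held-out fold,
FVE = 1 − Var(held − pred)/Var(held) with population variances, averaged
over folds; the reported 4D estimate is the average of the five
predictive means.  The same (train, validation) splits — produced once by
`make_cv_splits` — are passed to both the GP and the separable model so
that ΔFVE = FVE_GP − FVE_sep compares models on identical data.

## The separable model

The alternative model r̂(x, y, vx, vy) = f_pos(x, y) · f_vel(vx, vy) with
nonnegative factors (900 + 25 parameters) is fitted by projected gradient
descent on the squared error summed over training bins: a simultaneous
gradient step on both factors, then an elementwise clamp at zero.  The
raw gradient is badly conditioned — the curvature of a factor entry
scales with the number of training bins it touches, which differs between
the two factors by the 900/25 size ratio and with data density — so each
step is preconditioned by the exact per-coordinate second derivative
(other factor fixed), making the step size `lr` a dimensionless
relaxation factor (default 0.3).  Targets are internally rescaled to unit
RMS (restored afterwards), iteration cap 5000 with early stop when the
best loss improves by < 1e-8 (relative) over 100 iterations; the
best-loss iterate is returned.  Factors are initialised at
√(grand mean) × uniform(0.5, 1.5), seeded.  For reporting, f_vel is
normalised to unit mean with the scale absorbed into f_pos (a pure gauge
choice; predictions are unchanged).

By default the squared error is weighted by each bin's occupancy
seconds (normalised to unit mean).  This places the separable fit on the
same inverse-variance noise model as the heteroscedastic GP, so that
ΔFVE compares the models' expressiveness rather than their noise
handling: with an unweighted loss the separable model overfits the
noisiest (barely-visited) training bins and loses held-out FVE for
reasons unrelated to separability, biasing ΔFVE positive even for
exactly separable ground truth.  ``weighting="none"`` restores the plain
unweighted loss.

Fold fits use only that fold's training bins (honest held-out FVE);
consensus factors for reporting are fitted once on all high-occupancy
bins.

## Non-separability statistics

For each velocity bin (i, j), c(i, j) is the cosine similarity between
the position map restricted to that bin and the velocity-marginalised
position map (occupancy-weighted for binned curves; plain velocity-mean
for GP estimates).  For binned sources each inner product is restricted
to position bins defined in both maps; undefined entries (empty slices)
are excluded rather than imputed.  SDCS is the population standard
deviation of the defined c(i, j): exactly zero for separable tuning,
positive when fields shift, appear or disappear across velocity bins.
SDCS is scale-invariant (multiplying the 4D rate by any a > 0 changes
nothing).

Estimation noise alone produces positive SDCS, so each cell's score is
compared with a null distribution: sessions whose spikes are Poisson
draws from the cell's zero-velocity position map (the centre velocity
bin's 2D slice, nearest-bin lookup) along the same trajectory, analysed
with the same GP settings.  A cell is flagged non-separable when its
SDCS exceeds the null 95th percentile.  Because null replicates are
scored with a single GP fit on all high-occupancy bins (a fifth of the
cost of the k-fold fit), the cell's score for this comparison is computed
with that same single-fit procedure; the fold-averaged SDCS is reported
alongside.  In multi-cell sessions the pipeline builds the null per cell;
the acceptance experiments pool null scores across cells of a session
(cells share trajectory, grid scale and statistics, differing only in
phase and orientation, so their null scores are exchangeable), which
keeps ≥ 20 replicates per comparison at session level.

## Grid properties

Grid score and scale come from the rate map's spatial autocorrelogram:
Pearson correlation at each 2D lag over overlapping defined bins (lags
with < 20 overlapping bins are undefined — correlations over a handful of
corner bins are meaningless).  Peaks are 8-neighbourhood local maxima of
the lightly smoothed (σ = 1 bin) autocorrelogram with positive
correlation, after masking the contiguous region ≥ 0.5 around lag zero;
grid scale is the mean distance of the six peaks nearest the centre
(× 5 cm), grid score is the mean annulus correlation (0.5–1.5 × scale,
bilinear rotation sampling) at 60°/120° minus that at 30°/90°/150°.
Ideal hexagonal maps score > 1; isotropic bumps ≈ 0; square lattices < 0.

## The synthetic generator

The generator emulates the study conditions so every stage is testable
without recordings:

- **Trajectory:** Ornstein–Uhlenbeck velocity (stationary std 12 cm/s per
  axis, correlation time 1 s) integrated at 10 ms and folded into the
  arena by reflection.  This reproduces near-uniform position occupancy
  and a zero-mode velocity distribution with ≳ 90% of samples inside
  ±25 cm/s on both axes (mean speed ≈ 15 cm/s, unhurried foraging).  It
  does not emulate wall-following, theta-modulated locomotion bouts,
  reward-directed runs, or tracker noise.
- **Rate maps:** three-cosine hexagonal interference patterns rescaled to
  [0, peak_rate] (default peak 15 Hz, scale 50 cm), with four velocity
  modulations: `none`; `gain` (positive function of speed — separable by
  construction); `shift` (map evaluated at the velocity-lagged position,
  lag default 0.25 s ≈ one 5-cm bin at 20 cm/s — non-separable);
  `dropout` (logistic suppression of one half of the arena above a speed
  threshold, smooth in both variables so GP smoothness assumptions are
  not artificially violated — non-separable).
- **Spikes:** conditionally independent Poisson counts given behaviour;
  no theta oscillations, refractoriness, or inter-neuron noise
  correlations.

Because spikes are exactly Poisson and maps exactly hexagonal, passing
tests show the estimators recover what they claim under the model's own
assumptions; they do not certify robustness to non-Poisson firing,
unstable maps, or sorting errors in real recordings.

## Problem sizes in the test suite

The full study (hour-plus sessions, hundreds of cells, GP fits on every
high-occupancy bin) used GPU acceleration; the test suite and acceptance
script run on one CPU, so the experiments are scaled: the
dense-coverage separability experiment uses one 2-hour simulated session
shared by 10 shift-modulated cells (the coverage regime in which the
study's one high-coverage session detects non-separability), GP posterior
conditioning capped at 3000 bins, hyperparameter stage at 500 bins with
a 40-iteration cap, and 20 pooled null replicates; the
coverage-dependence experiment repeats this with a 5× shorter session.
The 2D reconstruction experiment matches the stated protocol exactly
(30-minute sessions, 50% training fraction, 10 replicates).  All seeds
derive deterministically from a single global seed via
`gridsep.pipeline.stage_seed`.

## Known limitations

- The exact-GP budget truncates training data; with ~15k high-occupancy
  bins available, a 3000-bin posterior attenuates small SDCS effects.
  Detection power at desk scale is accordingly lower than in the original
  GPU-scale analysis.
- The separable fit solves a non-convex problem; the preconditioned PGD
  matches an alternating-least-squares oracle on small tensors but both
  can in principle share a non-global optimum.
- The linear-mixed-effects layer over ΔFVE (animal as random effect) is
  out of scope; the per-cell CSV is shaped so it can be run externally.
- Null calibration assumes the zero-velocity slice is a faithful
  velocity-free map; in very short sessions that slice is itself noisy
  and the null correspondingly conservative.
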