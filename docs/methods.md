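# Methods

## The model

During smooth pursuit, perceived object velocity with respect to the head
is modeled as the sum of two independently estimated components:

* **R** — relative motion of the stimulus with respect to the pursuit
  target (image motion independent of the eye movement), and
* **T** — motion of the pursuit target with respect to the head.

Each channel delivers an unbiased but noisy measurement of its true input,

    m_X ~ N(v_X, sigma_X(v_X)^2),   sigma_X(v) = a_X * |v|^b_X + c_X,

so measurement precision falls with speed.  Each measurement is combined
with a zero-centered Gaussian prior over velocity ("objects tend to be at
rest") of width `sigma_p`, shared by both channels.  Under the Gaussian
approximation, the posterior peak is the familiar shrinkage estimate

    X' = w * m,   w = sigma_p^2 / (sigma_p^2 + sigma_X^2),

and the perceived head-centered velocity is `H' = R' + T'`.  MAP and
posterior mean coincide under the Gaussian approximation; the output is
simply called the "estimate".

### Where the likelihood width is evaluated

The width `sigma_X` inside the shrinkage weight can be conditioned on the
nominal (true) stimulus speed, `sigma(|v|)`, or on the measured speed,
`sigma(|m|)`.  Both modes are implemented throughout the pipeline
(generator, response probabilities, Monte-Carlo oracle, fitting, illusion
predictions); the pipeline default is the **true-speed mode**.  Three
considerations drove that choice:

1. *Tractability and shape.*  In true-speed mode the estimate is linear in
   the measurement, each interval's `H'` is exactly Gaussian, response
   probabilities are closed-form, and model psychometric functions are
   exact cumulative Gaussians — consistent with how such data are
   summarized in practice.
2. *Identifiability.*  In measured mode the estimator `w(|m|) m` is
   non-monotone for small priors, and the seven-parameter model acquires a
   mimicry regime (small `sigma_p`, small exponents `b`) whose likelihood
   on realistic session sizes matches or beats the generating parameters.
   Simulation at the reference design scale shows the measured-mode ML
   estimate landing in that regime in roughly a third of replicates, which
   makes parameter recovery unreliable; the true-speed model has no such
   regime and recovers cleanly.
3. *Speed.*  Closed-form probabilities make joint fits roughly forty times
   faster, which matters for bootstraps and recovery experiments.

The measured mode (`mode="measured"`) remains a first-class sensitivity
path, and the single-measurement estimator `bayes_estimate` keeps the
measured-width form as its default, since a lone measurement carries no
true speed.  An exact numerical MAP that maximizes
`N(m; v, sigma(|v|)^2) * N(v; 0, sigma_p^2)` over `v` is also provided.

When the T channel is noisier than the R channel — plausibly because the
target-motion signal combines extraretinal eye-velocity information with
retinal slip — its estimate is shrunk more, and a single asymmetry produces
the whole family of pursuit illusions at once: pursued stimuli appear
slower (Aubert-Fleischl), stationary backgrounds appear to drift against
pursuit (Filehne), trajectories of moving objects tilt during pursuit, and
the inferred eye-velocity gain ratio falls below 1.

The decisive structural claim is *where* the prior applies.  If the two
measurements were summed first and a single head-centered likelihood were
shrunk toward zero, no Filehne illusion or trajectory error could ever
arise: in those scenes the summed measurement is centered on the true
head-centered velocity (zero, or purely vertical), and a zero-centered
prior can compress magnitude but never displace a posterior that is already
centered on zero, nor rotate a direction.  The package implements this
summed-likelihood alternative (`summed_model_predictions`) so the null
predictions can be verified directly; they hold identically for every
parameter setting, by symmetry of the construction.

## Decision stage

A two-interval trial presents a standard and a comparison interval.
Fixation intervals map to scene inputs `(r = speed, t = 0)`; pursuit
intervals to `(r = 0, t = speed)`.  The observer draws fresh measurements
in each interval, forms `H'` per interval, and chooses the comparison iff
its `H'` is larger.  Only which interval holds the standard matters, not
temporal order — the model treats consecutive (Aubert-Fleischl) and
simultaneous (Filehne) comparisons identically.  An optional lapse rate
enters as `p = lapse/2 + (1 - lapse) * p0`; it defaults to 0 and is not
fit unless requested.

In true-speed mode each interval's `H'` is Gaussian with mean
`w_R(r) r + w_T(t) t` and variance `(w_R sigma_R)^2 + (w_T sigma_T)^2`, so
`P(H'_c > H'_s) = Phi((mu_c - mu_s) / sqrt(var_c + var_s))` exactly.

In measured mode `P(H'_c > H'_s)` has no closed form because the shrinkage
is nonlinear.  It is computed by numerical quadrature: each channel's
measurement density is
discretized at `n_nodes` nodes (default 61), giving `n_nodes^2` weighted
atoms of the per-interval `H'` distribution.  Because the estimate
`w(|m|) * m` has a kink at `m = 0`, plain Gauss-Hermite nodes converge
slowly (and oscillate) whenever the measurement density straddles zero —
i.e. for slow stimuli and for the zero-input channel; the integral is
therefore split at the kink, with Gauss-Legendre nodes mapped through the
truncated-normal quantile function on each side.  Each side keeps a fixed
node count while only its probability mass moves, so atom positions and
weights vary smoothly with the model parameters.  At 41 nodes this is
accurate to ~3e-4 in p (~1e-4 at 61), versus ~5e-3 for plain Gauss-Hermite
at the same cost.  The two interval distributions are then compared after
linear binning onto a shared uniform grid (default 2001 points spanning
all atoms).  Linear binning matters for
fitting: a raw atom-versus-atom comparison is piecewise constant in the
model parameters (probability only changes when two atoms cross), which
defeats quasi-Newton optimization, whereas binned probabilities are
continuous and piecewise linear in the atom positions.  The binning grid is
shared across all cells of a batch, so batch and single-cell evaluations of
the same cell can differ at the grid-resolution scale (~1e-3 in p); a
seeded Monte-Carlo path (`method="monte_carlo"`) is retained as an
independent oracle in both modes and agrees with the deterministic path to
well under 0.005 everywhere we test.  Ties have probability zero under
continuous noise; in
Monte Carlo they are resolved by a fair coin from the same seeded stream,
and on the shared grid coincident mass counts half.

## Psychometric extraction

Empirical and model-predicted psychometric functions are summarized by
binomial maximum-likelihood fits of a cumulative Gaussian: the mean is the
point of subjective equality (PSE), the SD the discrimination threshold.
The SD is optimized on a log scale with bounds tied to the span of the
comparison grid; all-0 or all-1 response sets are flagged non-identifiable
and the bounded optimum is reported as a limit.  Model thresholds and PSEs
are obtained by fitting the same cumulative Gaussian to model-generated
proportions on the same comparison grid as the data, so model and data
summaries are extracted identically.

## Joint fit

The seven free parameters `(a_R, b_R, c_R, a_T, b_T, c_T, sigma_p)` are
estimated by maximizing the binomial likelihood of the raw per-cell counts
across all of an observer's psychometric functions simultaneously — not by
fitting the extracted thresholds and PSEs.  Probabilities are clipped to
`[1e-9, 1 - 1e-9]` before logs.  Scale parameters are log-transformed
(bounds: a in [1e-4, 3], c in [0.02, 10], sigma_p in [0.1, 50] deg/s); the
exponents b are linear in [0, 3].  c is bounded strictly positive so that a
stationary input still carries measurement noise.  Optimization is
L-BFGS-B from multiple starts: one heuristic start read off per-curve
cumulative-Gaussian summaries (thresholds give crude (a, c) lines per
channel; the perceived-speed PSE ratio pins sigma_p through the ratio of
shrinkage weights), the rest Latin-hypercube samples inside the bounds.
The fit requires at least one discrimination condition (FF or EE) and one
perceived-speed condition (EF or FE); discrimination data alone cannot
separate the prior width from the noise scales, and the fit refuses with an
identifiability error rather than returning a ridge point.  In the default
true-speed mode one joint fit takes a few seconds; measured-mode fits use
the 41-node quadrature engine and take tens of seconds.

A configuration flag unshares the two prior widths (8 parameters), and a
lapse can be added (one more); the default remains the shared-prior,
no-lapse 7-parameter model.

Confidence intervals are nonparametric bootstrap, resampling trials with
replacement within each psychometric point (each cell keeps its n).
Per-curve PSE/threshold intervals come from cumulative-Gaussian refits of
each resample; per-parameter intervals from warm-started refits of the full
model.  B defaults to 500, which is appropriate for the cheap per-curve
intervals; full-model parameter intervals at B = 500 are expensive and are
typically run at smaller B or overnight.

## Synthetic data

No raw choice data are published for this paradigm, so the pipeline is
validated on synthetic observers drawn from the generative model itself.
The reference design has ten psychometric functions per observer — four
fixation-discrimination (FF) standards and four pursuit-discrimination (EE)
standards at 1, 2, 4 and 8 deg/s, plus two pursued-standard
perceived-speed (EF) standards at 2 and 8 deg/s — with seven comparison
levels from 0.5x to 1.5x the standard and 40 trials per point (2800 trials
per observer).  The total of ten functions matches the paradigm; the 4+4+2
split across conditions and the speed lists are this repository's fixture
choices, and the design is fully configurable.  Interval order is
randomized 50/50 and recorded but unused, since the decision rule is
order-invariant.

The generator emulates exactly the statistical structure the analysis
assumes: independent Gaussian measurement noise per channel and interval,
deterministic shrinkage, a larger-estimate decision rule, and binomial
sampling per design cell.  It does not emulate eye-tracking imperfections
(retinal slip from inaccurate pursuit, saccades, trial rejection), stimulus
rendering, sequential dependencies, or attention fluctuations — so passing
tests demonstrate internal consistency of the pipeline and identifiability
at the design scale, not robustness to those real-data complications.

The fixture observer is `sigma_R(v) = 0.15 v^0.7 + 0.30`,
`sigma_T(v) = 0.50 v^0.7 + 0.20`, `sigma_p = 2.0` deg/s.  It was chosen,
once, to sit in the regime the model describes: the pursuit channel is
roughly three times noisier than the image channel over the tested speeds,
pursuit discrimination thresholds exceed fixation thresholds about
two-fold at the lower standards (more at the fastest, where shrinkage
flattens the pursued psychometric function), the perceived-speed match
ratio at 8 deg/s is near 0.5, and the baseline terms c are genuinely
small — the zero-input channel contributes little noise to a
moving-channel judgment, which both matches how the model is described
and keeps the R-channel noise identifiable from FF thresholds (a large
c_T would let target-channel baseline noise dominate fixation judgments).
These values are documented fixtures, not estimates from any dataset.

## Parameter recovery

The recovery experiment simulates 20 independent observers from the
fixture parameters at the reference design scale, refits each with a
10-start configuration (a down-scaling of the 20-start default that
leaves results unchanged on this problem), and summarizes the median
relative error of sigma_p and the median pointwise relative error of the
noise-SD curves over the design's standard speeds.  With 2800 trials per
observer the likelihood surface has soft directions — the prior width
trades off against the noise scales through the shrinkage weights — so
individual parameters (a, b, c) are recovered far less precisely than the
noise-SD *curves* sigma_X(v) they jointly define; the curves and sigma_p
are the quantities the recovery experiment tracks.

Precision at the slowest standard is information-limited, not an
implementation artifact: the expected Fisher information of the design at
the fixture parameters gives asymptotic median relative errors of about
26% for sigma_R(1) and 19% for sigma_T(1) (versus 7-14% at 4-8 deg/s and
~19% for sigma_p).  Bounded estimation keeps the empirical medians
somewhat below these floors (~0.15-0.20 at 1 deg/s across seed batches,
under 0.13 elsewhere, ~0.10-0.16 for sigma_p), but recovering the noise
law at 1 deg/s to better than ~15% would require more than 40 trials per
point or additional slow-speed conditions.

## Numerical choices

* True-speed mode probabilities are closed-form (scipy's normal CDF); the
  quadrature settings below apply to measured mode only.
* Quadrature nodes: 61 per channel dimension for reported quantities, 41
  for fitting; agreement with a 10^6-sample Monte Carlo is ~1e-3 in p
  (dominated by the binning grid and MC error).
* Shared binning grid: 2001 points; accuracy ~1e-3 in p, which bounds the
  batch-vs-single discrepancy noted above.
* Measured-mode expectations of estimates (illusion predictions) use
  201-node 1-D split quadrature; the node construction mirrors under sign
  reversal, so symmetric-observer nulls hold to ~1e-16.  True-mode
  expectations are `w(v) v` exactly.  The summed-likelihood model's
  expectation is linear in the summed measurement and uses symmetric
  Gauss-Hermite nodes, making its null predictions exact.
* Aubert-Fleischl matching uses Brent root-finding of p = 0.5 on
  [1e-6, 3x standard]; a missing sign change raises an error with the
  bracket diagnostics.  Perceived-speed matching is defined as the p = 0.5
  point of the decision rule; matching expected estimates instead is
  available via `expected_estimate` and coincides under symmetric noise.
* Degenerate inputs: zero nodes/samples, empty grids, non-finite
  velocities, out-of-bounds parameters and non-binary responses all raise
  ValueError early; invalid parameter vectors inside the optimizer return
  +inf instead of raising.

## Known limitations

* The Gaussian-product shrinkage is an approximation to the exact
  non-Gaussian MAP when noise is speed-dependent; the `map` estimator mode
  quantifies the difference (small at the fixture parameters).
* The measured-speed estimator variant is weakly identifiable from choice
  data at realistic session sizes (see the mode discussion above); fits in
  that mode should be interpreted with care.
* Trajectory predictions treat the two axes independently with the same
  1-D priors; no 2-D (direction) prior is modeled.
* The decision uses signed estimates; all stimuli move in the same
  direction, so magnitude-versus-signed questions do not arise in the
  reference design.
* Early compressive nonlinearities on speed and contrast-dependent
  likelihood widths are out of scope.
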