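# Methods

## Model

A saccade trial is reduced to three scalar sensorimotor gains. With target
eccentricity P1 (degrees, rightward positive) and gain state
ω = (ω_v, ω_m, ω_cd):

    V1  = P1 · ω_v                  perceived pre-saccadic target position
    M   = V1 · ω_m                  motor command / saccade vector
    CDM = M                         corollary discharge of the command
    CDV = CDM · ω_cd                computed displacement of visual space
    V̂2  = V1 − CDV                  predicted post-saccadic retinal position
    V2  = P1(1 − ω_v ω_m) + Pd      actual post-saccadic retinal position

The trans-saccadic displacement Pd depends on the paradigm: with a constant
target step (CTS) the target moves Ps relative to its pre-saccadic
position, Pd = Ps; with a constant visual error (CVE) the target reappears
Ps away from the landing point, Pd = P1(ω_v ω_m − 1) + Ps, which clamps
V2 = Ps identically — the retinal error is then uncontrollable by learning.
A step-free baseline is CTS with Ps = 0.

Two candidate error signals drive learning:

    E_pre  = V2 − V̂2               visual prediction error
    E_post = V̂1 − M, V̂1 = V2 + CDV postdictive motor error

Gains adapt after every saccade by the delta rule,
ω(n+1) = ω(n) − 2 α E(n) g(n), where α = diag(α_v, α_m, α_cd) are learning
rates (1/deg²) and g is the learner's internal gradient estimate of
∂E/∂ω. Crucially, g treats Pd as an external given: in CVE the learner
does not differentiate through its own landing-point contingency. An
optional third mode learns on the raw retinal error E = V2 (with the same
Pd-clamping convention); it is provided for comparison only, since a pure
visual error predicts endless CVE learning and cannot explain observed
steady states.

All model evaluation is deterministic and noise-free; motor noise enters
only the synthetic-data generator. This matches the fitting target: fits
are to probe-block medians, in which zero-mean execution noise cancels.

## Gain estimation from probe data

Each probe block yields medians of pre-saccadic localization V1, saccade
vector M, and post-saccadic localization relative to the landing point V̂2.
The forward model is inverted exactly: CDV = V1 − V̂2, ω_v = V1/P1,
ω_m = M/V1, ω_cd = CDV/M (CDM identified with the measured vector).
Plasticity of each gain is a two-sided one-sample t-test of the block-5
minus block-1 change against zero across subjects; an explicit
sign-alignment helper flips inward-condition changes so magnitudes can be
pooled across directions. Heavier repeated-measures machinery (mixed
ANOVAs, post-hoc corrections) is deliberately out of scope; standard
statistics packages handle the exported per-subject tables.

## Trial filtering

Saccadic trials are accepted as reactive rightward saccades with latency in
[100, 400] ms and vector ≥ 5°. Post-saccadic localizations additionally
require the saccade no earlier than 100 ms after flash offset (avoids
peri-saccadic compression), gaze held at the landing point, a click above
the lower 30% of the display, and no fixation break longer than 1400 ms;
pre-saccadic localizations require no saccade within 400 ms of flash onset
plus the click-region and fixation-hold rules. When a trial violates
several rules the rejection is attributed to the first in the order
latency → amplitude → flash-timing → fixation-hold → click-region (the
order in which the rules act in the pipeline); the pre-saccadic
no-saccade rule is counted in the flash-timing category. Block medians
exclude points more than three scaled MADs from the median, with the
normal-consistency scale factor 1.4826 and a single pass (no re-iteration).
When the MAD is exactly zero but distinct values exist, only values equal
to the median are kept — this keeps degenerate noiseless fixtures sensible.

## Model fitting

The gain state at trial 1 is derived from probe block 1. The model is then
simulated over the 281 primary-task trials (the step applies from trial 1;
probe blocks sit at n = 1, 71, 141, 211, 281) and the learning rates are
chosen to minimize the weighted SSE over the 15 data points (5 blocks × 3
observables), with block weights η = 1.52 (long blocks, 21 localization
pairs) and 0.65 (short blocks, 9 pairs) reflecting measurement certainty.
Rates are bounded to [0, 9·10⁻⁵] 1/deg²; the residual standard error is
RSE = sqrt(SSE/(λ−1)) with λ = 15. Because both error models have
identical free parameters, fits are compared directly by paired t-tests on
subject RSEs.

Numerically the problem is a 3-parameter bounded nonlinear least-squares
fit; we use a trust-region reflective solver on the √η-weighted residual
vector with multistart (eight log-spaced diagonal starts in
[10⁻⁸, 9·10⁻⁵], the zero corner, and a few seeded log-uniform starts),
deterministic given the seed. The objective has plateaus near zero rates,
which the multistart covers. A simulation whose gains leave ±10 returns a
large finite penalty (10⁶ deg²) so the optimizer retreats without NaNs;
the cap exists because the rate upper bound alone does not preclude
transient exponential growth of the saccade vector. Tolerances are set
tight (1e-15) since a noiseless series must be fitted to SSE < 1e-10.

Shared fits minimize the summed SSE of a CTS and a CVE series of the same
subject with one rate vector. Error metrics per fit: baseline error
(trial-1 gains evaluated at Ps = 0), final error at trial 281, percentage
error decline from trial 1 (step included), the CDV error CDV − M, and the
visual endpoint error V2 at the first and last trial.

### Rate recovery on noisy cohorts

For noisy data two estimators of cohort-level rates exist: the mean of
per-subject fits and a fit to the cohort-mean probe series. With weakly
identified rates (α_v drives only the small pre-saccadic localization
change) the per-subject estimates scatter widely and the non-negativity
bound truncates them at zero, so their mean is biased upward. Averaging
the probe series across subjects before fitting suppresses the measurement
noise by √n first and avoids the truncation bias; the acceptance checks
therefore use the group-mean-series estimator. Both entry points are
available.

## Stability analysis

Setting the per-trial gain change Δω = −2αE_post·g to zero and solving for
the motor gain (ω_v ≠ 0) gives non-isolated fixed-point surfaces:

    CTS:  ω_m = −(P1 + Ps) / (P1 ω_v (ω_cd − 2))
    CVE:  ω_m = −Ps / (P1 ω_v (ω_cd − 1))

The Jacobian of Δω is computed analytically via the product rule,
J = −2 diag(α)(g ∇Eᵀ + E ∂g/∂ω), with a finite-difference variant as an
independent oracle. At an exact fixed point (E = 0) J is the rank-1 matrix
−2 diag(α) g ∇Eᵀ; for CTS (∇E = g) its single nonzero eigenvalue is
−2 Σ α_i g_i², strictly negative for positive rates: the surface is
neutrally stable along itself and attracting transversally. The primary
classification uses the eigenvalues of the full 3×3 Jacobian (stable /
unstable / marginal, with |λ| ≤ 1e-9 counted as a neutral direction); the
trace, determinant and discriminant τ² − 4·det of the 2×2 sub-Jacobian on
the (ω_m, ω_cd) slice at fixed ω_v are reported alongside, since the
vector-field plane is usually drawn there. For CVE the Jacobian follows
the learner convention (Pd clamped) by default; a flag differentiates
through the landing-point contingency for exploration. The CVE surface at
Ps = 0 degenerates to ω_m = 0, which is reported as computed; the
baseline-relevant fixed set is the CTS/Ps = 0 surface.

## Synthetic data

The generator emulates the study design: 9 blocks per session — probe
blocks 1, 3, 5, 7, 9 (sequences pre-loc / refresh / post-loc / refresh,
21 repetitions in blocks 1 and 9, nine in blocks 3, 5, 7, last refresh
dropped: 83 and 35 trials) interleaved with four 70-trial learning blocks;
551 trials total. Probe block 1 is a step-free baseline; the step applies
from block 2 on. The model-trial axis n = 1..281 counts the primary-task
trials so the probe blocks sit at n = [1, 71, 141, 211, 281]; the session
axis 1..551 is kept alongside.

Defaults (configurable): baseline gains (1.0, 0.95, 0.985) — accurate
vision, mildly hypometric saccades, slightly hypometric CDV; per-condition
generating rates at the postdiction-fit scale (e.g. (5.2·10⁻⁶, 3.5·10⁻⁵,
1.8·10⁻⁵) for inward constant steps); independent Gaussian motor and
report noise with SD 0.5° each (the probe-median pipeline only requires
zero-mean noise; Gaussian is the simplest adequate choice); cohort
baseline gains drawn from Gaussians with SDs (0.015, 0.02, 0.01). Filter
violations are drawn independently per rule with fractions whose defaults
land acceptance near the study's observed ~89% (pre-saccadic) and ~77%
(post-saccadic localization) rates — a configuration, not an inference.

Two deliberate simplifications: (1) learning updates use the noise-free
internal state (noise perturbs only the executed vector and the clicks), so
that probe medians estimate the modeled state without bias; (2) by default
no updates occur on probe-block refresh and localization saccades, so the
generative process and the 281-trial fitted model share one trial axis and
noiseless parameter recovery is exact. A `learn_during_probe` flag enables
probe-block learning for realism checks; with it on, fitted rates absorb
the extra updates and recovery is biased — which is itself informative
about what the 281-trial model can and cannot represent.

What the generator does not emulate: gaze traces and saccade kinematics,
peri-saccadic compression, corrective saccades, slow drifts of attention or
fatigue across a session, and any trial-to-trial correlation of noise.
Passing tests on synthetic cohorts therefore demonstrate correctness of the
pipeline and identifiability under the assumed noise model, not validity of
the model for any particular empirical dataset.

## Problem sizes

Simulations in the test-suite and acceptance script use 281-trial sessions
(the study schedule), cohorts of 17 subjects for recovery and gain-change
statistics, 6-subject cohorts per condition for the model-comparison
direction check, and grids of ~60 points per condition for fixed-point
verification; long-run convergence checks use 10⁴–2·10⁴ trials.

## Known limitations

- The deposited human dataset is not bundled; analyses of real data load a
  probe-series CSV (`data/zenodo_probe_series.csv`) derived from it via the
  column-mapping loader. Published group-level numbers can only be checked
  with that file present.
- The visual-error learning mode is a faithful E = V2 gradient construction
  but has no reference parameterization to validate against.
- RSE uses sqrt(SSE/(λ−1)); SSE/(λ−1) without the radical would not carry
  degree units and is not used.
- The fitted-rate upper bound and divergence cap are part of the model
  specification, not tuned quantities.
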