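# Methods

## The model

`brokenduet` simulates a dyad: a *speaker* whose internal dynamics generate an
ambiguous scalar signal, and a *listener* who infers the hidden causes of that
signal with a hierarchical Bayesian filter.  Misunderstanding is operationalised
as the listener settling in the wrong attracting set of a bistable system.

### Speaker

The speaker's latent state follows the Lorenz equations

    x' = sigma (y − x),   y' = x (r − z) − y,   z' = x y − b z

in the *broken* regime sigma = 0.12, r = 0, b = −0.6.  In this regime the
butterfly attractor splits into two disconnected attracting sets ("lobes"),
mirror images of one another under (x, y) → (−x, −y), with disjoint basins;
the sign of x identifies the lobe.  Two properties matter downstream:

* **Confinement.**  A trajectory started in one lobe never visits the other.
  Escape to infinity is the only way out of a basin: the attracting sets'
  basins are thin (b < 0 gives z positive feedback), so most far-field states
  diverge rather than fall onto either attractor.  Ensemble checks therefore
  sample starts on and near the attractors, and treat escape as exclusion,
  not as a lobe switch.
* **Mirror equivariance.**  The field commutes exactly with (x, y)-negation.
  Lobe switching during generation is emulated *in the observation map only*
  (below), which by this symmetry is equivalent to instantaneously mirroring
  the latent state, while the trajectory itself is integrated continuously.

The percept — the only signal that crosses to the listener — is

    v0(t) = 0.5 * v1(t) * y(t) + z(t)

where v1(t) ∈ {−1, +1} is a second-level "lobe" cause on a square-wave
schedule (constant +1 for the headline runs; period-128 switching for evoked
responses).  The percept deliberately omits x, the coordinate that separates
the lobes, and is invariant under (y, v1) → (−y, −v1): the lobe is never
directly observable, only inferable.

Integration uses fixed-step classical RK4 with 4 sub-steps per sample (a
local-linearisation stepper is available as an option); one sample advances
one unit of model time, giving a percept quasi-period of roughly ten samples.
Optional i.i.d. Gaussian observation noise is available; the default protocol
is noiseless, so every pipeline stage is deterministic and seeds only matter
when noise is enabled.

### Listener

The listener inverts a two-level generative model:

* **Level 1** — the same broken-Lorenz flow on beliefs (x̃, ỹ, z̃), with
  observation  ṽ0 = 0.5 · tanh(ṽ1) · ỹ + z̃.  The tanh squashes a
  real-valued lobe belief ṽ1 into (−1, 1) so the listener can smoothly
  interpolate between the two lobes' observation maps.
* **Level 2** — ṽ1 is a static cause (zero predicted motion) with Gaussian
  prior mean 1 and log-precision −1: initial confidence in the +1 lobe,
  revisable under evidence.

Two log-precisions parameterise the listener's confidence: *internal*
(weighting dynamics prediction errors) and *external* (weighting percept
prediction errors).  The four named regimes cross these over {0, 4}:
A = (0, 0), B = (4, 0), C = (0, 4), D = (4, 4).

## Generalized filtering

States, causes and observations are represented in generalized coordinates of
motion — a value plus its temporal derivatives up to an embedding order
(6 for states/outcomes, 2 for causes).  Three pieces of machinery:

* **Shift operator D** maps each derivative order to the next; prediction is
  motion along D.
* **Embedding** inverts the Taylor map of a symmetric window of samples
  (exact for polynomials of degree < order); the first and last half-windows
  reuse the nearest interior window rather than extrapolating.  Because the
  window is symmetric, each posterior reflects a few future samples — a
  short smoothing horizon without a backward pass.
* **Generalized precisions** encode analytic (smooth) noise: the covariance
  across derivative orders holds signed derivatives of a Gaussian
  autocorrelation rho(h) = exp(−h²/(4 s²)) with width s = 0.5 samples, so a
  unit-variance noise process has first-derivative variance 1/(2 s²).
  Odd–even cross-terms vanish by parity.

The variational posterior is Gaussian with modes only (fixed implicit
covariances).  Its free energy at each sample is

    F = 1/2 Σ_streams e' Π e − 1/2 Σ log|Π| + const

over three error streams: outcome (generalized percept minus predicted
percept), dynamics (D·states minus predicted flow), and cause prior
(generalized cause minus its prior).  Gradients of F are precision-weighted
prediction errors.

**Assimilation** integrates the generalized gradient flow

    mu' = D mu − rate · dF/dmu

over each sample interval in 8 local-linearisation sub-steps, with Jacobian
D − rate·H (H the Gauss–Newton curvature), which makes each sub-step
A-stable.  This is single-pass continuous assimilation: no backward sweep.
Two designs were rejected:

* *Separated predict-then-minimise* (shift the posterior, then damped
  Gauss–Newton descent at the new sample).  Unstable at external
  log-precision 4 — high-order derivative estimates chase embedding noise,
  the shift amplifies them into the value order, and the posterior runs away.
  It also destroys hysteresis: near-complete per-sample minimisation hops
  between basins, so every regime recovers the lobe and the study's central
  contrast vanishes.
* *Rate 1 flow.*  At log-precision 0 the gradient pull is too weak to track
  the percept within a sample, so the baseline regime never aligns with the
  speaker, contradicting its intended behaviour.  The default rate of 16 is
  the smallest power-of-two rate at which the baseline regime both tracks
  the percept (residual ≈ 3% of variance) and recovers the speaker's lobe;
  the regime pattern is stable over rates 16–32.

Because the drift D·mu is part of the integrated flow, free energy is *not*
monotone across individual sub-steps (the data's moving frame does work on
the posterior).  What does hold, and what the tests assert: the net
free-energy change across each sample's sub-steps is a descent for ≳99% of
samples, and on static (constant) data the flow settles monotonically into a
free-energy plateau.

### Validation against exact inference

On linear-Gaussian systems the exact posterior is computable classically, so
the engine is checked against an independent Kalman smoother (statsmodels).
The validation systems are lightly damped random rotations (state dimension
1–3) observed through orthogonal matrices, driven by small serially
correlated noise whose autocorrelation width matches the engine's smoothness
assumption (process sd 0.0025, observation sd 0.01, 500 samples).  In this
near-exact-inference regime the two posteriors agree to ≈2% RMS of the state
sd (bound asserted: 5%).  The regime is chosen deliberately: a modes-only
filter that assumes analytic noise has no mechanism to match a smoother under
heavy white noise or ill-conditioned observation — with white noise and
random (non-orthogonal) observation matrices the discrepancy is unbounded in
practice.  The check validates calibration and lag-freeness, not robustness
to model mismatch.

## Experiments

Each headline run generates the percept from speaker start (0.8, −3, 0) (the
+1 lobe) and inverts it with the listener started at the mirror point
(−0.8, 3, 0), under one precision regime.  Outcomes:

* **log-MSE** — natural log of the mean squared Euclidean distance between
  speaker states and posterior state means, after discarding a 10% burn-in
  (floored at log 1e−12).
* **Lobe recovery** — two conditions must both hold: the trailing-window mean
  of tanh(ṽ1) sides with the generating lobe, *and* the trailing-half
  state-lobe occupancy (fraction of samples with sign(x̃) = sign(x_speaker))
  is at least 0.75.  The belief alone is not sufficient: in the
  high-external-precision regimes the belief can remain weakly positive while
  the state trajectory disperses across both lobes, and it is the state-space
  trajectory that defines which attractor the listener occupies.
* **Percept tracking** — residual MSE of the predicted percept as a fraction
  of percept variance.

The precision sweep repeats this over a 5×5 grid of internal × external
log-precisions {0..4}.

**Default problem sizes.**  Headline and ERP runs use 4,096 samples and sweep
cells 1,024 samples (the generator's own default remains 16,384).  The
qualitative pattern — baseline recovers the lobe, high-external-precision
regimes do not, external-axis error growth exceeding the internal-axis
effect — is stable across 1,024–4,096-sample runs.

## Evoked responses

Precision-weighted prediction errors play the role of superficial-pyramidal
population activity: the weighted percept error is the LFP of a first
(sensory) region, the weighted lobe-cause error that of a second (higher)
region; the zeroth generalized order of each stream is used.  Epochs of
−5..+25 samples around each lobe switch are extracted, upsampled 10× by
cubic interpolation, split by direction (−1→+1 "expected" under the lobe
prior; +1→−1 "unexpected") and averaged within direction.  Epochs clipped by
the series boundary or contaminated by a second switch are dropped and
counted; a direction with no clean epochs yields NaN waveforms rather than
an error.  "Return to baseline" is the first post-peak time at which the
response's deviation from its pre-switch mean falls below 10% of the
post-switch peak (threshold configurable); interpolation artefacts from
upsampling are attenuated by averaging, as they are not time-locked to the
switch.

## Known limitations

* The high-internal/low-external regime (B) only partially reproduces its
  intended "convergence through shared narrative": its state-lobe occupancy
  hovers near chance at desk scale.  No acceptance property depends on it.
* Precisions are fixed; no precision learning, no full-covariance posteriors,
  no action.  The hierarchy is limited to two levels.
* The in silico LFPs are algorithmic stand-ins (weighted prediction errors),
  not biophysical neural-mass simulations; peristimulus times are in samples,
  not milliseconds, so no quantitative latency mapping is implied.
* The synthetic generator emulates the study's idealised conditions
  (deterministic percept, square-wave lobe schedule, shared model parameters
  between speaker and listener).  Passing tests demonstrate properties of
  this idealised system, not of real speech signals.
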