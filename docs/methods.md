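# Methods

## Models

All networks share one stochastic rate equation for the membrane potential
`V_i` (mV, time in ms):

    tau_i dV_i/dt = -V_i + V_rest + h_i(t) + eta_i(t) + sum_j W_ij r(V_j)

with a piecewise-constant deterministic input `h`, a multivariate
Ornstein-Uhlenbeck (OU) noise process `eta` (correlation time `tau_noise`,
spatial covariance `Sigma`), and a static nonlinearity `r`.

**Stabilized supralinear network (SSN).**  `r(V) = k max(V - V0, 0)^n` with
`k = 0.3 mV^-2 s^-1`, `n = 2`, `V0 = V_rest = -70 mV`.  Two variants:

* *Two-population*: one E and one I unit, `W = [[1.25, -0.65], [1.2, -0.5]]`
  mV s, `tau_E = 20 ms`, `tau_I = 10 ms`, uncorrelated noise.
* *Ring*: 50 E + 50 I units co-located pairwise at evenly spaced angles on
  the full circle.  Weights follow a circular Gaussian
  `exp((cos(dtheta) - 1)/ell_syn^2)` and each row of each of the four
  (post, pre) population blocks is rescaled so summed incoming weights equal
  the two-population magnitudes exactly.  Input
  `h = b + c A_max exp((cos(theta - theta_stim) - 1)/ell_stim^2)` with
  `b = 2 mV`, `A_max = 20 mV`; noise correlations fall off with the same
  circular-Gaussian form at scale `ell_noise`.
  `ell_syn = 45°`, `ell_noise = ell_stim = 60°`.

**Spiking SSN.**  4000 E + 1000 I neurons (a quarter-scale preset,
1000 E / 250 I, is the desk default); each neuron fires a Bernoulli spike
per 0.1 ms step with probability `dt·r(V_i)`.  Spikes are delayed by
0.5 ms, filtered by exponential synapses (`tau_syn = 2 ms`, unit jump) and
fed back through sparse random connectivity with exact in-degrees
(`p_E N_E` E and `p_I N_I` I partners; `p_E = 0.1`, `p_I = 0.4`) and
efficacies `J_ij = W_ab/(tau_syn p_b N_b)`, so the mean recurrent drive
matches the reduced model at equal rates.  Input noise has uniform pairwise
correlation `rho = 0.2`, sampled through its exact low-rank factor (one
private deviate per neuron plus one shared deviate).

**Multi-attractor ring.**  100 units, `V_rest = 0`,
`r(V) = g_max tanh(k max(V, 0))` with `g_max = 100 s^-1`, `k = 0.1 mV^-1`;
connectivity `W_ij = (Wbar + Wdelta cos(dtheta))/N` with `Wbar = -0.4`,
`Wdelta = 0.33` mV s (all entries inhibitory).  The conventional quotation of
these parameters is ambiguous about the units of `g_max` and whether `Wbar` is a per-entry or
row-total weight.  The per-entry reading makes the summed inhibition 100x
stronger, which clamps the mean rate at `b/|N Wbar| = 0.05 Hz` -- a silent
network with Fano ~= 1.  The row-total reading adopted here gives a
marginally unstable cosine mode (gain `Wdelta/2 · r'(V) ~ 1.65` near
threshold): a bump of activity (peak ~10 Hz over a ~0.7 Hz baseline) forms
spontaneously at a noise-selected angle and drifts around the ring, and the
spontaneous population Fano lands at ~1.5, the calibration this
model family is conventionally tuned to.  Input
`h = b + c(1 - A + A cos(theta - theta_stim))` with `A = 0.1`;
`sigma_0 = 0.15 mV`, `tau_m = 10 ms`.

**Chaotic network.**  2000 units, deterministic (`eta = 0`),
`r(V) = tanh(V)`, `W_ij ~ N(0, sigma_W^2/N)` with `sigma_W = 2` (spectral
radius ~2, chaotic), `tau_m = 10 ms`.  Stimulus `h_i = c cos(phi_i)` with
fixed random phases.  Across-trial variability comes from random initial
conditions; a strong enough stimulus entrains the trajectories and
suppresses the chaos.

## Input noise

The OU process obeys
`<eta_i(t) eta_j(t+s)> = Sigma_ij exp(-|s|/tau_noise)` with
`tau_noise = 50 ms`.  Amplitudes use the scaling
`sigma_a = sigma_0a sqrt(1 + tau_a/tau_noise)` so that an *uncoupled* unit
shows Vm fluctuations of standard deviation exactly `sigma_0a`; this is the
closed form used as a test oracle throughout.  The merged parameter-table
columns are parsed as `sigma_0E = 0.2, sigma_0I = 0.1` for the
two-population model and `sigma_0E = 1, sigma_0I = 0.5` for the
spiking/ring models -- the unique reading consistent with
`sigma_0I = sigma_0E/2`.

## Numerics

* Euler integration at `dt = 0.1 ms` (the stochastic networks).  The
  chaotic network, being deterministic and smooth with `tau_m = 10 ms`,
  is integrated at `dt = 1 ms` in single precision; halving that step does
  not measurably change its variance trajectories and the dense
  2000 x 2000 coupling dominates the cost.
* The OU noise is advanced by its exact one-step update
  (`exp(-dt/tau)` decay plus matched increment), so its stationary law is
  exact at any `dt`.  Dense covariances are factorised by symmetric
  eigendecomposition with eigenvalues below `-1e-10 · max(eig)` rejected
  and smaller negative ones clipped to zero.
* Per-trial randomness: a root `SeedSequence` spawns one child stream per
  trial; each stream is consumed in the order (initial condition if random,
  stationary initial OU state, per-step OU increments).  Trial k therefore
  reproduces bit for bit regardless of batch size, and every simulation is
  deterministic given `(seed, dt, n_trials)`.
* Fixed points: relaxation (noiseless integration to residual
  `< 1e-8 mV`) by default, Newton with the analytic Jacobian as a
  cross-check; a warning is attached if the Jacobian at the solution has a
  non-negative eigenvalue.
* Linearized covariance: the joint (dV, eta) system is linear, so its
  stationary covariance solves one continuous Lyapunov equation on the
  2N-dimensional state; the dV block is returned.  This replaces the
  original study's moment-closure analytics.  It is exact for the
  linearized dynamics (machine precision against the uncoupled closed
  form), but for the threshold-quadratic SSN it deviates systematically
  from Monte Carlo where the nonlinearity matters: at `h = 0` the fixed
  point sits exactly at the rectification threshold (linear theory predicts
  the uncoupled variance; simulation shows ~16% amplification from
  suprathreshold excursions), and at the `h ~ 2 mV` variability peak the
  ~1 mV fluctuations are large on the ~3 mV curvature scale (~19%
  overestimate).  At `h = 15 mV` agreement is ~1%.  These bands are
  reported by the oracle test and should be kept in mind wherever the
  linearized covariance is used quantitatively near threshold.

## Analysis conventions

* Spike counts: doubly stochastic Poisson draws from `integral r dt` per
  100 ms window; sliding onset-aligned windows step by 25 ms (four 25 ms
  sub-bins summed).  Neurons with mean count below 0.01 are flagged and
  excluded from population Fano averages (configurable).
* Normalized counts: each neuron is rescaled relative to its trial mean
  `m_i` as `1 + (c - m_i)/sqrt(m_i)`, so the per-neuron mean is 1 and the
  variance is exactly the Fano factor (covariance entries become
  `C_ij/sqrt(m_i m_j)`).  The plain mean division
  `c/m` often quoted for this statistic is inconsistent with the
  variance-equals-Fano property (`Var(c/m) = Fano/m`), and the property -- which is
  what keeps Poisson mean-scaling out of the shared-variability estimate
  and stops low-rate neurons dominating -- is taken as authoritative.
* Factor analysis: `eigen` mode (model data) takes the top-k eigenmodes of
  the normalized-count covariance, so shared + private equals the total
  exactly; `ml` mode (realistic data sizes) is maximum-likelihood FA (EM,
  via scikit-learn) with a 1e-6 ridge.  Note the eigen route absorbs some
  sampling noise into the shared part when trials are few; the ml route is
  the less biased estimator in that regime.
* Bump fit: per stored time step, `V - V0` across the E ring is fitted by
  `a·exp((cos(theta - mu) - 1)/sigma^2)` with `(mu, sigma)` free
  (Levenberg-Marquardt, warm-started from the previous step, initialised at
  the circular centre of mass/spread) and `a` constrained so the total
  population rate equals its time mean; for the power law this constraint
  has the closed form `a = (Rbar/(k sum g^n))^(1/n)` (a monotone 1-D root
  find is used for other nonlinearities).  The captured fraction is
  `1 - <residual^2>/Var(V)` with the variance pooled over cells x time x
  trials (around the grand mean, so it covers both the mean bump shape and
  its fluctuations); a per-trial-pooled variant is also reported and agrees
  to within a percentage point.  Covariance templates are outer products of
  the central-difference patterns `d(bump)/d(mu)` and `d(bump)/d(sigma)`
  (the latter including the constraint-induced amplitude change), scaled by
  the variances/covariance of the fitted series.
* Timescales: suppression half-time = first crossing of
  `(baseline + plateau)/2` after onset minus the onset latency (last time
  the trajectory is inside the baseline mean +/- 2 SD noise band); recovery
  analogous after offset relative to the plateau band.  Suppression % is
  `100 (baseline - plateau)/baseline`.
* Spectra/coherence: Welch, 1 s Hann windows, 50% overlap, per-segment
  detrend; LFP power normalized to unit total per condition.
* Orientation handling: ring angles live on the full 360° circle
  (direction convention); preferred orientations are `theta/2` on a 180°
  cycle, pair classification splits at 45° orientation difference.  The
  angular length scales (45°, 60°) are converted to radians inside
  `exp((cos(dtheta) - 1)/ell^2)`; the expression is dimensionally
  inconsistent otherwise.

## Synthetic data

The fixture generator emulates the *shape* of an awake-monkey V1 grating
dataset (orientation conditions x trials x ~100 tuned units, 100 ms count
windows): parametric mode draws circular-Gaussian tuning curves
(`f0 ~ U(0.5, 3) Hz`, `fm ~ U(10, 40) Hz`, `kappa ~ U(0.8, 2.5)`, uniform
preferred orientations) with a rank-1 multiplicative shared gain
(SD 0.6 by default, clipped at zero) on top of Poisson spiking; ring mode
drives the counts with ring-SSN simulations.  It provides ground truth for
recovery tests (tuning fits, OTI filters, factor analysis).  It does not
emulate real-data nuisances -- sorting contamination, session drift,
non-Poisson refractory effects, eye movements -- so passing recovery tests
validates the estimators, not their robustness to those nuisances.

## Problem sizes and defaults

Headline quantities are computed at 500 trials (two-population means,
ring and multi-attractor Fano factors, evoked correlation curves), 100
trials x 1 s of evoked steady state for the bump fit (5 ms sampling,
~20,000 constrained fits), and 200 trials per amplitude for the
chaos-suppression timescales.  Stimulus amplitudes for the timescale
experiments span roughly 20-90% variance suppression per regime (chaotic
c = 0.6-1.25; ring contrasts 0.33-1; multi-attractor c = 1-2).  Each figure
driver completes in well under 15 minutes on one CPU at these defaults.

## Known limitations

* The linearized covariance inherits the near-threshold bias described
  above; moment-closure corrections are intentionally out of scope.
* At the reference parameters the two-population I unit fires at
  4.3 Hz (deterministic) / ~4.9 Hz (stochastic mean) at `h = 2 mV`,
  slightly above the "3-4 Hz" conventionally quoted for both
  populations; this is forced by the weights (the fixed point is
  independent of every other parameter) and is treated as rounded prose.
* The multi-attractor weight-table reading is provisional (see above); it
  is validated against the spontaneous-Fano calibration rather than stated
  units.
* Gamma-band spiking fluctuations, conductance synapses, refractoriness
  and real-data re-analysis are out of scope.
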