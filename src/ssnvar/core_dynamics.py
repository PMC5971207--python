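"""Stochastic rate-network dynamics.

This module implements the common dynamical core shared by all network
architectures in the package: membrane potentials :math:`V_i` obey

.. math::

    \\tau_i \\frac{dV_i}{dt} = -V_i + V_\\mathrm{rest} + h_i(t) + \\eta_i(t)
        + \\sum_j W_{ij}\\, r(V_j),

where ``r`` is a static nonlinearity (threshold power law for the SSN,
rectified-saturating or plain ``tanh`` for the competitor regimes), ``h`` is a
deterministic, piecewise-constant stimulus input and ``eta`` is a multivariate
Ornstein-Uhlenbeck (OU) noise process with spatial covariance ``Sigma`` and
correlation time ``tau_noise``.

Units: time in ms, voltages in mV, rates in s^-1, weights in mV*s.  The Euler
step defaults to 0.1 ms; the OU process is advanced with its exact one-step
update so its stationary law is correct at any step size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "Nonlinearity",
    "NetworkSpec",
    "NoiseSpec",
    "OUIntegrator",
    "StimulusProtocol",
    "Segment",
    "Trajectory",
    "SimOutput",
    "eval_nonlinearity",
    "sample_ou_noise",
    "simulate",
    "integrate",
    "fixed_point",
    "jacobian",
    "effective_weights",
    "linearized_covariance",
    "ConfigurationError",
    "InvalidCovarianceError",
    "InstabilityError",
    "NoFixedPointError",
    "StabilityWarning",
]

PSD_CLIP_TOL = 1e-10


class ConfigurationError(ValueError):
    """Inconsistent or unknown model configuration."""


class InvalidCovarianceError(ValueError):
    """Noise covariance is not symmetric positive semi-definite."""


class InstabilityError(RuntimeError):
    """Simulated voltages diverged, or no stationary covariance exists."""


class NoFixedPointError(RuntimeError):
    """Fixed-point search failed to converge."""


class StabilityWarning(UserWarning):
    """A computed fixed point is linearly unstable."""


# ---------------------------------------------------------------------------
# Nonlinearities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Nonlinearity:
    """Static voltage-to-rate nonlinearity.

    kind
        ``"powerlaw"``: ``r = k * max(V - V0, 0)**n`` (SSN),
        ``"rect_tanh"``: ``r = gmax * tanh(k * max(V, 0))`` (multi-attractor),
        ``"tanh"``: ``r = tanh(V)`` (chaotic network; may go negative).
    k
        Gain; mV^-n s^-1 for ``powerlaw``, mV^-1 for ``rect_tanh``.
    n
        Power-law exponent (dimensionless).
    V0
        Rectification threshold (mV, ``powerlaw`` only).
    gmax
        Saturation rate (s^-1, ``rect_tanh`` only).
    """

    kind: str
    k: float = 0.3
    n: float = 2.0
    V0: float = -70.0
    gmax: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("powerlaw", "rect_tanh", "tanh"):
            raise ConfigurationError(f"unknown nonlinearity kind {self.kind!r}")

    @classmethod
    def powerlaw(cls, k: float = 0.3, n: float = 2.0, V0: float = -70.0) -> "Nonlinearity":
        return cls("powerlaw", k=k, n=n, V0=V0)

    @classmethod
    def rect_tanh(cls, k: float = 0.1, gmax: float = 100.0) -> "Nonlinearity":
        return cls("rect_tanh", k=k, gmax=gmax)

    @classmethod
    def pure_tanh(cls) -> "Nonlinearity":
        return cls("tanh")

    def rate(self, V: np.ndarray) -> np.ndarray:
        """Elementwise firing rate r(V)."""
        V = np.asarray(V)
        if self.kind == "powerlaw":
            v = np.maximum(V - self.V0, 0.0)
            if self.n == 2.0:
                return self.k * v * v
            return self.k * v ** self.n
        if self.kind == "rect_tanh":
            return self.gmax * np.tanh(self.k * np.maximum(V, 0.0))
        return np.tanh(V)

    def slope(self, V: np.ndarray) -> np.ndarray:
        """Analytic derivative dr/dV, used for effective connectivity."""
        V = np.asarray(V)
        if self.kind == "powerlaw":
            v = np.maximum(V - self.V0, 0.0)
            return self.k * self.n * v ** (self.n - 1.0)
        if self.kind == "rect_tanh":
            v = np.maximum(V, 0.0)
            s = 1.0 / np.cosh(self.k * v) ** 2
            return np.where(V > 0.0, self.gmax * self.k * s, 0.0)
        return 1.0 / np.cosh(V) ** 2

    __call__ = rate


def eval_nonlinearity(nl: Nonlinearity, V: np.ndarray) -> np.ndarray:
    """Apply a nonlinearity elementwise to a voltage array."""
    return nl.rate(V)


# ---------------------------------------------------------------------------
# Network, noise and stimulus specifications
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Architecture-agnostic network description.

    ``W[i, j]`` is the signed weight of the connection from unit j onto unit
    i, in mV*s.  The first ``N_E`` units are excitatory.  ``tau`` may be a
    scalar or a length-N vector of membrane time constants (ms).  ``theta``
    holds preferred angles (degrees on the full circle) for ring models.
    """

    N_E: int
    N_I: int
    W: np.ndarray
    tau: np.ndarray
    Vrest: float
    nonlinearity: Nonlinearity
    theta: np.ndarray | None = None
    dale: bool = False

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        N = self.N_E + self.N_I
        if self.W.shape != (N, N):
            raise ConfigurationError(f"W has shape {self.W.shape}, expected {(N, N)}")
        self.tau = np.broadcast_to(np.asarray(self.tau, dtype=float), (N,)).copy()
        if np.any(self.tau <= 0):
            raise ConfigurationError("membrane time constants must be positive")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
            if self.theta.shape != (N,):
                raise ConfigurationError("theta must have one angle per unit")
        if self.dale:
            e = self.e_mask
            if np.any(self.W[:, e] < 0) or np.any(self.W[:, ~e] > 0):
                raise ConfigurationError("weight matrix violates Dale's law")

    @property
    def N(self) -> int:
        return self.N_E + self.N_I

    @property
    def e_mask(self) -> np.ndarray:
        m = np.zeros(self.N, dtype=bool)
        m[: self.N_E] = True
        return m

    def rate(self, V: np.ndarray) -> np.ndarray:
        return self.nonlinearity.rate(V)


@dataclass
class NoiseSpec:
    """Multivariate OU input-noise specification.

    One of three representations of the stationary spatial covariance
    (mV^2) may be supplied:

    * ``Sigma`` -- dense N x N covariance;
    * ``factor`` -- matrix B with ``Sigma = B @ B.T``;
    * ``diag_amp`` + ``shared_amp`` -- compound-symmetric low-rank form
      ``Sigma = diag(diag_amp^2) + shared_amp shared_amp^T`` (one private
      deviate per unit plus a single shared deviate), which avoids ever
      materialising the N x N matrix for large uniformly-correlated
      networks such as the spiking SSN.
    """

    tau_noise: float
    Sigma: np.ndarray | None = None
    factor: np.ndarray | None = None
    diag_amp: np.ndarray | None = None
    shared_amp: np.ndarray | None = None
    _cached_factor: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.tau_noise <= 0:
            raise ConfigurationError("tau_noise must be positive")
        if self.Sigma is None and self.factor is None and self.diag_amp is None:
            raise ConfigurationError("NoiseSpec needs Sigma, a factor, or amplitudes")
        if self.Sigma is not None:
            self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
            if not np.allclose(self.Sigma, self.Sigma.T):
                raise InvalidCovarianceError("Sigma must be symmetric")
        if self.factor is not None:
            self.factor = np.atleast_2d(np.asarray(self.factor, dtype=float))
        if self.diag_amp is not None:
            self.diag_amp = np.asarray(self.diag_amp, dtype=float)
            if self.shared_amp is None:
                self.shared_amp = np.zeros_like(self.diag_amp)
            self.shared_amp = np.asarray(self.shared_amp, dtype=float)

    @property
    def N(self) -> int:
        if self.diag_amp is not None:
            return self.diag_amp.shape[0]
        if self.factor is not None:
            return self.factor.shape[0]
        return self.Sigma.shape[0]

    @property
    def sampling_dim(self) -> int:
        """Number of standard-normal deviates consumed per time step."""
        if self.diag_amp is not None:
            return self.N + 1
        return self.sampling_factor().shape[1]

    def covariance(self) -> np.ndarray:
        if self.Sigma is not None:
            return self.Sigma
        if self.diag_amp is not None:
            return np.diag(self.diag_amp**2) + np.outer(self.shared_amp,
                                                        self.shared_amp)
        return self.factor @ self.factor.T

    def transform(self, z: np.ndarray) -> np.ndarray:
        """Map deviates z (..., sampling_dim) to correlated increments (..., N)."""
        if self.diag_amp is not None:
            return z[..., : self.N] * self.diag_amp + z[..., self.N:] * self.shared_amp
        return z @ self.sampling_factor().T

    def sampling_factor(self, tol: float = PSD_CLIP_TOL) -> np.ndarray:
        """Matrix B with Sigma = B B^T.

        Dense covariances are factorised by symmetric eigendecomposition;
        eigenvalues in (-tol*scale, 0) are clipped to zero, anything more
        negative raises :class:`InvalidCovarianceError`.
        """
        if self.factor is not None:
            return self.factor
        if self.diag_amp is not None:
            return np.concatenate([np.diag(self.diag_amp),
                                   self.shared_amp[:, None]], axis=1)
        if self._cached_factor is None:
            evals, evecs = np.linalg.eigh(self.Sigma)
            scale = max(evals.max(), 1.0)
            if evals.min() < -tol * scale:
                raise InvalidCovarianceError(
                    f"Sigma has eigenvalue {evals.min():.3e} below -tol"
                )
            evals = np.clip(evals, 0.0, None)
            self._cached_factor = evecs * np.sqrt(evals)
        return self._cached_factor


class OUIntegrator:
    """Exact one-step integrator for the multivariate OU input noise.

    Shared by the rate-model engine and the spiking simulator.  State shape
    is (n_trials, N); per-trial deviates come from the caller so that trial
    streams stay independent and reproducible.
    """

    def __init__(self, noise: NoiseSpec, dt: float, dtype=np.float64):
        self.noise = noise
        self.decay = dtype(np.exp(-dt / noise.tau_noise))
        self.amp = dtype(np.sqrt(1.0 - float(self.decay) ** 2))
        self.m = noise.sampling_dim
        if noise.diag_amp is not None:
            self._d = noise.diag_amp.astype(dtype)
            self._s = noise.shared_amp.astype(dtype)
            self._Bt = None
        else:
            self._Bt = np.ascontiguousarray(noise.sampling_factor().T, dtype=dtype)
            self._d = self._s = None

    def transform(self, z: np.ndarray) -> np.ndarray:
        if self._Bt is not None:
            return z @ self._Bt
        N = self.noise.N
        return z[..., :N] * self._d + z[..., N:] * self._s

    def stationary(self, z: np.ndarray) -> np.ndarray:
        """Initial state drawn from the stationary law, given deviates z."""
        return self.transform(z)

    def step(self, eta: np.ndarray, z: np.ndarray) -> None:
        """Advance eta in place by one time step using deviates z."""
        eta *= self.decay
        eta += self.amp * self.transform(z)


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant stimulus segment."""

    duration: float  # ms
    h: np.ndarray | float  # mV, scalar or length-N vector
    c: float | None = None  # optional contrast label

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("segment durations must be positive")


@dataclass(frozen=True)
class StimulusProtocol:
    """A sequence of piecewise-constant input segments."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ConfigurationError("protocol must contain at least one segment")

    @classmethod
    def constant(cls, h, duration: float, c: float | None = None) -> "StimulusProtocol":
        return cls((Segment(duration, h, c),))

    @classmethod
    def step(cls, h_pre, h_stim, h_post, t_pre: float, t_stim: float,
             t_post: float) -> "StimulusProtocol":
        """Baseline / stimulus / baseline three-segment protocol."""
        return cls((Segment(t_pre, h_pre), Segment(t_stim, h_stim),
                    Segment(t_post, h_post)))

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def resolve(self, N: int) -> list[tuple[float, np.ndarray]]:
        out = []
        for s in self.segments:
            h = np.broadcast_to(np.asarray(s.h, dtype=float), (N,))
            out.append((s.duration, h))
        return out


@dataclass
class Trajectory:
    """One simulated trial: recorded voltages and derived rates."""

    dt: float
    times: np.ndarray
    V: np.ndarray  # (T, N) mV
    nonlinearity: Nonlinearity
    protocol: StimulusProtocol | None = None
    seed: int | None = None

    @property
    def r(self) -> np.ndarray:
        """Firing rates (s^-1) implied by the stored voltages."""
        return self.nonlinearity.rate(self.V)


@dataclass
class SimOutput:
    """Batched simulation output (see :func:`simulate`).

    Heavy per-step state is reduced on the fly: voltages are stored only at
    ``record_dt`` resolution, spike-rate integrals per counting bin, and
    across-trial moments per recorded step, as requested.
    """

    dt: float
    seed: int
    times: np.ndarray | None = None          # recorded times (ms)
    V: np.ndarray | None = None              # (n_trials, T_rec, N)
    rate_integral: np.ndarray | None = None  # (n_trials, n_bins, N) expected counts
    bin_times: np.ndarray | None = None      # bin centers (ms)
    trial_mean: np.ndarray | None = None     # (T_rec, N) across-trial mean V
    trial_var: np.ndarray | None = None      # (T_rec, N) across-trial var V
    final_V: np.ndarray | None = None        # (n_trials, N)
    protocol: StimulusProtocol | None = None


# ---------------------------------------------------------------------------
# OU noise sampling
# ---------------------------------------------------------------------------

def sample_ou_noise(spec: NoiseSpec, duration: float, dt: float,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample one stationary OU noise trajectory of shape (T, N).

    The process satisfies ``<eta_i(t) eta_j(t+s)> = Sigma_ij exp(-|s|/tau)``;
    the exact exponential one-step update makes this hold at any ``dt`` and
    the initial state is drawn from the stationary distribution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ou = OUIntegrator(spec, dt)
    N, m = spec.N, ou.m
    n_steps = int(round(duration / dt))
    out = np.empty((n_steps, N))
    eta = ou.stationary(rng.standard_normal((1, m)))
    for t in range(n_steps):
        out[t] = eta[0]
        ou.step(eta, rng.standard_normal((1, m)))
    return out


# ---------------------------------------------------------------------------
# Integration engine
# ---------------------------------------------------------------------------

def _trial_generators(seed: int, n_trials: int) -> list[np.random.Generator]:
    """Independent per-trial RNG streams spawned from a root seed.

    Stream order within each trial: (1) random initial condition, if
    requested; (2) stationary initial OU state; (3) per-step OU increments in
    time order.  Trial k's stream depends only on (seed, k), so the same
    trial is reproducible regardless of batch size.
    """
    root = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in root.spawn(n_trials)]


def simulate(net: NetworkSpec,
             protocol: StimulusProtocol,
             noise: NoiseSpec | None,
             dt: float = 0.1,
             seed: int = 0,
             n_trials: int = 1,
             record_dt: float | None = None,
             count_bin: float | None = None,
             count_start: float = 0.0,
             trial_stats: bool = False,
             init: str | np.ndarray = "rest",
             init_scale: float = 1.0,
             guard: float = 1e3,
             dtype=np.float64) -> SimOutput:
    """Euler-integrate the stochastic rate dynamics, batched over trials.

    Parameters
    ----------
    record_dt
        If set, store voltages every ``record_dt`` ms (must be a multiple of
        ``dt``); otherwise no full voltage record is kept.
    count_bin, count_start
        If ``count_bin`` is set, accumulate the expected spike count
        ``integral of r(V) dt`` per neuron in consecutive bins of that width,
        starting at ``count_start`` (ms).  These integrals feed the doubly
        stochastic Poisson spike-count generator.
    trial_stats
        Store the across-trial mean and variance of V at every recorded step
        (requires ``record_dt``) without keeping per-trial voltages.
    init
        ``"rest"`` (V = Vrest), ``"fixed_point"`` (noiseless fixed point of
        the first segment's input), ``"random"`` (Vrest + init_scale *
        standard normal, per-trial stream), or an explicit length-N vector.
    guard
        Instability guard: |V| exceeding this (mV) raises
        :class:`InstabilityError` naming the first offending step.
    """
    N = net.N
    if dt > 0.1 * float(np.min(net.tau)) + 1e-12:
        raise ConfigurationError(f"dt={dt} exceeds 0.1*min(tau)")
    segments = protocol.resolve(N)
    n_steps = int(round(protocol.duration / dt))

    gens = _trial_generators(seed, n_trials)
    Vrest = float(net.Vrest)

    # initial conditions -----------------------------------------------------
    V = np.full((n_trials, N), Vrest, dtype=dtype)
    if isinstance(init, np.ndarray):
        V[:] = init.astype(dtype)
    elif init == "fixed_point":
        V[:] = fixed_point(net, segments[0][1]).astype(dtype)
    elif init == "random":
        for k, g in enumerate(gens):
            V[k] = Vrest + init_scale * g.standard_normal(N)
    elif init != "rest":
        raise ConfigurationError(f"unknown init {init!r}")

    if noise is not None:
        ou = OUIntegrator(noise, dt, dtype=dtype)
        m = ou.m
        z0 = np.empty((n_trials, m), dtype=dtype)
        for k, g in enumerate(gens):
            z0[k] = g.standard_normal(m)
        eta = np.asarray(ou.stationary(z0), dtype=dtype)
    else:
        eta = None

    # recording setup --------------------------------------------------------
    rec_stride = None
    if record_dt is not None:
        rec_stride = int(round(record_dt / dt))
        if abs(rec_stride * dt - record_dt) > 1e-9:
            raise ConfigurationError("record_dt must be a multiple of dt")
        rec_steps = np.arange(0, n_steps, rec_stride)
        times = rec_steps * dt
        V_rec = (np.empty((n_trials, len(rec_steps), N), dtype=dtype)
                 if not trial_stats else None)
        t_mean = np.empty((len(rec_steps), N)) if trial_stats else None
        t_var = np.empty((len(rec_steps), N)) if trial_stats else None
    else:
        times = V_rec = t_mean = t_var = None
        if trial_stats:
            raise ConfigurationError("trial_stats requires record_dt")

    if count_bin is not None:
        bin_steps = int(round(count_bin / dt))
        start_step = int(round(count_start / dt))
        n_bins = (n_steps - start_step) // bin_steps
        counts = np.zeros((n_trials, n_bins, N))
        bin_times = count_start + count_bin * (np.arange(n_bins) + 0.5)
        acc = np.zeros((n_trials, N), dtype=dtype)
    else:
        counts = bin_times = acc = None

    Wt = np.ascontiguousarray(net.W.T, dtype=dtype)
    inv_tau = (dt / net.tau).astype(dtype)
    nl = net.nonlinearity
    dt_sec = dt / 1000.0

    # noise chunking: bounded scratch memory for pre-drawn normal deviates
    if noise is not None:
        bytes_per_step = n_trials * m * np.dtype(dtype).itemsize
        chunk = int(np.clip(64e6 // max(bytes_per_step, 1), 1, n_steps))
    else:
        chunk = n_steps

    seg_edges = np.cumsum([int(round(d / dt)) for d, _ in segments])
    seg_edges[-1] = n_steps
    seg_idx = 0
    h = segments[0][1].astype(dtype)

    rec_i = 0
    step = 0
    while step < n_steps:
        this_chunk = min(chunk, n_steps - step)
        if noise is not None:
            z = np.empty((n_trials, this_chunk, m), dtype=dtype)
            for k, g in enumerate(gens):
                z[k] = g.standard_normal((this_chunk, m), dtype=dtype) \
                    if dtype == np.float32 else g.standard_normal((this_chunk, m))
        for j in range(this_chunk):
            while step >= seg_edges[seg_idx]:
                seg_idx += 1
                h = segments[seg_idx][1].astype(dtype)
            if rec_stride is not None and step % rec_stride == 0:
                if V_rec is not None:
                    V_rec[:, rec_i, :] = V
                if trial_stats:
                    t_mean[rec_i] = V.mean(axis=0)
                    t_var[rec_i] = V.var(axis=0, ddof=1) if n_trials > 1 else 0.0
                rec_i += 1
            r = nl.rate(V)
            drive = -V + Vrest + h + r @ Wt
            if eta is not None:
                drive += eta
                ou.step(eta, z[:, j, :])
            V += inv_tau * drive
            if counts is not None and step >= start_step:
                b = (step - start_step) // bin_steps
                if b < n_bins:
                    acc += r * dt_sec
                    if (step - start_step) % bin_steps == bin_steps - 1:
                        counts[:, b, :] = acc
                        acc[:] = 0.0
            step += 1
            if step % 200 == 0 or step == n_steps:
                amax = np.abs(V).max()
                if not np.isfinite(amax) or amax > guard:
                    raise InstabilityError(
                        f"|V| exceeded {guard} mV by step {step} (t={step * dt:.1f} ms)"
                    )

    return SimOutput(dt=dt, seed=seed, times=times,
                     V=None if V_rec is None else np.asarray(V_rec, dtype=float),
                     rate_integral=counts, bin_times=bin_times,
                     trial_mean=t_mean, trial_var=t_var,
                     final_V=np.asarray(V, dtype=float), protocol=protocol)


def integrate(net: NetworkSpec,
              protocol: StimulusProtocol,
              noise: NoiseSpec | None,
              dt: float = 0.1,
              seed: int = 0,
              n_trials: int = 1,
              record_dt: float | None = None,
              guard: float = 1e3,
              init: str | np.ndarray = "rest") -> list[Trajectory]:
    """Integrate and return one :class:`Trajectory` per trial.

    Thin wrapper over :func:`simulate` recording voltages at ``record_dt``
    (default: every step).  Deterministic given (seed, dt, n_trials).
    """
    record_dt = dt if record_dt is None else record_dt
    out = simulate(net, protocol, noise, dt=dt, seed=seed, n_trials=n_trials,
                   record_dt=record_dt, guard=guard, init=init)
    return [
        Trajectory(dt=record_dt, times=out.times, V=out.V[k],
                   nonlinearity=net.nonlinearity, protocol=protocol, seed=seed)
        for k in range(n_trials)
    ]


# ---------------------------------------------------------------------------
# Fixed points and linearization
# ---------------------------------------------------------------------------

def _residual(net: NetworkSpec, V: np.ndarray, h: np.ndarray) -> np.ndarray:
    return -V + net.Vrest + h + net.W @ net.rate(V)


def fixed_point(net: NetworkSpec, h, method: str = "relaxation",
                tol: float = 1e-8, max_iter: int = 100_000,
                V0: np.ndarray | None = None,
                check_stability: bool = True) -> np.ndarray:
    """Steady state of the noiseless dynamics for constant input ``h``.

    ``relaxation`` integrates the noiseless ODE to tolerance (robust for the
    stable single-attractor regimes studied here); ``newton`` solves the
    root problem with the analytic Jacobian.  The returned state satisfies
    ``max|residual| < tol`` (mV).  If the Jacobian at the fixed point has an
    eigenvalue with non-negative real part, a :class:`StabilityWarning` is
    issued.
    """
    h = np.broadcast_to(np.asarray(h, dtype=float), (net.N,))
    V = np.full(net.N, float(net.Vrest)) if V0 is None else np.asarray(V0, float).copy()
    if method == "relaxation":
        dt = 0.1 * float(np.min(net.tau))
        step = dt / net.tau
        for it in range(max_iter):
            res = _residual(net, V, h)
            if np.max(np.abs(res)) < tol:
                break
            V = V + step * res
            if not np.all(np.isfinite(V)) or np.max(np.abs(V)) > 1e6:
                raise NoFixedPointError("relaxation diverged")
        else:
            raise NoFixedPointError(f"no convergence after {max_iter} iterations")
    elif method == "newton":
        def fun(v):
            return _residual(net, v, h)

        def jac(v):
            return -np.eye(net.N) + net.W * net.nonlinearity.slope(v)[None, :]

        sol = optimize.root(fun, V, jac=jac, method="hybr",
                            options={"xtol": 1e-12})
        if not sol.success or np.max(np.abs(fun(sol.x))) > tol:
            raise NoFixedPointError(f"newton failed: {sol.message}")
        V = sol.x
    else:
        raise ConfigurationError(f"unknown fixed-point method {method!r}")

    if check_stability:
        ev = np.linalg.eigvals(jacobian(net, V))
        if np.max(ev.real) >= 0:
            warnings.warn(
                f"fixed point is linearly unstable (max Re eig = {ev.real.max():.3g})",
                StabilityWarning, stacklevel=2)
    return V


def effective_weights(net: NetworkSpec, Vbar: np.ndarray) -> np.ndarray:
    """Effective connectivity W_eff[i, j] = W[i, j] * r'(Vbar[j]).

    The slope of the nonlinearity at the operating point scales each
    presynaptic column; for the supralinear SSN this grows with stimulus
    drive, which is what shifts the network between amplifying and
    variability-quenching regimes.
    """
    return net.W * net.nonlinearity.slope(np.asarray(Vbar))[None, :]


def jacobian(net: NetworkSpec, Vbar: np.ndarray) -> np.ndarray:
    """Jacobian A = diag(1/tau) (W_eff - I) of the deterministic dynamics (1/ms)."""
    A = effective_weights(net, Vbar) - np.eye(net.N)
    return A / net.tau[:, None]


def linearized_covariance(net: NetworkSpec, noise: NoiseSpec, h,
                          Vbar: np.ndarray | None = None) -> np.ndarray:
    """Stationary Vm covariance of fluctuations linearized about the fixed point.

    The joint linear system in (dV, eta),

    .. math::
        \\tau\\, d\\delta V = (W_\\mathrm{eff} - I)\\,\\delta V\\,dt + \\eta\\,dt,
        \\qquad
        \\tau_n\\, d\\eta = -\\eta\\,dt + \\sqrt{2\\tau_n \\Sigma}\\, d\\xi,

    has a stationary covariance solving a continuous Lyapunov equation on the
    2N-dimensional augmented state; the dV block is returned (mV^2).
    Raises :class:`InstabilityError` if the Jacobian is unstable.
    """
    h = np.broadcast_to(np.asarray(h, dtype=float), (net.N,))
    if Vbar is None:
        Vbar = fixed_point(net, h, check_stability=False)
    N = net.N
    A_V = jacobian(net, Vbar)
    if np.max(np.linalg.eigvals(A_V).real) >= 0:
        raise InstabilityError("unstable Jacobian: no stationary covariance")
    tau_n = noise.tau_noise
    A = np.zeros((2 * N, 2 * N))
    A[:N, :N] = A_V
    A[:N, N:] = np.diag(1.0 / net.tau)
    A[N:, N:] = -np.eye(N) / tau_n
    Q = np.zeros((2 * N, 2 * N))
    Q[N:, N:] = 2.0 * noise.covariance() / tau_n
    C = linalg.solve_continuous_lyapunov(A, -Q)
    C = 0.5 * (C + C.T)
    return C[:N, :N]
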