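"""Event-based stochastic spiking SSN and spike-count generation.

Each neuron emits spikes as a Bernoulli event per Euler step with
probability ``dt * r(V_i)`` (an inhomogeneous Poisson process in the small-
``dt`` limit).  Spikes are filtered into exponentially decaying synaptic
traces after a fixed axonal delay and re-enter the voltage dynamics through
sparse random connectivity whose efficacies are scaled so the mean
recurrent drive matches the reduced two-population rate model,
``J_ij = W_ab / (tau_syn p_b N_b)``.

Also provides the LFP proxy (momentary population-averaged Vm) and the
doubly stochastic Poisson spike-count generator used with the rate models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .core_dynamics import (
    ConfigurationError,
    InstabilityError,
    Nonlinearity,
    OUIntegrator,
    SimOutput,
    StimulusProtocol,
    _trial_generators,
)
from .architectures import DEFAULT_WEIGHTS, noise_sigma, uniform_noise_cov

__all__ = [
    "SpikingNetSpec",
    "SpikeData",
    "build_connectivity",
    "simulate_spiking",
    "lfp_proxy",
    "poisson_counts",
]


@dataclass(frozen=True)
class SpikingNetSpec:
    """Sparse random spiking SSN (defaults: full-scale table values)."""

    N_E: int = 4000
    N_I: int = 1000
    p_E: float = 0.1
    p_I: float = 0.4
    tau_syn: float = 2.0    # ms
    delay: float = 0.5      # ms
    tau_E: float = 20.0
    tau_I: float = 10.0
    Vrest: float = -70.0
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    nonlinearity: Nonlinearity = Nonlinearity.powerlaw()
    sigma_0E: float = 1.0
    sigma_0I: float = 0.5
    rho: float = 0.2
    tau_noise: float = 50.0

    @property
    def N(self) -> int:
        return self.N_E + self.N_I

    @property
    def in_degree(self) -> tuple[int, int]:
        """Exact (E, I) in-degree of every neuron."""
        return int(round(self.p_E * self.N_E)), int(round(self.p_I * self.N_I))

    @classmethod
    def quarter_scale(cls, **kwargs) -> "SpikingNetSpec":
        """1/4-scale preset (1000 E / 250 I); J rescales automatically."""
        return cls(N_E=1000, N_I=250, **kwargs)

    def tau(self) -> np.ndarray:
        return np.concatenate([np.full(self.N_E, self.tau_E),
                               np.full(self.N_I, self.tau_I)])

    def noise_spec(self):
        sig = np.concatenate([
            np.full(self.N_E, noise_sigma(self.sigma_0E, self.tau_E, self.tau_noise)),
            np.full(self.N_I, noise_sigma(self.sigma_0I, self.tau_I, self.tau_noise)),
        ])
        return uniform_noise_cov(self.N, sig, self.rho, tau_noise=self.tau_noise)


@dataclass
class SpikeData:
    """Per-trial spike events and binned count matrices."""

    events: list  # one (neuron_id array, time_ms array) pair per trial
    duration: float
    n_neurons: int

    def counts(self, bin_ms: float, t_start: float = 0.0,
               t_stop: float | None = None) -> np.ndarray:
        """Histogram events into (trials, bins, neurons) count matrices."""
        t_stop = self.duration if t_stop is None else t_stop
        n_bins = int((t_stop - t_start) // bin_ms)
        out = np.zeros((len(self.events), n_bins, self.n_neurons), dtype=np.int64)
        edges = t_start + bin_ms * np.arange(n_bins + 1)
        for k, (ids, times) in enumerate(self.events):
            m = (times >= t_start) & (times < edges[-1])
            b = ((times[m] - t_start) // bin_ms).astype(int)
            np.add.at(out[k], (b, ids[m]), 1)
        return out


def build_connectivity(spec: SpikingNetSpec, seed: int = 0) -> sparse.csr_matrix:
    """Signed synaptic efficacy matrix J (mV), exact in-degree per neuron.

    Every neuron receives exactly ``p_E N_E`` excitatory and ``p_I N_I``
    inhibitory presynaptic partners drawn uniformly without replacement.
    Realised efficacies are ``W_ab / (tau_syn p_b N_b)`` with the sign of
    the presynaptic population (tau_syn in seconds so that J * a is in mV
    for unit-jump traces and rates in s^-1).
    """
    rng = np.random.default_rng(seed)
    kE, kI = spec.in_degree
    tau_syn_s = spec.tau_syn / 1000.0
    w = spec.weights
    jE = {True: w["EE"] / (tau_syn_s * spec.p_E * spec.N_E),
          False: w["IE"] / (tau_syn_s * spec.p_E * spec.N_E)}
    jI = {True: -w["EI"] / (tau_syn_s * spec.p_I * spec.N_I),
          False: -w["II"] / (tau_syn_s * spec.p_I * spec.N_I)}
    rows, cols, vals = [], [], []
    for i in range(spec.N):
        post_e = i < spec.N_E
        pre_E = rng.choice(spec.N_E, size=kE, replace=False)
        pre_I = spec.N_E + rng.choice(spec.N_I, size=kI, replace=False)
        rows.append(np.full(kE + kI, i))
        cols.append(np.concatenate([pre_E, pre_I]))
        vals.append(np.concatenate([np.full(kE, jE[post_e]),
                                    np.full(kI, jI[post_e])]))
    J = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(spec.N, spec.N))
    return J


def simulate_spiking(spec: SpikingNetSpec,
                     protocol: StimulusProtocol,
                     dt: float = 0.1,
                     seed: int = 0,
                     n_trials: int = 1,
                     record_dt: float | None = None,
                     record_cells: np.ndarray | None = None,
                     J: sparse.csr_matrix | None = None,
                     connectivity_seed: int | None = None,
                     rate_guard: float = 0.2) -> tuple[SpikeData, SimOutput]:
    """Simulate the stochastic spiking SSN.

    Per step each neuron fires with probability ``dt * r(V_i)`` (dt in s);
    a guard raises if this exceeds ``rate_guard``.  Spikes increment the
    presynaptic trace ``a_j`` (unit jump, exponential decay ``tau_syn``)
    after the axonal delay, and voltages follow the same leaky dynamics as
    the rate model with recurrent drive ``J a`` and shared-plus-private OU
    noise (uniform correlations ``rho``).

    Returns spike events plus a voltage record (``record_dt`` resolution,
    optionally restricted to ``record_cells``).
    """
    N = spec.N
    if J is None:
        J = build_connectivity(
            spec, seed if connectivity_seed is None else connectivity_seed)
    n_steps = int(round(protocol.duration / dt))
    segments = protocol.resolve(N)
    seg_edges = np.cumsum([int(round(d / dt)) for d, _ in segments])
    seg_edges[-1] = n_steps
    delay_steps = max(int(round(spec.delay / dt)), 1)
    syn_decay = np.exp(-dt / spec.tau_syn)
    tau = spec.tau()
    inv_tau = dt / tau
    dt_sec = dt / 1000.0
    noise = spec.noise_spec()
    ou = OUIntegrator(noise, dt)
    gens = _trial_generators(seed, n_trials)

    rec_stride = None
    cells = np.arange(N) if record_cells is None else np.asarray(record_cells)
    if record_dt is not None:
        rec_stride = int(round(record_dt / dt))
        rec_steps = np.arange(0, n_steps, rec_stride)
        V_rec = np.empty((n_trials, len(rec_steps), len(cells)))
        times = rec_steps * dt
    else:
        V_rec = times = None

    events = []
    for k, g in enumerate(gens):
        V = np.full(N, float(spec.Vrest))
        eta = ou.stationary(g.standard_normal((1, ou.m)))[0]
        a = np.zeros(N)
        ring = [np.zeros(N) for _ in range(delay_steps)]
        ids_list, t_list = [], []
        seg_idx = 0
        h = segments[0][1]
        rec_i = 0
        for step in range(n_steps):
            while step >= seg_edges[seg_idx]:
                seg_idx += 1
                h = segments[seg_idx][1]
            if rec_stride is not None and step % rec_stride == 0:
                V_rec[k, rec_i] = V[cells]
                rec_i += 1
            r = spec.nonlinearity.rate(V)
            p = dt_sec * r
            pmax = p.max()
            if pmax > rate_guard:
                raise ConfigurationError(
                    f"dt*r = {pmax:.3f} exceeds the {rate_guard} guard at "
                    f"step {step}; reduce dt")
            spikes = g.random(N) < p
            if np.any(spikes):
                ids = np.flatnonzero(spikes)
                ids_list.append(ids)
                t_list.append(np.full(len(ids), step * dt))
            # delayed entry into synaptic traces
            a *= syn_decay
            a += ring[step % delay_steps]
            ring[step % delay_steps] = spikes.astype(float)
            drive = -V + spec.Vrest + h + eta + J @ a
            ou.step(eta[None, :], g.standard_normal((1, ou.m)))
            V += inv_tau * drive
            if step % 500 == 499 and not np.all(np.isfinite(V)):
                raise InstabilityError(f"non-finite voltage at step {step}")
        events.append((
            np.concatenate(ids_list) if ids_list else np.empty(0, dtype=int),
            np.concatenate(t_list) if t_list else np.empty(0),
        ))

    spikes_out = SpikeData(events=events, duration=protocol.duration, n_neurons=N)
    traj = SimOutput(dt=dt, seed=seed, times=times, V=V_rec, protocol=protocol)
    return spikes_out, traj


def lfp_proxy(V: np.ndarray, population: np.ndarray | None = None) -> np.ndarray:
    """LFP proxy: momentary unweighted population-averaged Vm.

    ``V`` is (..., T, N); returns (..., T).  ``population`` optionally
    restricts the average to a subset of neurons (default: all).
    """
    V = np.asarray(V)
    if population is not None:
        V = V[..., population]
    return V.mean(axis=-1)


def poisson_counts(rate_integral: np.ndarray, seed: int = 0) -> np.ndarray:
    """Doubly stochastic Poisson spike counts from expected-count integrals.

    ``rate_integral`` holds ``integral of r dt`` per (trial, bin, neuron) as
    produced by the rate-model engine; counts are conditionally independent
    Poisson draws given the rates, so across-trial count variability is
    Poisson noise plus the underlying rate variability
    (Fano = 1 + Var(integral)/Mean(integral)).
    """
    lam = np.asarray(rate_integral)
    if np.any(lam < 0):
        raise ConfigurationError("rate integrals must be non-negative")
    return np.random.default_rng(seed).poisson(lam)
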