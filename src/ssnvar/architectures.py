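"""Concrete network architectures and their inputs and noise covariances.

Five models are built here, all sharing the dynamical core in
:mod:`ssnvar.core_dynamics`:

* a reduced two-population SSN (one E and one I unit),
* a ring SSN (50 E + 50 I units arranged by preferred angle),
* the sparse spiking SSN connectivity (see :mod:`ssnvar.spiking_sim`),
* a marginally stable multi-attractor ring network (single population,
  purely inhibitory cosine connectivity, saturating rectified-tanh rates),
* a chaotic random rate network (Gaussian weights, tanh rates, no noise).

Angular length scales (``ell_syn``, ``ell_noise``, ``ell_stim``) are given in
degrees on the full 360-degree circle and are converted to radians inside
the circular-Gaussian profile ``exp((cos(dtheta) - 1)/ell^2)``; angles halve
when read out as orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_dynamics import (
    ConfigurationError,
    NetworkSpec,
    NoiseSpec,
    Nonlinearity,
)

__all__ = [
    "TwoPopParams",
    "RingGeometry",
    "RingInputParams",
    "MultiAttractorParams",
    "ChaoticParams",
    "build_two_pop",
    "build_ring_ssn",
    "build_ring",
    "ring_input",
    "ring_noise_cov",
    "uniform_noise_cov",
    "build_multiattractor",
    "multiattractor_input",
    "build_chaotic",
    "chaotic_input",
    "noise_sigma",
]

# Reduced-model synaptic weight magnitudes (mV*s), shared by the two-pop,
# ring and spiking SSN variants.
DEFAULT_WEIGHTS = {"EE": 1.25, "IE": 1.2, "EI": 0.65, "II": 0.5}


def noise_sigma(sigma_0: float, tau_m: float, tau_noise: float) -> float:
    """Noise amplitude scaling sigma = sigma_0 * sqrt(1 + tau_m/tau_noise).

    With this scaling an isolated unit (W = 0) driven by OU noise shows
    stationary Vm fluctuations of standard deviation exactly ``sigma_0``.
    """
    return sigma_0 * np.sqrt(1.0 + tau_m / tau_noise)


def _circ_gauss(dtheta_deg: np.ndarray, ell_deg: float) -> np.ndarray:
    """Circular-Gaussian profile exp((cos(dtheta) - 1)/ell^2), ell in degrees."""
    ell = np.deg2rad(ell_deg)
    return np.exp((np.cos(np.deg2rad(dtheta_deg)) - 1.0) / ell**2)


# ---------------------------------------------------------------------------
# Two-population SSN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoPopParams:
    """Reduced two-population SSN parameters (defaults: table values)."""

    W_EE: float = 1.25
    W_IE: float = 1.2
    W_EI: float = 0.65
    W_II: float = 0.5
    tau_E: float = 20.0
    tau_I: float = 10.0
    Vrest: float = -70.0
    k: float = 0.3
    n: float = 2.0
    V0: float = -70.0
    sigma_0E: float = 0.2
    sigma_0I: float = 0.1
    tau_noise: float = 50.0


def build_two_pop(params: TwoPopParams | None = None) -> tuple[NetworkSpec, NoiseSpec]:
    """Two-unit SSN with signed weights [[WEE, -WEI], [WIE, -WII]].

    Noise is uncorrelated between the units, with per-population variances
    scaled so that the uncoupled fluctuation size is sigma_0E / sigma_0I.
    """
    p = params or TwoPopParams()
    for name in ("W_EE", "W_IE", "W_EI", "W_II"):
        if getattr(p, name) < 0:
            raise ConfigurationError(f"{name} must be a non-negative magnitude")
    W = np.array([[p.W_EE, -p.W_EI], [p.W_IE, -p.W_II]])
    net = NetworkSpec(
        N_E=1, N_I=1, W=W, tau=np.array([p.tau_E, p.tau_I]), Vrest=p.Vrest,
        nonlinearity=Nonlinearity.powerlaw(k=p.k, n=p.n, V0=p.V0), dale=True)
    sig_E = noise_sigma(p.sigma_0E, p.tau_E, p.tau_noise)
    sig_I = noise_sigma(p.sigma_0I, p.tau_I, p.tau_noise)
    noise = NoiseSpec(tau_noise=p.tau_noise, Sigma=np.diag([sig_E**2, sig_I**2]))
    return net, noise


# ---------------------------------------------------------------------------
# Ring SSN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RingGeometry:
    """Units evenly spaced on the full circle; E and I co-located pairwise."""

    N_E: int = 50
    N_I: int = 50
    ell_syn: float = 45.0
    ell_noise: float = 60.0
    ell_stim: float = 60.0

    @property
    def N(self) -> int:
        return self.N_E + self.N_I

    @property
    def theta_E(self) -> np.ndarray:
        return np.linspace(0.0, 360.0, self.N_E, endpoint=False)

    @property
    def theta_I(self) -> np.ndarray:
        return np.linspace(0.0, 360.0, self.N_I, endpoint=False) if self.N_I else np.empty(0)

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.theta_E, self.theta_I])


@dataclass(frozen=True)
class RingInputParams:
    """Circular-Gaussian stimulus input on the ring."""

    b: float = 2.0        # baseline (mV)
    A_max: float = 20.0   # modulation at 100% contrast (mV)
    c: float = 1.0        # contrast in [0, 1]
    theta_stim: float = 0.0  # stimulus angle (deg)

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise ConfigurationError("contrast c must lie in [0, 1]")
        if self.b < 0 or self.A_max < 0:
            raise ConfigurationError("b and A_max must be non-negative")


def build_ring_ssn(geometry: RingGeometry | None = None,
                   weights: dict[str, float] | None = None,
                   tau_E: float = 20.0, tau_I: float = 10.0,
                   Vrest: float = -70.0,
                   nonlinearity: Nonlinearity | None = None) -> NetworkSpec:
    """Ring SSN connectivity: circular-Gaussian profile, row/quadrant rescaled.

    Weights fall off with angular distance with length scale ``ell_syn``;
    each row of each of the four (post, pre) population quadrants is then
    rescaled so the summed incoming E and I weights onto every neuron match
    the reduced-model magnitudes (W_EE, W_IE, -W_EI, -W_II) exactly.
    """
    geo = geometry or RingGeometry()
    wts = dict(DEFAULT_WEIGHTS, **(weights or {}))
    theta = geo.theta
    prof = _circ_gauss(theta[:, None] - theta[None, :], geo.ell_syn)
    e = np.zeros(geo.N, dtype=bool)
    e[: geo.N_E] = True
    W = np.zeros((geo.N, geo.N))
    targets = {
        (True, True): wts["EE"], (False, True): wts["IE"],
        (True, False): -wts["EI"], (False, False): -wts["II"],
    }
    for post_is_e in (True, False):
        rows = e if post_is_e else ~e
        for pre_is_e in (True, False):
            cols = e if pre_is_e else ~e
            block = prof[np.ix_(rows, cols)]
            rowsum = block.sum(axis=1, keepdims=True)
            if np.any(rowsum == 0):
                raise ConfigurationError("zero profile row: cannot rescale")
            W[np.ix_(rows, cols)] = targets[(post_is_e, pre_is_e)] * block / rowsum
    tau = np.where(e, tau_E, tau_I)
    nl = nonlinearity or Nonlinearity.powerlaw()
    return NetworkSpec(N_E=geo.N_E, N_I=geo.N_I, W=W, tau=tau, Vrest=Vrest,
                       nonlinearity=nl, theta=theta, dale=True)


def ring_input(params: RingInputParams, geometry: RingGeometry) -> np.ndarray:
    """Mean input h_i = b + c * A_max * exp((cos(theta_i - theta_stim) - 1)/ell_stim^2).

    E and I cells at the same angle receive identical input.
    """
    p = params
    return p.b + p.c * p.A_max * _circ_gauss(geometry.theta - p.theta_stim,
                                             geometry.ell_stim)


def ring_noise_cov(geometry: RingGeometry,
                   sigma_0E: float = 1.0, sigma_0I: float = 0.5,
                   tau_E: float = 20.0, tau_I: float = 10.0,
                   tau_noise: float = 50.0) -> NoiseSpec:
    """Ring noise covariance: amplitudes per population, circular-Gaussian correlations.

    Sigma_ij = sigma_a(i) sigma_a(j) exp((cos(theta_i - theta_j) - 1)/ell_noise^2),
    with sigma_a = sigma_0a * sqrt(1 + tau_a/tau_noise).
    """
    geo = geometry
    sig = np.concatenate([
        np.full(geo.N_E, noise_sigma(sigma_0E, tau_E, tau_noise)),
        np.full(geo.N_I, noise_sigma(sigma_0I, tau_I, tau_noise)),
    ])
    theta = geo.theta
    corr = _circ_gauss(theta[:, None] - theta[None, :], geo.ell_noise)
    return NoiseSpec(tau_noise=tau_noise, Sigma=np.outer(sig, sig) * corr)


def build_ring(geometry: RingGeometry | None = None,
               sigma_0E: float = 1.0, sigma_0I: float = 0.5,
               tau_noise: float = 50.0,
               **net_kwargs) -> tuple[NetworkSpec, NoiseSpec]:
    """Convenience constructor: ring SSN network + its table noise covariance."""
    geo = geometry or RingGeometry()
    net = build_ring_ssn(geo, **net_kwargs)
    noise = ring_noise_cov(geo, sigma_0E=sigma_0E, sigma_0I=sigma_0I,
                           tau_noise=tau_noise)
    return net, noise


# ---------------------------------------------------------------------------
# Uniform (compound-symmetric) noise, used by the spiking SSN
# ---------------------------------------------------------------------------

def uniform_noise_cov(N: int, sigma, rho: float,
                      tau_noise: float = 50.0) -> NoiseSpec:
    """Compound-symmetric covariance Sigma_ij = s_i s_j [delta_ij (1-rho) + rho].

    ``sigma`` may be a scalar or a per-unit vector.  Sampling uses the exact
    low-rank form eta = sqrt(1-rho) s z_i + sqrt(rho) s z0 with a single
    shared deviate z0, avoiding the dense N x N matrix.
    """
    if not 0.0 <= rho <= 1.0:
        raise ConfigurationError("rho must lie in [0, 1]")
    s = np.broadcast_to(np.asarray(sigma, dtype=float), (N,))
    return NoiseSpec(tau_noise=tau_noise, diag_amp=np.sqrt(1.0 - rho) * s,
                     shared_amp=np.sqrt(rho) * s)


# ---------------------------------------------------------------------------
# Multi-attractor ring network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiAttractorParams:
    """Marginally stable ring network (single population, inhibitory weights).

    ``gmax`` is read as the 100 s^-1 saturation rate of the rectified-tanh
    nonlinearity with gain ``k`` = 0.1 mV^-1; the connectivity parameters are
    conventionally quoted as -40/gmax and 33/gmax (mV*s).
    """

    N: int = 100
    gmax: float = 100.0
    k: float = 0.1
    W_bar: float = -40.0 / 100.0   # summed (row-total) weight, mV*s
    W_delta: float = 33.0 / 100.0  # cosine modulation of the row profile, mV*s
    tau_m: float = 10.0
    sigma_0: float = 0.15
    ell_noise: float = 60.0
    ell_stim: float = 60.0
    tau_noise: float = 50.0
    b: float = 2.0
    A: float = 0.1


def build_multiattractor(params: MultiAttractorParams | None = None,
                         ) -> tuple[NetworkSpec, NoiseSpec]:
    """Cosine connectivity W_ij = (W_bar + W_delta cos(theta_i - theta_j)) / N.

    ``W_bar`` is the summed incoming weight (the row total, -40/gmax mV*s)
    and ``W_delta`` the cosine modulation of the row profile; with the default
    parameters all connections are inhibitory.  The uniform activity mode is
    then strongly stabilised (total rate regulation) while the two cosine
    modes, with effective gain W_delta/2 * r', sit just beyond the margin of
    stability: a bump of activity forms spontaneously at a noise-selected
    position and drifts freely around the ring (the attractor continuum).
    Dynamics follow the same voltage equation as the SSN with Vrest = 0 and
    a saturating rectified-tanh rate function.
    """
    p = params or MultiAttractorParams()
    theta = np.linspace(0.0, 360.0, p.N, endpoint=False)
    dtheta = np.deg2rad(theta[:, None] - theta[None, :])
    W = (p.W_bar + p.W_delta * np.cos(dtheta)) / p.N
    if np.any(W >= 0):
        raise ConfigurationError(
            "multi-attractor weights must all be inhibitory with table parameters")
    net = NetworkSpec(N_E=0, N_I=p.N, W=W, tau=p.tau_m, Vrest=0.0,
                      nonlinearity=Nonlinearity.rect_tanh(k=p.k, gmax=p.gmax),
                      theta=theta)
    sig = noise_sigma(p.sigma_0, p.tau_m, p.tau_noise)
    corr = _circ_gauss(theta[:, None] - theta[None, :], p.ell_noise)
    noise = NoiseSpec(tau_noise=p.tau_noise, Sigma=sig**2 * corr)
    return net, noise


def multiattractor_input(params: MultiAttractorParams, c: float,
                         theta_stim: float = 0.0) -> np.ndarray:
    """Input h_i = b + c (1 - A + A cos(theta_i - theta_stim))."""
    p = params
    theta = np.linspace(0.0, 360.0, p.N, endpoint=False)
    return p.b + c * (1.0 - p.A
                      + p.A * np.cos(np.deg2rad(theta - theta_stim)))


# ---------------------------------------------------------------------------
# Chaotic random network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChaoticParams:
    """Classical chaotic rate network: Gaussian weights, tanh rates, no noise."""

    N: int = 2000
    sigma_W: float = 2.0
    tau_m: float = 10.0


def build_chaotic(params: ChaoticParams | None = None,
                  seed: int = 0) -> tuple[NetworkSpec, np.ndarray]:
    """Random network W_ij ~ N(0, sigma_W^2/N) plus fixed random input phases.

    Returns the network and the phase vector phi (uniform on [0, 2pi)); the
    stimulus of strength ``c`` is the constant vector ``h_i = c cos(phi_i)``.
    With sigma_W = 2 the spectral radius of W is ~2 and the autonomous
    dynamics are chaotic; sufficiently strong input entrains the trajectories
    and suppresses the chaos.
    """
    p = params or ChaoticParams()
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, p.sigma_W / np.sqrt(p.N), size=(p.N, p.N))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=p.N)
    net = NetworkSpec(N_E=0, N_I=p.N, W=W, tau=p.tau_m, Vrest=0.0,
                      nonlinearity=Nonlinearity.pure_tanh())
    return net, phi


def chaotic_input(phi: np.ndarray, c: float) -> np.ndarray:
    """Constant stimulus vector h_i = c * cos(phi_i)."""
    return c * np.cos(phi)
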