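"""Unit and property tests for the dynamical core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssnvar.core_dynamics import (
    ConfigurationError,
    InstabilityError,
    InvalidCovarianceError,
    NetworkSpec,
    NoiseSpec,
    Nonlinearity,
    StimulusProtocol,
    effective_weights,
    eval_nonlinearity,
    fixed_point,
    integrate,
    jacobian,
    linearized_covariance,
    sample_ou_noise,
    simulate,
)


class TestNonlinearity:
    @pytest.mark.parametrize("V,expected", [(-70.0, 0.0), (-60.0, 30.0),
                                            (-80.0, 0.0)])
    def test_powerlaw_values(self, V, expected):
        """Threshold-quadratic: zero at/below threshold, k*(V-V0)^n above."""
        nl = Nonlinearity.powerlaw(k=0.3, n=2, V0=-70.0)
        assert eval_nonlinearity(nl, np.array([V]))[0] == pytest.approx(expected)

    def test_rect_tanh_limits(self):
        nl = Nonlinearity.rect_tanh(k=0.1, gmax=100.0)
        assert nl.rate(np.array([-5.0]))[0] == 0.0
        assert nl.rate(np.array([1e4]))[0] == pytest.approx(100.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            Nonlinearity("sigmoid")

    @given(st.floats(-100, 100))
    @settings(deadline=None, max_examples=50)
    def test_ranges_and_slopes(self, V):
        """Range invariants of all three nonlinearities, and analytic slopes
        matching central finite differences away from the kinks."""
        v = np.array([V])
        pl = Nonlinearity.powerlaw()
        rt = Nonlinearity.rect_tanh()
        th = Nonlinearity.pure_tanh()
        assert pl.rate(v)[0] >= 0.0
        assert 0.0 <= rt.rate(v)[0] <= 100.0
        assert -1.0 <= th.rate(v)[0] <= 1.0
        eps = 1e-4
        for nl, kink in ((pl, -70.0), (rt, 0.0), (th, None)):
            if kink is not None and abs(V - kink) < 1e-2:
                continue
            fd = (nl.rate(v + eps) - nl.rate(v - eps))[0] / (2 * eps)
            assert nl.slope(v)[0] == pytest.approx(fd, abs=1e-4, rel=1e-3)


class TestOUNoise:
    def test_zero_sigma_gives_zero(self):
        spec = NoiseSpec(tau_noise=50.0, Sigma=np.zeros((3, 3)))
        traj = sample_ou_noise(spec, 100.0, 1.0, seed=0)
        assert np.all(traj == 0.0)

    def test_stationary_variance_and_autocovariance(self):
        """Scalar OU: empirical variance -> sigma^2 and autocovariance at lag
        tau_noise -> sigma^2/e (exact one-step update at dt comparable to tau)."""
        sigma2 = 4.0
        spec = NoiseSpec(tau_noise=50.0, Sigma=np.array([[sigma2]]))
        traj = sample_ou_noise(spec, 400_000.0, 5.0, seed=3)[:, 0]
        n_eff = len(traj) * 5.0 / (2 * 50.0)
        tol = 4 * sigma2 * np.sqrt(2.0 / n_eff)
        assert traj.var() == pytest.approx(sigma2, abs=tol)
        lag = 10  # 50 ms at dt = 5 ms
        acov = np.mean(traj[:-lag] * traj[lag:])
        assert acov == pytest.approx(sigma2 / np.e, abs=3 * tol)

    def test_invalid_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalue -1
        with pytest.raises(InvalidCovarianceError):
            NoiseSpec(tau_noise=50.0, Sigma=bad).sampling_factor()

    def test_small_negative_eigenvalues_clipped(self):
        eps = 1e-13
        sig = np.array([[1.0, 1.0], [1.0, 1.0 - eps]])
        B = NoiseSpec(tau_noise=50.0, Sigma=sig).sampling_factor()
        assert np.allclose(B @ B.T, sig, atol=1e-10)

    def test_compound_representation_matches_dense(self, rng):
        """Low-rank uniform-correlation sampling reproduces the dense
        covariance sigma^2[(1-rho) I + rho 11^T]."""
        from ssnvar.architectures import uniform_noise_cov
        N, sigma, rho = 4, 1.5, 0.2
        spec = uniform_noise_cov(N, sigma, rho)
        dense = sigma**2 * ((1 - rho) * np.eye(N) + rho * np.ones((N, N)))
        assert np.allclose(spec.covariance(), dense)
        z = rng.standard_normal((200_000, spec.sampling_dim))
        emp = np.cov(spec.transform(z).T)
        assert np.allclose(emp, dense, atol=0.05)


class TestIntegrate:
    def test_rc_response(self):
        """W=0, no noise, h=10: V relaxes to Vrest+10 with time constant tau."""
        nl = Nonlinearity.powerlaw()
        net = NetworkSpec(N_E=1, N_I=0, W=np.zeros((1, 1)), tau=20.0,
                          Vrest=-70.0, nonlinearity=nl)
        traj = integrate(net, StimulusProtocol.constant(10.0, 200.0),
                         None, dt=0.1, seed=0)[0]
        V = traj.V[:, 0]
        i_tau = np.searchsorted(traj.times, 20.0)
        assert V[i_tau] == pytest.approx(-70.0 + 10.0 * (1 - np.exp(-1)), abs=0.05)
        assert V[-1] == pytest.approx(-60.0, abs=1e-3)

    def test_uncoupled_stationary_std_matches_sigma0(self):
        """W=0 with the scaled noise amplitude gives Vm std = sigma_0 exactly
        (closed form) and within MC error in simulation."""
        from ssnvar.architectures import build_two_pop
        net, noise = build_two_pop()
        net0 = NetworkSpec(N_E=1, N_I=1, W=np.zeros((2, 2)), tau=net.tau,
                           Vrest=-70.0, nonlinearity=net.nonlinearity)
        assert np.allclose(np.diag(linearized_covariance(net0, noise, 0.0)),
                           [0.2**2, 0.1**2], rtol=1e-8)
        out = simulate(net0, StimulusProtocol.constant(0.0, 4000.0), noise,
                       dt=0.1, seed=9, n_trials=60, record_dt=1.0,
                       init="fixed_point")
        std = out.V[:, 500:, :].reshape(-1, 2).std(axis=0)
        assert std == pytest.approx([0.2, 0.1], rel=0.05)

    def test_bit_reproducible_and_trial_streams(self, two_pop):
        """Same (seed, dt) -> identical output; trial k's trajectory does not
        depend on how many trials are in the batch."""
        net, noise = two_pop
        proto = StimulusProtocol.constant(2.0, 50.0)
        a = simulate(net, proto, noise, dt=0.1, seed=7, n_trials=3, record_dt=1.0)
        b = simulate(net, proto, noise, dt=0.1, seed=7, n_trials=3, record_dt=1.0)
        assert np.array_equal(a.V, b.V)
        solo = simulate(net, proto, noise, dt=0.1, seed=7, n_trials=1, record_dt=1.0)
        assert np.allclose(a.V[0], solo.V[0])

    def test_guard_raises_on_divergence(self):
        nl = Nonlinearity.pure_tanh()
        net = NetworkSpec(N_E=1, N_I=0, W=np.zeros((1, 1)), tau=10.0,
                          Vrest=0.0, nonlinearity=nl)
        with pytest.raises(InstabilityError, match="step"):
            simulate(net, StimulusProtocol.constant(1e5, 100.0), None,
                     dt=1.0, seed=0, guard=1e3)

    def test_dt_precondition(self, two_pop):
        net, noise = two_pop
        with pytest.raises(ConfigurationError):
            simulate(net, StimulusProtocol.constant(0.0, 10.0), noise, dt=2.0)

    def test_trajectory_rate_consistency(self, two_pop):
        net, noise = two_pop
        traj = integrate(net, StimulusProtocol.constant(2.0, 20.0), noise,
                         seed=1)[0]
        assert np.allclose(traj.r, net.nonlinearity.rate(traj.V))


class TestFixedPoint:
    def test_uncoupled_exact(self):
        net = NetworkSpec(N_E=1, N_I=0, W=np.zeros((1, 1)), tau=20.0,
                          Vrest=-70.0, nonlinearity=Nonlinearity.powerlaw())
        assert fixed_point(net, 5.0)[0] == pytest.approx(-65.0, abs=1e-8)

    @pytest.mark.parametrize("h", [0.0, 2.0, 15.0])
    def test_relaxation_newton_agree(self, two_pop, h):
        net, _ = two_pop
        Vr = fixed_point(net, h, method="relaxation")
        Vn = fixed_point(net, h, method="newton")
        assert np.max(np.abs(Vr - Vn)) < 1e-6

    def test_rates_supralinear_then_sublinear(self, two_pop):
        """E rates grow supralinearly at small h, sublinearly at large h, and
        the I/E rate ratio increases with h (inhibition-dominated regime)."""
        net, _ = two_pop
        hs = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        rates = np.array([net.rate(fixed_point(net, h)) for h in hs])
        rE, rI = rates[:, 0], rates[:, 1]
        # supralinear: doubling small h more than doubles the rate
        assert rE[1] > 2 * rE[0]
        # sublinear: doubling large h less than doubles the rate
        assert rE[4] < 2 * rE[3]
        ratio = rI / rE
        assert np.all(np.diff(ratio) > 0)


class TestLinearization:
    def test_effective_weights_zero_at_threshold(self, two_pop):
        net, _ = two_pop
        Vbar = np.full(2, -70.0)
        assert np.all(effective_weights(net, Vbar) == 0.0)

    def test_effective_weights_scale_linearly(self, two_pop):
        """For n=2 the slope is 2k(V-V0): doubling the suprathreshold voltage
        doubles every effective weight."""
        net, _ = two_pop
        W1 = effective_weights(net, np.array([-68.0, -68.0]))
        W2 = effective_weights(net, np.array([-66.0, -66.0]))
        assert np.allclose(W2, 2 * W1)

    def test_effective_connectivity_grows_with_h(self, two_pop):
        net, _ = two_pop
        W2 = effective_weights(net, fixed_point(net, 2.0))
        W15 = effective_weights(net, fixed_point(net, 15.0))
        assert np.all(np.abs(W15) > np.abs(W2))

    def test_uncoupled_covariance_closed_form(self, two_pop):
        net, noise = two_pop
        net0 = NetworkSpec(N_E=1, N_I=1, W=np.zeros((2, 2)), tau=net.tau,
                           Vrest=-70.0, nonlinearity=net.nonlinearity)
        C = linearized_covariance(net0, noise, 3.0)
        assert np.allclose(C, np.diag([0.04, 0.01]), atol=1e-10)

    def test_unstable_jacobian_raises(self):
        net = NetworkSpec(N_E=1, N_I=0, W=np.array([[30.0]]), tau=10.0,
                          Vrest=0.0, nonlinearity=Nonlinearity.pure_tanh())
        noise = NoiseSpec(tau_noise=50.0, Sigma=np.array([[1.0]]))
        with pytest.raises(InstabilityError):
            linearized_covariance(net, noise, 0.0, Vbar=np.zeros(1))

    def test_nonmonotonic_variability(self, two_pop):
        """std(V_E)(h) rises then falls: single interior peak over 0..20 mV."""
        net, noise = two_pop
        hs = np.arange(0.0, 20.5, 0.5)
        stds = np.array([np.sqrt(linearized_covariance(net, noise, h)[0, 0])
                         for h in hs])
        i = int(np.argmax(stds))
        assert 0 < i < len(hs) - 1
        assert np.all(np.diff(stds[: i + 1]) > 0)
        assert np.all(np.diff(stds[i:]) < 0)
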