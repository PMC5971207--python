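"""Tests of the variability-analysis suite on synthetic data with known truth."""

import numpy as np
import pytest

from ssnvar.core_dynamics import ConfigurationError, Nonlinearity
from ssnvar.analysis import (
    UndefinedTimescaleError,
    bump_fit,
    covariance_templates,
    factor_analysis,
    fano_and_correlations,
    normalized_counts,
    orientation_diff,
    passes_tuning_filter,
    spectra_and_coherence,
    tuning_and_oti,
    tuning_averaged_correlations,
    variability_timescales,
)


class TestFanoAndCorrelations:
    def test_identical_trials_flagged(self):
        counts = np.tile([[3, 5, 0]], (10, 1))
        st = fano_and_correlations(counts)
        assert st.fano[0] == 0.0 and st.fano[1] == 0.0
        assert np.isnan(st.fano[2])  # zero-mean unit flagged, not divided
        assert np.isnan(st.corr[0, 1])  # zero variance -> undefined

    def test_poisson_counts_fano_one(self, rng):
        counts = rng.poisson(3.0, size=(4000, 20))
        st = fano_and_correlations(counts)
        assert np.nanmean(st.fano) == pytest.approx(1.0, abs=0.05)
        off = st.corr[np.triu_indices(20, 1)]
        assert np.abs(off).mean() < 0.05

    def test_single_trial_rejected(self):
        with pytest.raises(ConfigurationError):
            fano_and_correlations(np.ones((1, 5)))

    def test_correlation_matches_numpy(self, rng):
        counts = rng.poisson(5.0, size=(200, 4)) + rng.poisson(2.0, size=(200, 1))
        st = fano_and_correlations(counts)
        assert np.allclose(st.corr, np.corrcoef(counts.T), atol=1e-10)


class TestNormalizedCounts:
    def test_constant_counts_become_one(self):
        norm, kept = normalized_counts(np.full((7, 3), 4.0))
        assert np.allclose(norm, 1.0) and len(kept) == 3

    def test_variance_equals_fano_identity(self, rng):
        counts = rng.poisson(rng.uniform(0.5, 8.0, size=12), size=(300, 12))
        st = fano_and_correlations(counts, min_mean=0.0)
        norm, kept = normalized_counts(counts)
        assert np.allclose(norm.var(axis=0, ddof=1),
                           st.fano[kept] * 1.0, rtol=1e-12)
        assert np.allclose(norm.mean(axis=0), 1.0)

    def test_zero_neuron_dropped(self):
        counts = np.array([[1, 0], [2, 0], [3, 0]])
        with pytest.warns(UserWarning, match="dropped"):
            norm, kept = normalized_counts(counts)
        assert list(kept) == [0]


class TestFactorAnalysis:
    def test_k0_all_private(self, rng):
        x = rng.standard_normal((100, 5))
        fm = factor_analysis(x, k=0)
        assert np.all(fm.shared == 0)
        assert np.allclose(fm.private, np.diag(np.cov(x.T)))

    def test_eigen_mode_exact_decomposition(self, rng):
        x = rng.standard_normal((200, 6)) @ rng.standard_normal((6, 6))
        fm = factor_analysis(x, k=2, mode="eigen")
        C = np.cov(x.T)
        assert np.allclose(fm.shared + np.diag(fm.private)
                           + (C - fm.shared - np.diag(fm.private)), C)
        # shared is the best rank-2 approximation: residual Frobenius norm
        # equals the tail eigenvalue energy
        evals = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.linalg.norm(C - fm.shared) == pytest.approx(
            np.sqrt((evals[2:] ** 2).sum()), rel=1e-8)

    @pytest.mark.parametrize("mode", ["eigen", "ml"])
    def test_rank1_recovery(self, mode, rng):
        """Rank-1 shared covariance + diagonal noise: shared variance is
        recovered within a few percent by both estimation routes."""
        n, N = 5000, 12
        u = rng.uniform(0.5, 1.5, N)
        g = rng.standard_normal((n, 1))
        x = g @ u[None, :] + 0.5 * rng.standard_normal((n, N))
        fm = factor_analysis(x, k=1, mode=mode)
        assert fm.shared_variance.mean() == pytest.approx((u**2).mean(), rel=0.05)


class TestSpectraCoherence:
    def test_identical_signals_full_coherence(self, rng):
        x = rng.standard_normal(4000)
        f, p, coh = spectra_and_coherence(x, x[:, None], fs=500.0)
        assert np.all(coh > 0.999)
        assert p.sum() == pytest.approx(1.0)

    def test_independent_noise_low_coherence(self, rng):
        x = rng.standard_normal(20000)
        y = rng.standard_normal((20000, 1))
        _, _, coh = spectra_and_coherence(x, y, fs=500.0)
        assert coh.mean() < 0.1

    def test_short_segment_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            spectra_and_coherence(rng.standard_normal(600), rng.standard_normal((600, 1)),
                                  fs=500.0, window_s=1.0)


class TestBumpFit:
    theta = np.linspace(0.0, 360.0, 50, endpoint=False)
    nl = Nonlinearity.powerlaw()

    def _bump(self, a, mu, sigma):
        th = np.deg2rad(self.theta)
        return self.nl.V0 + a * np.exp((np.cos(th - mu) - 1.0) / sigma**2)

    def test_exact_bump_recovered(self):
        """An input that IS a bump gives zero residual and exact (mu, sigma)."""
        mu, sigma = 0.7, 0.9
        V = self._bump(8.0, mu, sigma)[None, None, :]
        fit = bump_fit(V, self.theta, self.nl)
        assert fit.mu[0, 0] == pytest.approx(mu, abs=1e-6)
        assert fit.sigma[0, 0] == pytest.approx(sigma, abs=1e-6)
        assert fit.residual_var < 1e-12

    def test_jittered_series_recovery(self, rng):
        """Known jittered (mu_t, sigma_t) series plus small noise: both series
        recovered with correlation > 0.95."""
        T = 150
        mu_t = 0.3 * rng.standard_normal(T)
        sg_t = 1.0 + 0.15 * rng.standard_normal(T)
        V = np.stack([self._bump(8.0, m, s) for m, s in zip(mu_t, sg_t)])
        V = V + 0.2 * rng.standard_normal(V.shape)
        fit = bump_fit(V[None], self.theta, self.nl)
        assert np.corrcoef(fit.mu[0], mu_t)[0, 1] > 0.95
        assert np.corrcoef(fit.sigma[0], sg_t)[0, 1] > 0.95

    def test_fraction_rotation_invariant(self, rng):
        """Ring symmetry: rigidly rotating the stimulus (cyclic shift of all
        cells) leaves the captured-variance fraction unchanged."""
        T = 40
        mu_t = 0.2 * rng.standard_normal(T)
        V = np.stack([self._bump(8.0, m, 1.0) for m in mu_t])
        V = V + 0.3 * rng.standard_normal(V.shape)
        f1 = bump_fit(V[None], self.theta, self.nl).fraction
        f2 = bump_fit(np.roll(V, 13, axis=1)[None], self.theta, self.nl).fraction
        assert f1 == pytest.approx(f2, abs=1e-6)


@pytest.fixture(scope="module")
def templates():
    theta = np.linspace(0.0, 360.0, 50, endpoint=False)
    return covariance_templates(theta, Nonlinearity.powerlaw(), mu_bar=0.0,
                                sigma_bar=1.0, Rbar=400.0,
                                var_mu=0.05, var_sigma=0.02)


class TestCovarianceTemplates:

    def test_mu_template_signs(self, templates):
        """Sideways bump motion: cells on opposite sides of the stimulus are
        anti-correlated; the variance vanishes at the bump peak."""
        T_mu, _, _ = templates
        i_left, i_right = 45, 5  # -36 vs +36 degrees
        assert T_mu[i_left, i_right] < 0
        assert T_mu[5, 7] > 0  # same side
        assert abs(T_mu[0, 0]) < 1e-12 * np.abs(T_mu).max()

    def test_sigma_template_signs(self, templates):
        """Width fluctuations split cells into a peak group (activity drops
        as the bump widens, amplitude being conserved) and a flank group
        (activity rises): positive covariance within each group, negative
        between them."""
        _, T_sg, _ = templates
        peak, far_flank_l, far_flank_r = 0, 20, 30  # 0 vs 144/216 degrees
        assert T_sg[far_flank_l, far_flank_r] > 0   # flank-flank
        assert T_sg[peak, far_flank_l] < 0          # peak-flank
        assert T_sg[peak, peak] > 0


class TestTimescales:
    def test_exponential_half_time(self):
        """var(t) = plateau + (base-plateau) exp(-t/tau) crosses the half
        level at tau*ln2 after onset."""
        t = np.arange(0.0, 1000.0, 1.0)
        onset, tau = 300.0, 40.0
        var = np.where(t < onset, 2.0, 1.0 + np.exp(-(t - onset) / tau))
        res = variability_timescales(t, var, onset=onset,
                                     baseline_window=(0.0, onset),
                                     plateau_window=(800.0, 1000.0))
        assert res.suppression_half_time == pytest.approx(tau * np.log(2), abs=2.0)
        assert res.suppression_pct == pytest.approx(50.0, abs=1.0)

    def test_recovery_half_time(self):
        t = np.arange(0.0, 1500.0, 1.0)
        on, off, tau = 300.0, 800.0, 60.0
        var = np.full_like(t, 2.0)
        stim = (t >= on) & (t < off)
        var[stim] = 1.0 + np.exp(-(t[stim] - on) / 20.0)
        var[t >= off] = 2.0 - np.exp(-(t[t >= off] - off) / tau)
        res = variability_timescales(t, var, onset=on, offset=off,
                                     baseline_window=(0.0, on),
                                     plateau_window=(600.0, 800.0))
        assert res.recovery_half_time == pytest.approx(tau * np.log(2), abs=3.0)

    def test_flat_trajectory_rejected(self):
        t = np.arange(0.0, 500.0, 1.0)
        with pytest.raises(UndefinedTimescaleError):
            variability_timescales(t, np.ones_like(t), onset=200.0)


class TestTuning:
    def test_flat_tuning_zero_oti(self):
        ori = np.arange(0.0, 180.0, 22.5)
        fit = tuning_and_oti(ori, np.full(8, 5.0))
        assert fit.oti == pytest.approx(0.0, abs=1e-3)

    def test_zero_baseline_oti_closed_form(self):
        """f0 = 0: OTI reduces to (1 - e^-2k)/(1 + e^-2k)."""
        ori = np.arange(0.0, 180.0, 11.25)
        kappa = 1.3
        rates = 20.0 * np.exp(kappa * (np.cos(2 * np.deg2rad(ori - 40.0)) - 1.0))
        fit = tuning_and_oti(ori, rates)
        expected = (1 - np.exp(-2 * kappa)) / (1 + np.exp(-2 * kappa))
        assert fit.oti == pytest.approx(expected, abs=1e-3)
        assert fit.theta_pref == pytest.approx(40.0, abs=1.0)
        assert fit.kappa == pytest.approx(kappa, rel=0.05)

    def test_too_few_conditions(self):
        with pytest.raises(ConfigurationError):
            tuning_and_oti(np.array([0.0, 45.0, 90.0]), np.ones(3))

    def test_filter_predicate(self):
        ori = np.arange(0.0, 180.0, 22.5)
        sharp = tuning_and_oti(ori, 20.0 * np.exp(
            3.0 * (np.cos(2 * np.deg2rad(ori)) - 1.0)))
        broad = tuning_and_oti(ori, 5.0 + 2.0 * np.exp(
            0.5 * (np.cos(2 * np.deg2rad(ori)) - 1.0)))
        assert passes_tuning_filter(sharp, evoked_rate=5.0)
        assert not passes_tuning_filter(broad, evoked_rate=5.0)  # low OTI
        assert not passes_tuning_filter(sharp, evoked_rate=0.5)  # low rate


class TestTuningAveragedCorrelations:
    def test_uniform_matrix_gives_flat_curves(self):
        theta = np.linspace(0.0, 360.0, 40, endpoint=False)
        n = len(theta)
        corr = np.full((n, n), 0.3)
        np.fill_diagonal(corr, 1.0)
        st = fano_and_correlations(np.random.default_rng(0).poisson(5, (50, n)))
        st.corr = corr
        st.valid[:] = True
        centers, sim, orth = tuning_averaged_correlations(st, theta, 0.0)
        assert np.allclose(sim[np.isfinite(sim)], 0.3)
        assert np.allclose(orth[np.isfinite(orth)], 0.3)

    def test_orientation_diff(self):
        assert orientation_diff(0.0, 180.0) == pytest.approx(90.0)
        assert orientation_diff(0.0, 350.0) == pytest.approx(5.0)
        assert orientation_diff(10.0, 10.0) == 0.0
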