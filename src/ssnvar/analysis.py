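"""Variability statistics for simulated (or fixture) population activity.

Covers the full analysis chain used to characterise stimulus modulation of
neural variability: spike-count Fano factors and pairwise correlations,
tuning-resolved correlation curves, normalized-count factor analysis
(shared vs private variability), LFP power spectra and Vm-LFP coherence,
the circular-Gaussian bump decomposition of ring-network activity with its
covariance templates, variability suppression/recovery timescales, and
orientation tuning-curve fits with the orientation tuning index (OTI).

Conventions: ring unit angles ``theta`` live on the full 360-degree circle;
preferred orientations are ``theta/2`` on a 180-degree cycle.  Spike counts
are arrays of shape (trials, neurons) unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .core_dynamics import ConfigurationError, Nonlinearity

__all__ = [
    "VariabilityStats",
    "FactorModel",
    "BumpFit",
    "TimescaleResult",
    "TuningFit",
    "UndefinedTimescaleError",
    "fano_and_correlations",
    "tuning_averaged_correlations",
    "normalized_counts",
    "factor_analysis",
    "spectra_and_coherence",
    "bump_fit",
    "covariance_templates",
    "variability_timescales",
    "tuning_and_oti",
    "orientation_diff",
]


class UndefinedTimescaleError(RuntimeError):
    """No suppression (or recovery) is present in the variance trajectory."""


# ---------------------------------------------------------------------------
# Spike-count statistics
# ---------------------------------------------------------------------------

@dataclass
class VariabilityStats:
    """Per-neuron Fano factors and pairwise spike-count correlations."""

    fano: np.ndarray            # (neurons,), NaN where the mean count is ~0
    corr: np.ndarray            # (neurons, neurons), NaN rows for flagged units
    mean_count: np.ndarray      # (neurons,)
    valid: np.ndarray           # (neurons,) bool: mean count above threshold
    condition: dict = field(default_factory=dict)


def fano_and_correlations(counts: np.ndarray, min_mean: float = 0.01,
                          condition: dict | None = None) -> VariabilityStats:
    """Across-trial Fano factors and Pearson correlations of spike counts.

    ``fano_i = Var_i / Mean_i`` across trials.  Neurons whose mean count is
    below ``min_mean`` are flagged (NaN) rather than divided; they are
    excluded from population averages downstream.  Requires >= 2 trials.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ConfigurationError("counts must be (trials >= 2, neurons)")
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    valid = mean > min_mean
    fano = np.full(counts.shape[1], np.nan)
    fano[valid] = var[valid] / mean[valid]
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(var)
        ok = sd > 0
        z = np.where(ok, (counts - mean) / np.where(ok, sd, 1.0), np.nan)
        corr = (z.T @ z) / (counts.shape[0] - 1)
        corr[~ok, :] = np.nan
        corr[:, ~ok] = np.nan
    np.fill_diagonal(corr, np.where(ok, 1.0, np.nan))
    return VariabilityStats(fano=fano, corr=corr, mean_count=mean, valid=valid,
                            condition=condition or {})


def orientation_diff(theta_a, theta_b) -> np.ndarray:
    """Absolute preferred-orientation difference (deg, in [0, 90]).

    ``theta`` are ring angles on the full circle; orientations are
    ``theta/2`` with a 180-degree cycle, so the maximal orientation
    difference is 90 degrees.
    """
    d = np.mod(np.asarray(theta_a) / 2.0 - np.asarray(theta_b) / 2.0, 180.0)
    return np.minimum(d, 180.0 - d)


def tuning_averaged_correlations(stats: VariabilityStats, theta: np.ndarray,
                                 theta_stim: float, split: float = 45.0,
                                 bin_width: float = 15.0,
                                 symmetrize: bool = False):
    """Correlation vs stimulus orientation relative to pair-average PO.

    Pairs are classified as *similar* (|dPO| < split, in orientation
    degrees) or *orthogonal* (|dPO| > split).  For each pair, the x
    coordinate is the stimulus orientation relative to the circular mean of
    the pair's preferred orientations, in [-90, 90).  With ``symmetrize``
    the curves are averaged with their mirror image in x -- exact for the
    ring models, whose statistics are even in the stimulus-relative angle,
    and the standard treatment of the corresponding data curves; it halves
    the estimator noise of nearly flat curves.  Returns
    ``(bin_centers, similar_curve, orthogonal_curve)``; empty bins are NaN.
    """
    theta = np.asarray(theta, dtype=float)
    n = len(theta)
    iu, ju = np.triu_indices(n, k=1)
    c = stats.corr[iu, ju]
    ok = np.isfinite(c) & stats.valid[iu] & stats.valid[ju]
    dpo = orientation_diff(theta[iu], theta[ju])
    # circular mean of the two POs on the 180-degree cycle
    po_i, po_j = theta[iu] / 2.0, theta[ju] / 2.0
    mean_po = np.rad2deg(np.angle(
        np.exp(2j * np.deg2rad(po_i)) + np.exp(2j * np.deg2rad(po_j)))) / 2.0
    x = np.mod(theta_stim / 2.0 - mean_po + 90.0, 180.0) - 90.0
    edges = np.arange(-90.0, 90.0 + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    curves = {}
    for name, mask in (("similar", dpo < split), ("orthogonal", dpo > split)):
        m = mask & ok
        curve = np.full(len(centers), np.nan)
        idx = np.digitize(x[m], edges) - 1
        idx = np.clip(idx, 0, len(centers) - 1)
        for b in range(len(centers)):
            sel = idx == b
            if np.any(sel):
                curve[b] = c[m][sel].mean()
        if symmetrize:
            with np.errstate(invalid="ignore"):
                curve = np.nanmean(np.stack([curve, curve[::-1]]), axis=0)
        curves[name] = curve
    return centers, curves["similar"], curves["orthogonal"]


def normalized_counts(counts: np.ndarray):
    """Mean-normalize counts so each neuron's variance equals its Fano factor.

    Each neuron's counts are rescaled relative to its trial mean m_i,
    ``c~_ik = 1 + (c_ik - m_i)/sqrt(m_i)``, so the per-neuron trial mean of
    the output is 1 and its variance is exactly Var_i/m_i, the Fano factor.
    This keeps tuning-driven mean-rate structure (the "Poisson part", which
    scales with the mean count) out of the normalized covariance, whose
    entries become C_ij/sqrt(m_i m_j).  All-zero neurons are dropped;
    returns ``(normalized, kept_index)``.
    """
    counts = np.asarray(counts, dtype=float)
    mean = counts.mean(axis=0)
    kept = np.flatnonzero(mean > 0)
    if len(kept) < counts.shape[1]:
        warnings.warn(f"dropped {counts.shape[1] - len(kept)} all-zero neurons")
    m = mean[kept]
    return 1.0 + (counts[:, kept] - m) / np.sqrt(m), kept


# ---------------------------------------------------------------------------
# Factor analysis of normalized counts
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    """Rank-k shared + diagonal private decomposition of a covariance."""

    k: int
    mode: str
    shared: np.ndarray    # (N, N), PSD of rank <= k
    private: np.ndarray   # (N,) diagonal
    total: np.ndarray     # (N, N) covariance that was decomposed

    @property
    def shared_variance(self) -> np.ndarray:
        """Per-neuron shared variance (diagonal of the shared covariance)."""
        return np.diag(self.shared).copy()


def factor_analysis(normalized: np.ndarray, k: int,
                    mode: str = "eigen", ridge: float = 1e-6,
                    max_iter: int = 1000) -> FactorModel:
    """Decompose the normalized-count covariance into shared + private parts.

    ``eigen`` mode (used for model data, where the covariance is estimated
    near-perfectly) takes the top-k eigenmodes of the covariance as the
    shared part; shared + private then equals the total covariance exactly
    and the shared part is the best rank-k approximation in Frobenius norm.
    ``ml`` mode runs maximum-likelihood factor analysis (EM, as used for
    real data); a small ridge stabilises the covariance.
    """
    X = np.asarray(normalized, dtype=float)
    C = np.cov(X.T)
    if k < 0:
        raise ConfigurationError("k must be >= 0")
    if k == 0:
        return FactorModel(k=0, mode=mode, shared=np.zeros_like(C),
                           private=np.diag(C).copy(), total=C)
    if mode == "eigen":
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:k]
        shared = (evecs[:, order] * evals[order]) @ evecs[:, order].T
        private = np.diag(C - shared).copy()
        return FactorModel(k=k, mode=mode, shared=shared, private=private, total=C)
    if mode == "ml":
        from sklearn.decomposition import FactorAnalysis
        fa = FactorAnalysis(n_components=k, max_iter=max_iter, tol=1e-6)
        Xr = X + ridge * np.random.default_rng(0).standard_normal(X.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            fa.fit(Xr)
        if fa.n_iter_ >= max_iter:
            warnings.warn("factor-analysis EM did not converge; best iterate kept")
        shared = fa.components_.T @ fa.components_
        return FactorModel(k=k, mode=mode, shared=shared,
                           private=fa.noise_variance_.copy(), total=C)
    raise ConfigurationError(f"unknown factor-analysis mode {mode!r}")


# ---------------------------------------------------------------------------
# Spectra and coherence
# ---------------------------------------------------------------------------

def spectra_and_coherence(lfp: np.ndarray, vm: np.ndarray, fs: float,
                          window_s: float = 1.0, overlap: float = 0.5,
                          normalize_lfp: bool = True):
    """Welch LFP power spectrum and average single-cell Vm-LFP coherence.

    ``lfp``: (T,) population signal; ``vm``: (T, cells).  Hann windows of
    ``window_s`` seconds with fractional ``overlap``; power normalized to
    unit total (per condition) when ``normalize_lfp``.  Returns
    ``(freqs, lfp_power, coherence)`` with coherence averaged across cells.
    """
    lfp = np.asarray(lfp, dtype=float)
    vm = np.atleast_2d(np.asarray(vm, dtype=float))
    if vm.shape[0] == lfp.shape[0]:
        vm = vm.T
    nperseg = int(round(window_s * fs))
    if lfp.shape[0] < 2 * nperseg:
        raise ConfigurationError("segment shorter than two Welch windows")
    noverlap = int(round(overlap * nperseg))
    f, p = signal.welch(lfp, fs=fs, nperseg=nperseg, noverlap=noverlap,
                        window="hann", detrend="constant")
    if normalize_lfp:
        p = p / p.sum()
    coh = np.zeros_like(p)
    for cell in vm:
        _, cxy = signal.coherence(cell, lfp, fs=fs, nperseg=nperseg,
                                  noverlap=noverlap, window="hann",
                                  detrend="constant")
        coh += cxy
    coh /= vm.shape[0]
    return f, p, coh


# ---------------------------------------------------------------------------
# Bump kinetics
# ---------------------------------------------------------------------------

@dataclass
class BumpFit:
    """Per-time-step circular-Gaussian fit of the ring activity bump.

    The bump ``V_i - V0 = a exp[(cos(theta_i - mu) - 1)/sigma^2]`` is fitted
    over the excitatory population at each stored time step with location
    ``mu`` and width ``sigma`` free and the amplitude ``a`` constrained so
    the total population firing rate equals ``Rbar``.
    """

    a: np.ndarray       # (trials, T)
    mu: np.ndarray      # (trials, T), radians
    sigma: np.ndarray   # (trials, T), radians
    Rbar: float
    fraction: float             # pooled cells x time x trials
    fraction_per_trial: float   # variance pooled within trial, then averaged
    residual_var: float
    failed: np.ndarray  # (trials, T) bool: amplitude constraint unsolvable


def _bump_profile(theta: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp((np.cos(theta - mu) - 1.0) / sigma**2)


def _constrained_amplitude(g: np.ndarray, Rbar: float, nl: Nonlinearity) -> float:
    """Amplitude solving sum_i r(V0 + a g_i) = Rbar (monotone in a > 0)."""
    if nl.kind == "powerlaw":
        return (Rbar / (nl.k * (g ** nl.n).sum())) ** (1.0 / nl.n)

    def total_rate(a):
        return nl.rate(nl.V0 + a * g).sum() - Rbar

    hi = 1.0
    while total_rate(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("amplitude root find failed")
    return optimize.brentq(total_rate, 0.0, hi)


def bump_fit(V: np.ndarray, theta: np.ndarray, nonlinearity: Nonlinearity,
             Rbar: float | None = None) -> BumpFit:
    """Fit the constrained circular-Gaussian bump to every stored time step.

    ``V``: voltages (trials, T, N_E) or (T, N_E) over the excitatory ring;
    ``theta``: angles in degrees.  ``Rbar`` defaults to the time- and
    trial-mean total population rate.  The captured-variance fraction is
    ``1 - Var(residual) / Var(V)`` with the variance pooled over cells and
    time (and trials), i.e. around the grand mean, so it accounts for both
    the mean bump shape and its fluctuations.  Fluctuations of (mu, sigma)
    around their means describe the two principal modes of bump kinetics.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim == 2:
        V = V[None]
    n_trials, T, N = V.shape
    th = np.deg2rad(np.asarray(theta, dtype=float))
    nl = nonlinearity
    V0 = nl.V0 if nl.kind == "powerlaw" else 0.0
    x = V - V0
    if Rbar is None:
        Rbar = float(nl.rate(V).sum(axis=-1).mean())

    def residual_fn(p, xi):
        g = _bump_profile(th, p[0], abs(p[1]))
        a = _constrained_amplitude(g, Rbar, nl)
        return a * g - xi

    a_out = np.empty((n_trials, T))
    mu_out = np.empty((n_trials, T))
    sig_out = np.empty((n_trials, T))
    failed = np.zeros((n_trials, T), dtype=bool)
    resid = np.empty_like(x)
    # initialisation: circular center of mass and spread of the first frame
    for tr in range(n_trials):
        w = np.maximum(x[tr, 0], 0.0)
        z = (w * np.exp(1j * th)).sum() / max(w.sum(), 1e-12)
        p = np.array([np.angle(z), max(np.sqrt(max(-2 * np.log(max(abs(z), 1e-6)), 1e-4)), 0.3)])
        for t in range(T):
            try:
                sol = optimize.least_squares(residual_fn, p, args=(x[tr, t],),
                                             method="lm", xtol=1e-10)
                p = np.array([np.mod(sol.x[0] + np.pi, 2 * np.pi) - np.pi,
                              abs(sol.x[1])])
                resid[tr, t] = sol.fun
            except RuntimeError:
                failed[tr, t] = True
                resid[tr, t] = np.nan
            mu_out[tr, t], sig_out[tr, t] = p
            g = _bump_profile(th, p[0], p[1])
            a_out[tr, t] = _constrained_amplitude(g, Rbar, nl) if not failed[tr, t] else np.nan

    ok = ~failed
    res_flat = resid[ok]
    x_flat = x[ok]
    frac = 1.0 - (res_flat ** 2).mean() / x_flat.var()
    per_trial = []
    for tr in range(n_trials):
        m = ok[tr]
        if m.any():
            per_trial.append(1.0 - (resid[tr][m] ** 2).mean() / x[tr][m].var())
    return BumpFit(a=a_out, mu=mu_out, sigma=sig_out, Rbar=Rbar,
                   fraction=float(frac),
                   fraction_per_trial=float(np.mean(per_trial)),
                   residual_var=float((res_flat ** 2).mean()),
                   failed=failed)


def covariance_templates(theta: np.ndarray, nonlinearity: Nonlinearity,
                         mu_bar: float, sigma_bar: float, Rbar: float,
                         var_mu: float, var_sigma: float,
                         cov_mu_sigma: float = 0.0,
                         eps: float = 1e-5):
    """Covariance templates of the two bump-kinetics modes.

    The differential activity patterns d(bump)/d(mu) and d(bump)/d(sigma)
    (the latter including the amplitude change induced by the constant-rate
    constraint) are evaluated at the mean bump ``(mu_bar, sigma_bar)`` by
    central differences; the templates are their outer products scaled by
    the measured variances of the fitted series,

        T_mu = Var(mu) p_mu p_mu^T,   T_sigma = Var(sigma) p_s p_s^T,

    plus a cross term 2 Cov(mu, sigma) sym(p_mu p_s^T) in the total.
    Returns ``(T_mu, T_sigma, total)``.
    """
    th = np.deg2rad(np.asarray(theta, dtype=float))
    nl = nonlinearity
    V0 = nl.V0 if nl.kind == "powerlaw" else 0.0

    def bump(mu, sig):
        g = _bump_profile(th, mu, sig)
        return V0 + _constrained_amplitude(g, Rbar, nl) * g

    p_mu = (bump(mu_bar + eps, sigma_bar) - bump(mu_bar - eps, sigma_bar)) / (2 * eps)
    p_sg = (bump(mu_bar, sigma_bar + eps) - bump(mu_bar, sigma_bar - eps)) / (2 * eps)
    T_mu = var_mu * np.outer(p_mu, p_mu)
    T_sg = var_sigma * np.outer(p_sg, p_sg)
    cross = cov_mu_sigma * (np.outer(p_mu, p_sg) + np.outer(p_sg, p_mu))
    return T_mu, T_sg, T_mu + T_sg + cross


# ---------------------------------------------------------------------------
# Timescales of variability modulation
# ---------------------------------------------------------------------------

@dataclass
class TimescaleResult:
    """Suppression/recovery half-times of an across-trial variance trajectory."""

    times: np.ndarray
    var: np.ndarray
    baseline: float
    plateau: float
    suppression_pct: float
    suppression_half_time: float   # ms, latency discarded
    recovery_half_time: float | None  # ms, None if no offset given
    onset_latency: float
    offset_latency: float | None


def _half_crossing(times, var, start, target, direction):
    after = times >= start
    crossed = (var <= target) if direction == "down" else (var >= target)
    hit = after & crossed
    if not np.any(hit):
        raise UndefinedTimescaleError("variance never crosses the half level")
    return times[hit][0]


def _latency(times, var, start, t_cross, band_lo, band_hi):
    m = (times >= start) & (times <= t_cross) & (var >= band_lo) & (var <= band_hi)
    return times[m][-1] if np.any(m) else start


def variability_timescales(times: np.ndarray, var: np.ndarray,
                           onset: float, offset: float | None = None,
                           baseline_window: tuple[float, float] | None = None,
                           plateau_window: tuple[float, float] | None = None,
                           band_sd: float = 2.0) -> TimescaleResult:
    """Half-times of variance suppression (after onset) and recovery (after offset).

    The suppression half-time is the first crossing of
    ``(baseline + plateau)/2`` after stimulus onset, minus the onset latency
    -- the last time the trajectory is still inside the baseline noise band
    (mean +/- ``band_sd`` standard deviations of the baseline samples).
    Recovery is defined analogously after offset, relative to the plateau
    band.  ``suppression_pct = 100 (baseline - plateau)/baseline``.  Raises
    :class:`UndefinedTimescaleError` when baseline equals plateau or the
    half level is never crossed.
    """
    times = np.asarray(times, dtype=float)
    var = np.asarray(var, dtype=float)
    if baseline_window is None:
        baseline_window = (times[0], onset)
    if plateau_window is None:
        end = offset if offset is not None else times[-1]
        plateau_window = (max(onset, end - 0.4 * (end - onset)), end)
    b = (times >= baseline_window[0]) & (times < baseline_window[1])
    p = (times >= plateau_window[0]) & (times < plateau_window[1])
    base, base_sd = var[b].mean(), var[b].std()
    plat, plat_sd = var[p].mean(), var[p].std()
    if not plat < base - band_sd * base_sd / max(np.sqrt(b.sum()), 1.0):
        raise UndefinedTimescaleError(
            f"no suppression: baseline {base:.4g} vs plateau {plat:.4g}")
    half = 0.5 * (base + plat)
    t_cross = _half_crossing(times, var, onset, half, "down")
    lat_on = _latency(times, var, onset, t_cross,
                      base - band_sd * base_sd, base + band_sd * base_sd)
    supp_half = t_cross - lat_on

    rec_half = lat_off = None
    if offset is not None:
        t_rec = _half_crossing(times, var, offset, half, "up")
        lat_off = _latency(times, var, offset, t_rec,
                           plat - band_sd * plat_sd, plat + band_sd * plat_sd)
        rec_half = t_rec - lat_off
        lat_off = lat_off - offset
    return TimescaleResult(times=times, var=var, baseline=float(base),
                           plateau=float(plat),
                           suppression_pct=float(100.0 * (base - plat) / base),
                           suppression_half_time=float(supp_half),
                           recovery_half_time=None if rec_half is None else float(rec_half),
                           onset_latency=float(lat_on - onset),
                           offset_latency=lat_off)


# ---------------------------------------------------------------------------
# Orientation tuning
# ---------------------------------------------------------------------------

@dataclass
class TuningFit:
    """Circular-Gaussian orientation tuning curve and tuning index."""

    f0: float
    fm: float
    kappa: float
    theta_pref: float  # deg, orientation in [0, 180)
    oti: float
    converged: bool

    def predict(self, theta_deg: np.ndarray) -> np.ndarray:
        d = np.deg2rad(np.asarray(theta_deg) - self.theta_pref)
        return self.f0 + self.fm * np.exp(self.kappa * (np.cos(2 * d) - 1.0))


def tuning_and_oti(orientations: np.ndarray, rates: np.ndarray) -> TuningFit:
    """Fit f(theta) = f0 + fm exp[kappa (cos 2(theta - theta_pref) - 1)].

    ``orientations`` in degrees (>= 4 distinct conditions), ``rates`` the
    mean evoked rate per condition.  The OTI is computed from the fitted
    curve at the preferred and orthogonal orientations:
    OTI = (f(pref) - f(orth)) / (f(pref) + f(orth)).
    """
    ori = np.asarray(orientations, dtype=float)
    y = np.asarray(rates, dtype=float)
    if len(np.unique(np.mod(ori, 180.0))) < 4:
        raise ConfigurationError("need >= 4 orientation conditions")

    def f(th, f0, fm, kappa, pref):
        return f0 + fm * np.exp(kappa * (np.cos(2 * np.deg2rad(th - pref)) - 1.0))

    pref0 = ori[np.argmax(y)]
    p0 = [max(y.min(), 1e-3), max(y.max() - y.min(), 1e-3), 1.0, pref0]
    try:
        popt, _ = optimize.curve_fit(
            f, ori, y, p0=p0,
            bounds=([0, 0, 1e-3, pref0 - 90.0], [np.inf, np.inf, 50.0, pref0 + 90.0]),
            maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    f0, fm, kappa, pref = popt
    fp = f0 + fm
    fo = f0 + fm * np.exp(-2.0 * kappa)
    oti = (fp - fo) / (fp + fo) if fp + fo > 0 else 0.0
    return TuningFit(f0=float(f0), fm=float(fm), kappa=float(kappa),
                     theta_pref=float(np.mod(pref, 180.0)), oti=float(oti),
                     converged=converged)


def passes_tuning_filter(fit: TuningFit, evoked_rate: float,
                         min_oti: float = 0.75, min_rate: float = 1.0) -> bool:
    """Unit-inclusion predicate: OTI >= 0.75 and mean evoked rate >= 1 s^-1."""
    return fit.converged and fit.oti >= min_oti and evoked_rate >= min_rate
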