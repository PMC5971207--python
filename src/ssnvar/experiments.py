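"""Config-driven, desk-scale experiment drivers and fixture generation.

Each driver runs one of the package's standard figure-level experiments at sizes
chosen to complete on a single CPU in minutes: the input-sweep of
population variability in the reduced SSN (``fig2d``), the spiking-network
LFP spectra and coherence (``fig3``), tuning-resolved Fano factors and
factor analysis on the ring (``fig4``), bump-kinetics decomposition
(``fig5``), correlation tuning in the ring SSN versus the multi-attractor
network (``fig6``), and the timescales of variability suppression and
recovery across the three dynamical regimes (``fig7``).

Outputs are tidy CSV files plus a provenance JSON (config, hash, seeds,
package version); re-running a config reproduces all outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_dynamics import (
    ConfigurationError,
    NetworkSpec,
    StimulusProtocol,
    fixed_point,
    jacobian,
    linearized_covariance,
    simulate,
)
from .architectures import (
    ChaoticParams,
    MultiAttractorParams,
    RingGeometry,
    RingInputParams,
    TwoPopParams,
    build_chaotic,
    build_multiattractor,
    build_ring,
    build_two_pop,
    chaotic_input,
    multiattractor_input,
    ring_input,
)
from .spiking_sim import SpikingNetSpec, lfp_proxy, poisson_counts, simulate_spiking
from .analysis import (
    bump_fit,
    factor_analysis,
    fano_and_correlations,
    normalized_counts,
    spectra_and_coherence,
    tuning_averaged_correlations,
    variability_timescales,
)
from .io import config_hash, dump_yaml, ensure_dir, load_yaml

__all__ = [
    "ExperimentConfig",
    "FixtureSpec",
    "run_experiment",
    "generate_fixture",
    "parameter_sweep",
    "DRIVERS",
]


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment run."""

    name: str
    seed: int = 0
    dt: float = 0.1
    n_trials: int | None = None
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls(**load_yaml(path))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def _write(outdir: Path, tables: dict[str, pd.DataFrame], config: ExperimentConfig):
    outdir = ensure_dir(outdir)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
    prov = {"config": config.to_dict(), "config_hash": config.hash,
            "package_version": __version__}
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2,
                                                       sort_keys=True))
    dump_yaml(config.to_dict(), outdir / "config.yaml")


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def _fano_from_integrals(lam: np.ndarray, seed: int, min_mean: float = 0.01):
    """Population Fano from (trials, bins, neurons) expected-count integrals.

    Counts are drawn once per bin; Fano is computed across trials per
    (bin, neuron) and averaged over bins.
    """
    counts = poisson_counts(lam, seed=seed)
    fanos = []
    for b in range(counts.shape[1]):
        st = fano_and_correlations(counts[:, b, :], min_mean=min_mean)
        fanos.append(st.fano)
    return np.nanmean(np.stack(fanos), axis=0), counts


def drive_fig2d(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Input sweep of the reduced SSN: mean rates/Vm and Vm std vs h.

    Monte-Carlo statistics over ``n_trials`` (default 500) trials of 2.5 s
    alongside the linearized (Lyapunov) prediction, plus the feedforward
    (W = 0) control.
    """
    p = TwoPopParams(**cfg.params.get("two_pop", {}))
    net, noise = build_two_pop(p)
    net0 = NetworkSpec(N_E=1, N_I=1, W=np.zeros((2, 2)), tau=net.tau,
                       Vrest=net.Vrest, nonlinearity=net.nonlinearity)
    n_trials = cfg.n_trials or 500
    hs = np.asarray(cfg.params.get("h_grid", np.arange(0.0, 21.0, 1.0)), float)
    rows = []
    for i, h in enumerate(hs):
        proto = StimulusProtocol.constant(h, 2500.0)
        out = simulate(net, proto, noise, dt=cfg.dt, seed=cfg.seed + i,
                       n_trials=n_trials, record_dt=1.0, init="fixed_point")
        V = out.V[:, 500:, :].reshape(-1, 2)
        out0 = simulate(net0, proto, noise, dt=cfg.dt, seed=cfg.seed + i,
                        n_trials=max(n_trials // 5, 20), record_dt=1.0,
                        init="fixed_point")
        V0 = out0.V[:, 500:, :].reshape(-1, 2)
        lin = np.sqrt(np.diag(linearized_covariance(net, noise, h)))
        r = net.rate(V).mean(axis=0)
        rows.append(dict(h=h, rate_E=r[0], rate_I=r[1],
                         mean_VE=V[:, 0].mean(), mean_VI=V[:, 1].mean(),
                         std_VE=V[:, 0].std(), std_VI=V[:, 1].std(),
                         std_VE_ff=V0[:, 0].std(), std_VI_ff=V0[:, 1].std(),
                         lin_std_VE=lin[0], lin_std_VI=lin[1]))
    return {"fig2d_sweep": pd.DataFrame(rows)}


def drive_fig3(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Spiking SSN: LFP power and Vm-LFP coherence, spontaneous vs evoked.

    Desk-scale default: quarter-scale network (1000 E / 250 I), one long
    trial per condition (h = 2 and 15 mV).
    """
    preset = cfg.params.get("scale", "quarter")
    spec = (SpikingNetSpec.quarter_scale() if preset == "quarter"
            else SpikingNetSpec())
    dur = float(cfg.params.get("duration_ms", 6000.0))
    n_cells = int(cfg.params.get("n_coherence_cells", 20))
    fs = 1000.0 / 2.0  # 2 ms Vm record
    tables = {}
    rows_rate = []
    for label, h in (("spontaneous", 2.0), ("evoked", 15.0)):
        spk, traj = simulate_spiking(spec, StimulusProtocol.constant(h, dur),
                                     dt=cfg.dt, seed=cfg.seed, n_trials=1,
                                     record_dt=2.0, connectivity_seed=cfg.seed)
        V = traj.V[0][traj.times > 500.0]
        lfp = lfp_proxy(V)
        cells = V[:, :n_cells]  # E cells for single-cell pairing
        f, pw, coh = spectra_and_coherence(lfp, cells, fs=fs)
        tables[f"fig3_spectra_{label}"] = pd.DataFrame(
            dict(freq_hz=f, lfp_power=pw, vm_lfp_coherence=coh))
        ids, ts = spk.events[0]
        m = ts > 500.0
        rows_rate.append(dict(
            condition=label, h=h,
            rate_E=(ids[m] < spec.N_E).sum() / ((dur - 500) / 1000) / spec.N_E,
            rate_I=(ids[m] >= spec.N_E).sum() / ((dur - 500) / 1000) / spec.N_I,
            lfp_var=lfp.var()))
    tables["fig3_rates"] = pd.DataFrame(rows_rate)
    return tables


def _ring_evoked_protocol(geo, c, pre, stim, post, theta_stim=0.0, A_max=20.0,
                          b=2.0):
    h0 = ring_input(RingInputParams(b=b, A_max=A_max, c=0.0), geo)
    h1 = ring_input(RingInputParams(b=b, A_max=A_max, c=c,
                                    theta_stim=theta_stim), geo)
    return StimulusProtocol.step(h0, h1, h0, pre, stim, post)


def drive_fig4(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Ring SSN: Fano-factor drop at stimulus onset, tuning of rates/Fano/Vm
    variance, and shared variability (factor analysis, k = 3)."""
    geo = RingGeometry(**cfg.params.get("geometry", {}))
    net, noise = build_ring(geo)
    n_trials = cfg.n_trials or 500
    contrasts = cfg.params.get("contrasts", [0.0, 0.5, 1.0])
    k_fa = int(cfg.params.get("k_factors", 3))
    pre, stim = 600.0, 600.0
    h0 = ring_input(RingInputParams(c=0.0), geo)
    rows_t, rows_po, rows_fa = [], [], []
    counts_by_c = {}
    for ci, c in enumerate(contrasts):
        h1 = ring_input(RingInputParams(c=c), geo)
        proto = StimulusProtocol.step(h0, h1, h0, pre, stim, 1.0)
        out = simulate(net, proto, noise, dt=cfg.dt, seed=cfg.seed + ci,
                       n_trials=n_trials, record_dt=5.0, count_bin=25.0,
                       count_start=100.0, init="fixed_point")
        lam25 = out.rate_integral  # 25 ms sub-bins -> sliding 100 ms windows
        n_win = lam25.shape[1] - 3
        lam100 = np.stack([lam25[:, i:i + 4].sum(axis=1) for i in range(n_win)], 1)
        counts = poisson_counts(lam100, seed=cfg.seed + 91 + ci)
        counts_by_c[c] = counts
        centers = out.bin_times[:n_win] + 37.5
        for w in range(n_win):
            st = fano_and_correlations(counts[:, w, :])
            rows_t.append(dict(c=c, t_ms=centers[w] - pre,
                               fano=np.nanmean(st.fano[net.e_mask])))
        # steady-state (last 300 ms of stimulus) tuning profiles
        sel = (centers > pre + 250.0) & (centers < pre + stim)
        Vs = out.V[:, (out.times > pre + 250.0) & (out.times < pre + stim), :]
        fano_ss = np.nanmean(np.stack(
            [fano_and_correlations(counts[:, w, :]).fano
             for w in np.flatnonzero(sel)]), axis=0)
        rate_ss = lam100[:, sel, :].mean(axis=(0, 1)) * 10.0
        for i in np.flatnonzero(net.e_mask):
            rows_po.append(dict(c=c, theta=net.theta[i], po=net.theta[i] / 2.0,
                                rate=rate_ss[i], fano=fano_ss[i],
                                vm_std=Vs[:, :, i].std()))
        # factor analysis on steady-state window counts
        w0 = np.flatnonzero(sel)[0]
        norm, kept = normalized_counts(counts[:, w0, :][:, net.e_mask])
        fm = factor_analysis(norm, k=k_fa, mode="eigen")
        rows_fa.append(dict(c=c, k=k_fa,
                            shared_var=float(fm.shared_variance.mean()),
                            private_var=float(fm.private.mean())))
    return {"fig4_fano_time": pd.DataFrame(rows_t),
            "fig4_tuning": pd.DataFrame(rows_po),
            "fig4_factor": pd.DataFrame(rows_fa)}


def drive_fig5(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Ring SSN bump kinetics: constrained circular-Gaussian fit and the
    location/width covariance templates."""
    geo = RingGeometry(**cfg.params.get("geometry", {}))
    net, noise = build_ring(geo)
    n_trials = cfg.n_trials or 100
    h1 = ring_input(RingInputParams(c=1.0), geo)
    out = simulate(net, StimulusProtocol.constant(h1, 1300.0), noise,
                   dt=cfg.dt, seed=cfg.seed, n_trials=n_trials, record_dt=5.0,
                   init="fixed_point")
    VE = out.V[:, out.times > 300.0, : geo.N_E]
    fit = bump_fit(VE, net.theta[: geo.N_E], net.nonlinearity)
    from .analysis import covariance_templates
    T_mu, T_sg, T_tot = covariance_templates(
        net.theta[: geo.N_E], net.nonlinearity,
        mu_bar=float(np.angle(np.exp(1j * fit.mu).mean())),
        sigma_bar=float(fit.sigma.mean()), Rbar=fit.Rbar,
        var_mu=float(fit.mu.var()), var_sigma=float(fit.sigma.var()),
        cov_mu_sigma=float(np.cov(fit.mu.ravel(), fit.sigma.ravel())[0, 1]))
    C_full = np.cov(VE.reshape(-1, geo.N_E).T)
    series = pd.DataFrame(dict(
        trial=np.repeat(np.arange(n_trials), fit.mu.shape[1]),
        t_ms=np.tile(out.times[out.times > 300.0], n_trials),
        a=fit.a.ravel(), mu_rad=fit.mu.ravel(), sigma_rad=fit.sigma.ravel()))
    summary = pd.DataFrame([dict(
        fraction=fit.fraction, fraction_per_trial=fit.fraction_per_trial,
        Rbar=fit.Rbar, var_mu=fit.mu.var(), var_sigma=fit.sigma.var(),
        corr_mu_sigma=np.corrcoef(fit.mu.ravel(), fit.sigma.ravel())[0, 1])])
    po = net.theta[: geo.N_E] / 2.0
    ii, jj = np.meshgrid(np.arange(geo.N_E), np.arange(geo.N_E), indexing="ij")
    cov = pd.DataFrame(dict(po_i=po[ii.ravel()], po_j=po[jj.ravel()],
                            T_mu=T_mu.ravel(), T_sigma=T_sg.ravel(),
                            T_total=T_tot.ravel(), C_full=C_full.ravel()))
    return {"fig5_summary": summary, "fig5_series": series,
            "fig5_covariances": cov}


def _mean_stats_over_bins(counts: np.ndarray):
    """Average across-trial correlation/Fano estimates over counting bins.

    ``counts`` is (trials, bins, neurons); each bin gives an independent
    across-trial estimate of the same stationary statistics.
    """
    import warnings as _w
    per_bin = [fano_and_correlations(counts[:, b, :])
               for b in range(counts.shape[1])]
    st = per_bin[0]
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        st.corr = np.nanmean(np.stack([s.corr for s in per_bin]), axis=0)
        st.fano = np.nanmean(np.stack([s.fano for s in per_bin]), axis=0)
    st.valid = np.all(np.stack([s.valid for s in per_bin]), axis=0)
    return st


def drive_fig6(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Evoked spike-count correlations vs tuning: ring SSN vs multi-attractor."""
    n_trials = cfg.n_trials or 500
    bin_ms = 100.0
    rows = []
    mats = {}
    # ring SSN, 100% contrast
    geo = RingGeometry(**cfg.params.get("geometry", {}))
    net, noise = build_ring(geo)
    h1 = ring_input(RingInputParams(c=1.0), geo)
    out = simulate(net, StimulusProtocol.constant(h1, 4300.0), noise,
                   dt=cfg.dt, seed=cfg.seed, n_trials=n_trials,
                   count_bin=bin_ms, count_start=300.0, init="fixed_point")
    counts = poisson_counts(out.rate_integral, seed=cfg.seed + 7)
    mats["ssn"] = (_mean_stats_over_bins(counts[:, :, net.e_mask]),
                   net.theta[net.e_mask])
    # multi-attractor, c = 1
    mp = MultiAttractorParams(**cfg.params.get("multiattractor", {}))
    mnet, mnoise = build_multiattractor(mp)
    h = multiattractor_input(mp, 1.0)
    mout = simulate(mnet, StimulusProtocol.constant(h, 2600.0), mnoise,
                    dt=cfg.dt, seed=cfg.seed + 1, n_trials=n_trials,
                    count_bin=bin_ms, count_start=1800.0, init="rest")
    mcounts = poisson_counts(mout.rate_integral, seed=cfg.seed + 8)
    mats["multiattractor"] = (_mean_stats_over_bins(mcounts), mnet.theta)
    for model, (st, theta) in mats.items():
        centers, sim, orth = tuning_averaged_correlations(st, theta, 0.0,
                                                          symmetrize=True)
        for x, s, o in zip(centers, sim, orth):
            rows.append(dict(model=model, stim_rel_po=x,
                             corr_similar=s, corr_orthogonal=o))
    return {"fig6_corr_tuning": pd.DataFrame(rows)}


def drive_fig7(cfg: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Across-trial variance trajectories and suppression/recovery half-times
    for the ring SSN, chaotic and multi-attractor regimes.

    Stimulus amplitudes default to values spanning roughly 20-90% variance
    suppression in each model (the multi-attractor stimulus is twice as
    long, so suppression is reached after its characteristic transient
    variance increase).
    """
    n_trials = cfg.n_trials or 200
    rows_var, rows_ts = [], []

    def add(model, amp, res):
        rows_ts.append(dict(model=model, amplitude=amp,
                            baseline=res.baseline, plateau=res.plateau,
                            suppression_pct=res.suppression_pct,
                            t_half_suppress_ms=res.suppression_half_time,
                            t_half_recover_ms=res.recovery_half_time))
        for t, v in zip(res.times, res.var):
            rows_var.append(dict(model=model, amplitude=amp, t_ms=t, var=v))

    # ring SSN
    geo = RingGeometry()
    net, noise = build_ring(geo)
    for c in cfg.params.get("ssn_contrasts", [0.33, 0.66, 1.0]):
        proto = _ring_evoked_protocol(geo, c, 400.0, 500.0, 600.0)
        out = simulate(net, proto, noise, dt=cfg.dt, seed=cfg.seed,
                       n_trials=n_trials, record_dt=2.0, trial_stats=True,
                       init="fixed_point")
        var = out.trial_var[:, net.e_mask].mean(axis=1)
        res = variability_timescales(out.times, var, onset=400.0, offset=900.0,
                                     baseline_window=(100.0, 400.0),
                                     plateau_window=(650.0, 900.0))
        add("ssn", c, res)
    # chaotic network
    cp = ChaoticParams(**cfg.params.get("chaotic", {}))
    cnet, phi = build_chaotic(cp, seed=cfg.seed)
    for c in cfg.params.get("chaotic_amplitudes", [0.6, 0.8, 1.0, 1.25]):
        proto = StimulusProtocol.step(0.0, chaotic_input(phi, c), 0.0,
                                      400.0, 500.0, 1100.0)
        out = simulate(cnet, proto, None, dt=1.0, seed=cfg.seed + 3,
                       n_trials=n_trials, record_dt=5.0, trial_stats=True,
                       init="random", init_scale=1.0, dtype=np.float32)
        var = out.trial_var.mean(axis=1)
        res = variability_timescales(out.times, var, onset=400.0, offset=900.0,
                                     baseline_window=(150.0, 400.0),
                                     plateau_window=(650.0, 900.0))
        add("chaotic", c, res)
    # multi-attractor (stimulus twice as long)
    mp = MultiAttractorParams(**cfg.params.get("multiattractor", {}))
    mnet, mnoise = build_multiattractor(mp)
    h0 = multiattractor_input(mp, 0.0)
    for c in cfg.params.get("multiattractor_amplitudes", [1.0, 2.0]):
        h1 = multiattractor_input(mp, c)
        proto = StimulusProtocol.step(h0, h1, h0, 1500.0, 1000.0, 800.0)
        out = simulate(mnet, proto, mnoise, dt=cfg.dt, seed=cfg.seed + 5,
                       n_trials=n_trials, record_dt=5.0, trial_stats=True,
                       init="rest")
        var = out.trial_var.mean(axis=1)
        res = variability_timescales(out.times, var, onset=1500.0,
                                     offset=2500.0,
                                     baseline_window=(800.0, 1500.0),
                                     plateau_window=(2200.0, 2500.0))
        add("multiattractor", c, res)
    return {"fig7_variance": pd.DataFrame(rows_var),
            "fig7_timescales": pd.DataFrame(rows_ts)}


DRIVERS = {"fig2d": drive_fig2d, "fig3": drive_fig3, "fig4": drive_fig4,
           "fig5": drive_fig5, "fig6": drive_fig6, "fig7": drive_fig7}


def run_experiment(config: ExperimentConfig, outdir=None) -> dict[str, pd.DataFrame]:
    """Run one named experiment driver; optionally write CSVs + provenance."""
    if config.name not in DRIVERS:
        raise ConfigurationError(
            f"unknown experiment {config.name!r}; choose from {sorted(DRIVERS)}")
    tables = DRIVERS[config.name](config)
    if outdir is not None:
        _write(Path(outdir), tables, config)
    return tables


# ---------------------------------------------------------------------------
# Synthetic spike-count fixtures
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Synthetic orientation-tuned spike-count dataset.

    Emulates the shape of an awake-V1 grating dataset: ``n_units``
    orientation-tuned units, counts per trial and orientation condition in a
    ``window_ms`` window.  ``mode='parametric'`` draws tuning curves
    f(theta) = f0 + fm exp[kappa(cos 2(theta - pref) - 1)] with a rank-1
    multiplicative shared gain (doubly stochastic Poisson);
    ``mode='ring'`` drives counts with ring-SSN rate simulations.
    """

    n_units: int = 100
    n_trials: int = 50
    orientations: tuple = tuple(np.arange(0.0, 180.0, 22.5))
    window_ms: float = 100.0
    mode: str = "parametric"
    f0_range: tuple = (0.5, 3.0)
    fm_range: tuple = (10.0, 40.0)
    kappa_range: tuple = (0.8, 2.5)
    shared_gain_std: float = 0.6
    ring_trials: int | None = None


def generate_fixture(spec: FixtureSpec, seed: int = 0):
    """Generate counts (conditions, trials, units) plus ground truth.

    Returns ``(counts_evoked, counts_spontaneous, truth)`` where truth holds
    the generating tuning parameters (parametric mode) or the underlying
    rate integrals (ring mode).
    """
    rng = np.random.default_rng(seed)
    win_s = spec.window_ms / 1000.0
    if spec.mode == "parametric":
        f0 = rng.uniform(*spec.f0_range, spec.n_units)
        fm = rng.uniform(*spec.fm_range, spec.n_units)
        kappa = rng.uniform(*spec.kappa_range, spec.n_units)
        pref = rng.uniform(0.0, 180.0, spec.n_units)
        oris = np.asarray(spec.orientations)
        lam = f0[None, :] + fm[None, :] * np.exp(
            kappa[None, :] * (np.cos(2 * np.deg2rad(oris[:, None] - pref[None, :])) - 1.0))
        gain = 1.0 + spec.shared_gain_std * rng.standard_normal(
            (len(oris), spec.n_trials))
        gain = np.maximum(gain, 0.0)
        rate = lam[:, None, :] * gain[:, :, None] * win_s
        counts = rng.poisson(rate)
        spont = rng.poisson(np.broadcast_to(f0 * win_s,
                                            (1, spec.n_trials, spec.n_units)))
        truth = dict(f0=f0, fm=fm, kappa=kappa, pref=pref,
                     shared_gain_std=spec.shared_gain_std, mode="parametric")
        return counts, spont, truth
    if spec.mode == "ring":
        geo = RingGeometry()
        net, noise = build_ring(geo)
        n_tr = spec.ring_trials or spec.n_trials
        lam_by_cond = []
        for ci, ori in enumerate(spec.orientations):
            h = ring_input(RingInputParams(c=1.0, theta_stim=2.0 * ori), geo)
            out = simulate(net, StimulusProtocol.constant(h, 400.0), noise,
                           dt=0.1, seed=seed + 101 * ci, n_trials=n_tr,
                           count_bin=spec.window_ms, count_start=300.0,
                           init="fixed_point")
            lam_by_cond.append(out.rate_integral[:, 0, net.e_mask])
        lam = np.stack(lam_by_cond)
        counts = rng.poisson(lam)
        out0 = simulate(net, StimulusProtocol.constant(
            ring_input(RingInputParams(c=0.0), geo), 400.0), noise,
            dt=0.1, seed=seed + 17, n_trials=n_tr,
            count_bin=spec.window_ms, count_start=300.0, init="fixed_point")
        spont = rng.poisson(out0.rate_integral[:, :1, net.e_mask].transpose(1, 0, 2))
        truth = dict(mode="ring", rate_integrals=lam,
                     theta=net.theta[net.e_mask])
        return counts, spont, truth
    raise ConfigurationError(f"unknown fixture mode {spec.mode!r}")


# ---------------------------------------------------------------------------
# Robustness sweep
# ---------------------------------------------------------------------------

def parameter_sweep(base: TwoPopParams | None, brackets: dict,
                    n_draws: int, seed: int = 0,
                    h_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Random sweep of reduced-SSN parameters within user-supplied brackets.

    Per draw: parameters are sampled uniformly inside ``brackets`` (keys are
    :class:`TwoPopParams` field names, values (lo, hi)); the draw is flagged
    unstable if the fixed point at the top of the input range loses
    stability.  For stable draws the linearized std(V_E)(h) curve is
    computed and its interior peak located.
    """
    base = base or TwoPopParams()
    rng = np.random.default_rng(seed)
    hs = np.arange(0.0, 20.5, 0.5) if h_grid is None else np.asarray(h_grid)
    rows = []
    for d in range(n_draws):
        over = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in brackets.items()}
        p = dataclasses.replace(base, **over)
        row = dict(draw=d, **over)
        try:
            net, noise = build_two_pop(p)
            Vtop = fixed_point(net, hs[-1], check_stability=False)
            stable = np.max(np.linalg.eigvals(jacobian(net, Vtop)).real) < 0
            row["stable"] = bool(stable)
            if stable:
                stds = np.array([np.sqrt(linearized_covariance(net, noise, h)[0, 0])
                                 for h in hs])
                i = int(np.argmax(stds))
                Vp = fixed_point(net, hs[i], check_stability=False)
                row.update(peak_h=float(hs[i]), peak_std=float(stds[i]),
                           rate_E_at_peak=float(net.rate(Vp)[0]),
                           std_at_h2=float(stds[np.searchsorted(hs, 2.0)]),
                           std_at_h15=float(stds[np.searchsorted(hs, 15.0)]))
        except Exception as err:  # noqa: BLE001 - per-draw flagging by design
            row["stable"] = False
            row["error"] = type(err).__name__
        rows.append(row)
    return pd.DataFrame(rows)
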