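"""Bayesian estimation of the volumetric force calibration constant.

In a purely viscous silicone-oil gel the Stokes drag balances the sinusoidal
magnetic force, so each probe's displacement is

    x(t) = -(2 r^2 fv) / (9 eta omega) cos(omega t) + C,

with fv the volumetric force constant (probe magnetization and field-gradient
amplitude fused into one N/m^3 quantity).  The joint model shares fv across
probes, treats each probe's true radius as latent under a measurement-error
model (measured radius = true + Normal(0, tau^2), true radii exchangeable
around a batch mean), uses a single Gaussian noise level for all signals
(tracking in oil is benign), marginalises the per-signal offset C
analytically, and absorbs small synchronisation errors into a tightly
constrained per-signal phase nuisance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._dists import (
    halfnormal_logpdf,
    invgamma_logpdf,
    normal_logpdf,
)
from ._mcmc import (
    EnsembleResult,
    MCMCSettings,
    convergence_flags,
    diagnostics_from_draws,
    find_map,
    initial_cov,
    run_ensemble,
)
from .datatypes import DisplacementSignal, Probe
from .signals import pointwise_fv
from .units import NM, UM

DEG = np.pi / 180.0


@dataclass
class CalibrationConfig:
    """Priors and physical constants for the oil calibration.

    The oil viscosity default corresponds to a 30,000 cSt silicone oil at
    0.975 g/mL density.  The fv prior is deliberately loose (5% CV); the
    radius hyperpriors are weakly informative around the nominal probe size.
    """

    viscosity: float = 29.2  # Pa s
    drive_frequency: float = 0.05  # Hz
    fv_prior_mean: float = 280_000.0  # N/m^3
    fv_prior_sd: float = 14_000.0
    radius_tau: float = 0.1  # um, radius measurement error
    r_mu_prior: tuple = (6.0, 1.0)  # Normal, um
    r_sigma_prior: tuple = (2.0, 0.5)  # InverseGamma(alpha, beta)
    noise_sd_prior_scale: float = 50.0  # Half-Normal scale, nm
    phase_nuisance: bool = True
    phase_nuisance_sd: float = 3.0 * DEG  # rad

    def __post_init__(self):
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.fv_prior_sd <= 0 or self.radius_tau <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class CalibrationPosterior:
    """Posterior draws (chains x draws) and diagnostics for the calibration."""

    fv: np.ndarray  # (chains, draws)
    r_star: np.ndarray  # (chains, draws, n_probes)
    r_mu: np.ndarray
    r_sigma: np.ndarray
    noise_sd: np.ndarray  # nm
    probe_ids: list
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True
    warnings: list = field(default_factory=list)
    config: Optional[CalibrationConfig] = None

    @property
    def fv_flat(self) -> np.ndarray:
        return self.fv.reshape(-1)

    def summary(self) -> dict:
        return summarize_calibration(self)


def detrend_linear(signal: DisplacementSignal) -> DisplacementSignal:
    """Remove a linear drift (slope only; the offset is a model nuisance)."""
    t = signal.times - signal.times.mean()
    slope = float(np.dot(t, signal.displacements) / np.dot(t, t))
    return DisplacementSignal(
        magnetic_probe_id=signal.magnetic_probe_id,
        reference_probe_id=signal.reference_probe_id,
        times=signal.times.copy(),
        displacements=signal.displacements - slope * t,
        drive_frequency=signal.drive_frequency,
    )


class _CalibrationDensity:
    """Vectorised log posterior over (walkers, dim).

    Parameter layout (unconstrained):
      [z_fv, r_mu, log_r_sigma, log_sigma, z_r (n), delta (S, optional)]
    with fv = prior_mean + prior_sd * z_fv and r*_i = r_mu + r_sigma * z_i.
    The per-signal offset C is marginalised under a flat prior, which reduces
    the Gaussian likelihood to the mean-centred residuals with n_s - 1
    effective samples per signal.
    """

    def __init__(self, signals, probes, config: CalibrationConfig):
        self.config = config
        mag = [p for p in probes if p.is_magnetic]
        by_id = {p.id: i for i, p in enumerate(mag)}
        self.probe_ids = [p.id for p in mag]
        self.r_meas = np.array([p.measured_radius for p in mag])
        self.n_probes = len(mag)
        if self.n_probes < 1:
            raise ValueError("need at least one magnetic probe")

        starts, t_all, y_all, p_of_s = [], [], [], []
        pos = 0
        for s in signals:
            if s.magnetic_probe_id not in by_id:
                raise ValueError(f"signal for unknown probe {s.magnetic_probe_id!r}")
            starts.append(pos)
            t_all.append(s.times)
            y_all.append(s.displacements)
            p_of_s.append(by_id[s.magnetic_probe_id])
            pos += len(s)
        self.n_signals = len(signals)
        self.starts = np.array(starts, dtype=np.intp)
        self.t = np.concatenate(t_all)
        self.y = np.concatenate(y_all)
        self.p_of_s = np.array(p_of_s, dtype=np.intp)
        self.ns = np.diff(np.append(self.starts, self.t.size)).astype(float)
        # per-sample signal index for broadcasting per-signal quantities
        self.s_of_t = np.repeat(np.arange(self.n_signals), self.ns.astype(int))
        omega = 2.0 * np.pi * config.drive_frequency
        self.cos_t = np.cos(omega * self.t)
        self.sin_t = np.sin(omega * self.t)
        self.omega = omega
        self.dim = 4 + self.n_probes + (self.n_signals if config.phase_nuisance else 0)

    def unpack(self, theta: np.ndarray) -> dict:
        theta = np.atleast_2d(theta)
        c = self.config
        out = {
            "fv": c.fv_prior_mean + c.fv_prior_sd * theta[:, 0],
            "r_mu": theta[:, 1],
            "r_sigma": np.exp(theta[:, 2]),
            "sigma": np.exp(theta[:, 3]),
            "z_r": theta[:, 4 : 4 + self.n_probes],
        }
        out["r_star"] = out["r_mu"][:, None] + out["r_sigma"][:, None] * out["z_r"]
        if c.phase_nuisance:
            out["delta"] = theta[:, 4 + self.n_probes :]
        else:
            out["delta"] = np.zeros((theta.shape[0], self.n_signals))
        return out

    def amplitude_nm(self, fv, r_star):
        """Oil-response amplitude in nm for batched fv (W,) and radii (W, n)."""
        r_m = r_star * UM
        return 2.0 * r_m**2 * fv[:, None] / (9.0 * self.config.viscosity * self.omega) / NM

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        c = self.config
        p = self.unpack(theta)
        lp = np.zeros(theta.shape[0])

        # priors (with log-jacobians of the log transforms)
        lp += normal_logpdf(theta[:, 0], 0.0, 1.0)
        lp += normal_logpdf(p["r_mu"], c.r_mu_prior[0], c.r_mu_prior[1])
        lp += invgamma_logpdf(p["r_sigma"], *c.r_sigma_prior) + theta[:, 2]
        lp += halfnormal_logpdf(p["sigma"], c.noise_sd_prior_scale) + theta[:, 3]
        lp += normal_logpdf(p["z_r"], 0.0, 1.0).sum(axis=1)
        if c.phase_nuisance:
            lp += normal_logpdf(p["delta"], 0.0, c.phase_nuisance_sd).sum(axis=1)

        bad = (p["fv"] <= 0) | np.any(p["r_star"] <= 0, axis=1)

        # radius measurement likelihood
        lp += normal_logpdf(self.r_meas[None, :], p["r_star"], c.radius_tau).sum(axis=1)

        # signal likelihood with offsets marginalised (flat prior on C)
        amp = self.amplitude_nm(p["fv"], p["r_star"])  # (W, n_probes)
        a_sig = amp[:, self.p_of_s]  # (W, S)
        cos_d = np.cos(p["delta"])
        sin_d = np.sin(p["delta"])
        mean = -a_sig[:, self.s_of_t] * (
            self.cos_t[None, :] * cos_d[:, self.s_of_t]
            - self.sin_t[None, :] * sin_d[:, self.s_of_t]
        )
        e = self.y[None, :] - mean
        seg_sum = np.add.reduceat(e, self.starts, axis=1)
        seg_sumsq = np.add.reduceat(e**2, self.starts, axis=1)
        sse = seg_sumsq - seg_sum**2 / self.ns[None, :]
        sigma = p["sigma"]
        lp += np.sum(
            -(self.ns[None, :] - 1.0) * np.log(sigma)[:, None] - sse / (2.0 * sigma[:, None] ** 2),
            axis=1,
        )
        lp[bad] = -np.inf
        return lp if theta.shape[0] > 1 else lp

    def initial_point(self) -> np.ndarray:
        c = self.config
        # data-driven start: pointwise fv per signal at measured radii
        fvs = []
        for s_idx in range(self.n_signals):
            sl = slice(
                self.starts[s_idx],
                self.starts[s_idx] + int(self.ns[s_idx]),
            )
            sig = DisplacementSignal(
                magnetic_probe_id="init",
                reference_probe_id="raw",
                times=self.t[sl],
                displacements=self.y[sl],
                drive_frequency=c.drive_frequency,
            )
            try:
                fvs.append(
                    pointwise_fv(sig, self.r_meas[self.p_of_s[s_idx]], c.viscosity)
                )
            except ValueError:
                pass
        fv0 = float(np.median(fvs)) if fvs else c.fv_prior_mean
        x0 = np.zeros(self.dim)
        x0[0] = (fv0 - c.fv_prior_mean) / c.fv_prior_sd
        x0[1] = float(np.mean(self.r_meas))
        x0[2] = np.log(max(float(np.std(self.r_meas)), 0.05))
        x0[3] = np.log(5.0)
        return x0


def fit_calibration(
    signals: Sequence[DisplacementSignal],
    probes: Sequence[Probe],
    config: Optional[CalibrationConfig] = None,
    mcmc: Optional[MCMCSettings] = None,
    detrend: bool = True,
) -> CalibrationPosterior:
    """Sample the joint calibration posterior.

    ``signals`` are oil-calibration tracks (one or more per magnetic probe);
    linear drift is removed up front unless the caller has already done so.
    Non-convergence (split R-hat > 1.05) is flagged on the returned object,
    never silently ignored.
    """
    config = config or CalibrationConfig()
    mcmc = mcmc or MCMCSettings(chains=4, draws=500, warmup=2000)
    if detrend:
        signals = [detrend_linear(s) for s in signals]
    density = _CalibrationDensity(signals, probes, config)
    x0 = find_map(density, density.initial_point(), maxiter=400)
    cov = initial_cov(density, x0)
    result: EnsembleResult = run_ensemble(density, x0, mcmc, init_cov=cov)

    chains, draws, _ = result.chain.shape
    p = density.unpack(result.flat)
    shape2 = (chains, draws)
    fv = p["fv"].reshape(shape2)
    draws_dict = {
        "fv": fv,
        "r_mu": p["r_mu"].reshape(shape2),
        "r_sigma": p["r_sigma"].reshape(shape2),
        "noise_sd": p["sigma"].reshape(shape2),
        "r_star": p["r_star"].reshape(chains, draws, -1),
    }
    report = diagnostics_from_draws(draws_dict)
    report["acceptance"] = result.acceptance
    converged, warns = convergence_flags(report)
    return CalibrationPosterior(
        fv=fv,
        r_star=draws_dict["r_star"],
        r_mu=draws_dict["r_mu"],
        r_sigma=draws_dict["r_sigma"],
        noise_sd=draws_dict["noise_sd"],
        probe_ids=density.probe_ids,
        diagnostics=report,
        converged=converged,
        warnings=warns,
        config=config,
    )


def summarize_calibration(posterior: CalibrationPosterior | np.ndarray) -> dict:
    """Mean, SD and coefficient of variation of fv over pooled draws."""
    draws = (
        posterior.fv_flat if isinstance(posterior, CalibrationPosterior) else np.ravel(posterior)
    )
    if draws.size == 0:
        raise ValueError("empty posterior draws")
    mean = float(np.mean(draws))
    sd = float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0
    return {"mean": mean, "sd": sd, "cv_percent": 100.0 * sd / mean}
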