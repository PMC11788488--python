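"""Hierarchical Bayesian spatial model of viscoelastic fields.

Each magnetic probe's noise-corrected displacement signal is modelled with a
Student-t likelihood whose mean is the sinusoidal response

    d_i(t) ~ StudentT(nu,  2 fv r*_i^2 / (9 g(x_i)) sin(2 pi f t - h(x_i)),  sigma_i)

where g (stiffness, Pa) and h (phase angle, rad) are latent spatial fields
with zero-mean Gaussian-process priors pushed through softplus and
arcsin(sigmoid) links.  Kernels are exponentiated-quadratic with white noise
and per-dimension length scales; kernel amplitudes are pooled hierarchically
across fields of view within a condition (noncentered, softplus-positive),
length scales share a generalized-inverse-Gaussian prior tied through a
common scale, field-of-view mean levels are pooled around condition-level
means, per-probe noise levels are partially pooled on the log scale, probe
radii carry a measurement-error model, and the force constant fv can inherit
the calibration posterior's uncertainty.

Sampling uses the ensemble driver in :mod:`vemap._mcmc`; walkers start from a
Laplace approximation at the MAP and are regrouped into pseudo-chains for
R-hat / ESS diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import gammaln

from ._dists import (
    gig_logpdf,
    halfnormal_logpdf,
    invgamma_logpdf,
    normal_logpdf,
    studentt_prior_logpdf,
)
from ._mcmc import (
    MCMCSettings,
    convergence_flags,
    diagnostics_from_draws,
    find_map,
    initial_cov,
    run_ensemble,
)
from .calibration import CalibrationPosterior
from .datatypes import DisplacementSignal, FOVDataset, Probe
from .links import inv_softplus, phase_link, sigmoid, softplus, stiffness_link
from .signals import baseline_estimates
from .units import NM, UM

# numerical floor for the stiffness field (Pa): keeps amplitudes finite when
# a prior draw pushes the softplus argument far negative
GSTAR_FLOOR = 1e-6


def signal_mean(t, fv, r_star_um, gstar_pa, phi, f):
    """Mean displacement (nm) of the Student-t likelihood."""
    if np.any(np.asarray(gstar_pa) <= 0):
        raise ValueError("gstar must be positive")
    amp = 2.0 * fv * (np.asarray(r_star_um) * UM) ** 2 / (9.0 * np.asarray(gstar_pa)) / NM
    return amp * np.sin(2.0 * np.pi * f * np.asarray(t) - phi)


@dataclass
class PriorConfig:
    """Every prior of the spatial model, overridable field by field.

    Scales are on the link (pre-softplus / logit) scale unless a unit is
    noted.  ``coord_scale`` rescales coordinates before the length-scale
    prior; at the default 100 um the GIG(2, 15, l_sigma) prior concentrates
    on FOV-sized smoothness.
    """

    mu_gstar_prior: tuple = (50.0, 15.0)  # Normal, pre-softplus Pa scale
    mu_phi_prior: tuple = (0.0, 0.3)  # Normal, logit scale
    fov_mean_scale_prior: float = 1.0  # Half-Normal, both fields
    alpha_mu_g_prior: tuple = (3.0, 0.0, 20.0)  # Student-t(df, loc, scale)
    alpha_sigma_g_prior: float = 5.0  # Half-Normal
    alpha_mu_h_prior: tuple = (0.0, 5.0)  # Normal
    alpha_sigma_h_prior: float = 1.0  # Half-Normal
    l_sigma_prior: float = 1.0  # Half-Normal
    sigma_sigma_prior: float = 1.0  # Half-Normal (kernel white noise)
    gig_p: float = 2.0
    gig_a: float = 15.0
    nu_prior: tuple = (3.0, 10.0)  # InverseGamma on the t dof
    noise_mu_prior: tuple = (np.log(5.0), 1.0)  # Normal on log sigma_i (nm)
    noise_scale_prior: float = 1.0  # Half-Normal on the pooling scale
    r_mu_prior: tuple = (6.0, 1.0)  # Normal, um
    r_sigma_prior: tuple = (2.0, 0.5)  # InverseGamma
    radius_tau: float = 0.1  # um
    radius_fixed: bool = False  # ablation: treat measured radii as exact
    coord_scale: float = 100.0  # um per length-scale unit


@dataclass
class KernelParams:
    """Kernel hyperparameters of one field in one field of view."""

    amplitude: float
    length_scales: np.ndarray  # um
    white_noise_sd: float = 0.0

    def __post_init__(self):
        self.length_scales = np.asarray(self.length_scales, dtype=float)
        if self.amplitude <= 0 or np.any(self.length_scales <= 0) or self.white_noise_sd < 0:
            raise ValueError("kernel parameters out of range")


def _batched_chol(k):
    """Cholesky of a (W, n, n) stack; returns (L, ok mask) without raising."""
    n = k.shape[-1]
    jitter = 1e-9 * np.mean(np.diagonal(k, axis1=-2, axis2=-1), axis=-1)
    k = k + jitter[..., None, None] * np.eye(n)
    try:
        return np.linalg.cholesky(k), np.ones(k.shape[0], dtype=bool)
    except np.linalg.LinAlgError:
        L = np.zeros_like(k)
        ok = np.zeros(k.shape[0], dtype=bool)
        for w in range(k.shape[0]):
            try:
                L[w] = np.linalg.cholesky(k[w])
                ok[w] = True
            except np.linalg.LinAlgError:
                pass
        return L, ok


class _Index:
    """Slice bookkeeping for the flat unconstrained parameter vector."""

    def __init__(self):
        self.slices: dict[str, slice] = {}
        self.dim = 0

    def add(self, name: str, size: int):
        self.slices[name] = slice(self.dim, self.dim + size)
        self.dim += size

    def __call__(self, theta: np.ndarray, name: str) -> np.ndarray:
        return theta[:, self.slices[name]]


class SpatialModel:
    """Joint log density over all random variables of the spatial model.

    Instances are callable on a (walkers, dim) array of unconstrained
    parameters and return the vector of log posterior densities.
    """

    def __init__(
        self,
        data: Sequence[FOVDataset],
        fv_source: Union[CalibrationPosterior, float, tuple],
        priors: Optional[PriorConfig] = None,
    ):
        self.priors = priors or PriorConfig()
        self.fovs = list(data)
        if not self.fovs:
            raise ValueError("need at least one FOV")
        self.conditions = sorted({f.condition for f in self.fovs})
        self.cond_of_fov = np.array(
            [self.conditions.index(f.condition) for f in self.fovs], dtype=np.intp
        )
        self.n_cond = len(self.conditions)
        self.n_fov = len(self.fovs)

        # fv handling
        if isinstance(fv_source, CalibrationPosterior):
            s = fv_source.summary()
            self.fv_mean, self.fv_sd = s["mean"], s["sd"]
        elif isinstance(fv_source, tuple):
            self.fv_mean, self.fv_sd = float(fv_source[0]), float(fv_source[1])
        else:
            self.fv_mean, self.fv_sd = float(fv_source), 0.0
        if self.fv_mean <= 0:
            raise ValueError("fv must be positive")

        # probe bookkeeping (magnetic probes only, FOV-major order)
        self.probe_ids: list[str] = []
        self.locations_um: list[np.ndarray] = []
        self.fov_probe_slices: list[slice] = []
        r_meas = []
        pos = 0
        self.drive_frequency = None
        t_all, y_all, p_of_t = [], [], []
        n_samples_per_probe = []
        for j, fov in enumerate(self.fovs):
            mags = fov.magnetic_probes()
            self.fov_probe_slices.append(slice(pos, pos + len(mags)))
            for p in mags:
                if p.measured_radius is None:
                    raise ValueError(f"magnetic probe {p.id!r} lacks a measured radius")
                sigs = fov.signals_for(p.id)
                if not sigs:
                    raise ValueError(f"magnetic probe {p.id!r} has no signal")
                count = 0
                for s in sigs:
                    if self.drive_frequency is None:
                        self.drive_frequency = s.drive_frequency
                    t_all.append(s.times)
                    y_all.append(s.displacements)
                    p_of_t.append(np.full(len(s), pos, dtype=np.intp))
                    count += len(s)
                n_samples_per_probe.append(count)
                self.probe_ids.append(p.id)
                self.locations_um.append(p.location)
                r_meas.append(p.measured_radius)
                pos += 1
        self.n_probes = pos
        self.r_meas = np.asarray(r_meas)
        self.locations_um = np.asarray(self.locations_um)
        self.t = np.concatenate(t_all)
        self.y = np.concatenate(y_all)
        self.p_of_t = np.concatenate(p_of_t)
        self.n_samples_per_probe = np.asarray(n_samples_per_probe, dtype=float)
        w = 2.0 * np.pi * self.drive_frequency
        self.sin_t = np.sin(w * self.t)
        self.cos_t = np.cos(w * self.t)

        # scaled coordinates and pairwise squared distances per FOV
        self.coords = [
            (self.locations_um[sl] / self.priors.coord_scale) for sl in self.fov_probe_slices
        ]
        self.sqdist = []
        for c in self.coords:
            d = c[:, None, :] - c[None, :, :]
            self.sqdist.append(d**2)  # (n_j, n_j, 2)

        self._build_index()

    # -- parameter layout ---------------------------------------------------
    def _build_index(self):
        ix = _Index()
        ix.add("log_nu", 1)
        if self.fv_sd > 0:
            ix.add("z_fv", 1)
        ix.add("noise_mu", 1)
        ix.add("log_noise_scale", 1)
        ix.add("r_mu", 1)
        ix.add("log_r_sigma", 1)
        ix.add("log_l_sigma", 1)
        ix.add("log_sigma_sigma", 1)
        ix.add("log_s_mu_g", 1)
        ix.add("log_s_mu_h", 1)
        ix.add("alpha_mu_g", self.n_cond)
        ix.add("log_alpha_sigma_g", self.n_cond)
        ix.add("alpha_mu_h", self.n_cond)
        ix.add("log_alpha_sigma_h", self.n_cond)
        ix.add("M_g", self.n_cond)
        ix.add("M_h", self.n_cond)
        ix.add("z_alpha_g", self.n_fov)
        ix.add("z_alpha_h", self.n_fov)
        ix.add("log_l_g", 2 * self.n_fov)
        ix.add("log_l_h", 2 * self.n_fov)
        ix.add("z_mu_g", self.n_fov)
        ix.add("z_mu_h", self.n_fov)
        ix.add("u_g", self.n_probes)
        ix.add("u_h", self.n_probes)
        ix.add("z_log_sigma", self.n_probes)
        if not self.priors.radius_fixed:
            ix.add("z_r", self.n_probes)
        self.index = ix
        self.dim = ix.dim

    # -- transforms ---------------------------------------------------------
    def unpack(self, theta: np.ndarray, with_latent: bool = True) -> dict:
        """Constrained parameters (and latent fields) for a (W, dim) batch."""
        theta = np.atleast_2d(theta)
        ix = self.index
        p: dict[str, np.ndarray] = {}
        p["nu"] = np.exp(ix(theta, "log_nu")[:, 0])
        if self.fv_sd > 0:
            p["fv"] = self.fv_mean + self.fv_sd * ix(theta, "z_fv")[:, 0]
        else:
            p["fv"] = np.full(theta.shape[0], self.fv_mean)
        p["noise_mu"] = ix(theta, "noise_mu")[:, 0]
        p["noise_scale"] = np.exp(ix(theta, "log_noise_scale")[:, 0])
        p["r_mu"] = ix(theta, "r_mu")[:, 0]
        p["r_sigma"] = np.exp(ix(theta, "log_r_sigma")[:, 0])
        p["l_sigma"] = np.exp(ix(theta, "log_l_sigma")[:, 0])
        p["sigma_sigma"] = np.exp(ix(theta, "log_sigma_sigma")[:, 0])
        p["s_mu_g"] = np.exp(ix(theta, "log_s_mu_g")[:, 0])
        p["s_mu_h"] = np.exp(ix(theta, "log_s_mu_h")[:, 0])
        for k in ("alpha_mu_g", "alpha_mu_h", "M_g", "M_h"):
            p[k] = ix(theta, k)
        p["alpha_sigma_g"] = np.exp(ix(theta, "log_alpha_sigma_g"))
        p["alpha_sigma_h"] = np.exp(ix(theta, "log_alpha_sigma_h"))
        c = self.cond_of_fov
        p["alpha_g"] = softplus(
            p["alpha_mu_g"][:, c] + p["alpha_sigma_g"][:, c] * ix(theta, "z_alpha_g")
        )
        p["alpha_h"] = softplus(
            p["alpha_mu_h"][:, c] + p["alpha_sigma_h"][:, c] * ix(theta, "z_alpha_h")
        )
        p["l_g"] = np.exp(ix(theta, "log_l_g")).reshape(theta.shape[0], self.n_fov, 2)
        p["l_h"] = np.exp(ix(theta, "log_l_h")).reshape(theta.shape[0], self.n_fov, 2)
        p["mu_g"] = p["M_g"][:, c] + p["s_mu_g"][:, None] * ix(theta, "z_mu_g")
        p["mu_h"] = p["M_h"][:, c] + p["s_mu_h"][:, None] * ix(theta, "z_mu_h")
        p["sigma_i"] = np.exp(
            p["noise_mu"][:, None] + p["noise_scale"][:, None] * ix(theta, "z_log_sigma")
        )
        if self.priors.radius_fixed:
            p["r_star"] = np.broadcast_to(self.r_meas[None, :], (theta.shape[0], self.n_probes))
        else:
            p["r_star"] = p["r_mu"][:, None] + p["r_sigma"][:, None] * ix(theta, "z_r")
        if with_latent:
            lat_g, ok_g = self._latents(theta, p, "g")
            lat_h, ok_h = self._latents(theta, p, "h")
            p["latent_g"], p["latent_h"] = lat_g, lat_h
            p["chol_ok"] = ok_g & ok_h
            p["g"] = np.maximum(
                stiffness_link(lat_g, p["mu_g"][:, self._fov_of_probe()]), GSTAR_FLOOR
            )
            p["h"] = phase_link(lat_h, p["mu_h"][:, self._fov_of_probe()])
        return p

    def _fov_of_probe(self):
        out = np.empty(self.n_probes, dtype=np.intp)
        for j, sl in enumerate(self.fov_probe_slices):
            out[sl] = j
        return out

    def _latents(self, theta, p, kind, return_chols=False):
        """Whitened-to-correlated latent values, FOV by FOV: f = chol(K) u."""
        u = self.index(theta, f"u_{kind}")
        alpha = p[f"alpha_{kind}"]
        ls = p[f"l_{kind}"]
        lat = np.empty_like(u)
        ok = np.ones(theta.shape[0], dtype=bool)
        chols = []
        for j, sl in enumerate(self.fov_probe_slices):
            quad = np.sum(
                self.sqdist[j][None, ...] / (2.0 * ls[:, j][:, None, None, :] ** 2), axis=-1
            )
            k = alpha[:, j, None, None] ** 2 * np.exp(-quad)
            k = k + (p["sigma_sigma"] ** 2)[:, None, None] * np.eye(k.shape[-1])
            L, ok_j = _batched_chol(k)
            lat[:, sl] = np.einsum("wij,wj->wi", L, u[:, sl])
            ok &= ok_j
            if return_chols:
                chols.append(L)
        if return_chols:
            return lat, ok, chols
        return lat, ok

    def ridge_move(self, coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Metropolis sweep along the radius-stiffness degeneracy ridge.

        The displacement amplitude pins only the product r*^2 / g, so the
        posterior has a soft valley where inflating a probe's radius and its
        stiffness together leaves the likelihood unchanged; generic ensemble
        moves traverse it poorly.  This move proposes, per walker, correlated
        shifts delta ~ N(0, (tau/2)^2) of every r*_i with the exactly
        compensating g rescaling (u_g re-whitened through the current
        Cholesky factors), and accepts with the Metropolis ratio including
        the Jacobian of the deterministic companion map.  It leaves the
        posterior invariant and is interleaved with the ensemble moves.
        """
        if self.priors.radius_fixed:
            return coords
        theta = np.array(coords, dtype=float)
        w = theta.shape[0]
        ix = self.index
        lp0 = self(theta)
        p = self.unpack(theta)
        fovidx = self._fov_of_probe()
        mu = p["mu_g"][:, fovidx]

        delta = rng.normal(0.0, 0.5 * self.priors.radius_tau, size=(w, self.n_probes))
        r_old = p["r_star"]
        r_new = r_old + delta
        with np.errstate(all="ignore"):
            ratio2 = (r_new / r_old) ** 2
            g_new = p["g"] * ratio2
            valid = (
                np.all(r_new > 0.1, axis=1)
                & np.all(g_new > GSTAR_FLOOR, axis=1)
                & np.all(p["g"] > GSTAR_FLOOR, axis=1)
            )
            g_new = np.maximum(g_new, GSTAR_FLOOR)
            f_old = p["latent_g"]
            f_new = inv_softplus(g_new) - mu
            # per-probe Jacobian of the companion map f -> f'
            log_jac = np.sum(
                np.log(sigmoid(f_old + mu)) + np.log(ratio2) - np.log(sigmoid(f_new + mu)),
                axis=1,
            )

        theta_new = theta.copy()
        theta_new[:, ix.slices["z_r"]] = (r_new - p["r_mu"][:, None]) / p["r_sigma"][:, None]
        _, _, chols = self._latents(theta, p, "g", return_chols=True)
        u_new = np.empty_like(f_new)
        for j, sl in enumerate(self.fov_probe_slices):
            u_new[:, sl] = np.linalg.solve(chols[j], f_new[:, sl][..., None])[..., 0]
        theta_new[:, ix.slices["u_g"]] = u_new

        lp1 = self(theta_new)
        with np.errstate(invalid="ignore"):
            log_alpha = lp1 - lp0 + log_jac
        log_alpha = np.where(np.isfinite(log_alpha) & valid, log_alpha, -np.inf)
        accept = np.log(rng.uniform(size=w)) < log_alpha
        theta[accept] = theta_new[accept]
        return theta

    # -- densities ----------------------------------------------------------
    def log_prior(self, theta: np.ndarray, p: dict) -> np.ndarray:
        pr = self.priors
        ix = self.index
        lp = np.zeros(theta.shape[0])
        lp += invgamma_logpdf(p["nu"], *pr.nu_prior) + ix(theta, "log_nu")[:, 0]
        if self.fv_sd > 0:
            lp += normal_logpdf(ix(theta, "z_fv")[:, 0], 0.0, 1.0)
        lp += normal_logpdf(p["noise_mu"], *pr.noise_mu_prior)
        lp += halfnormal_logpdf(p["noise_scale"], pr.noise_scale_prior) + ix(
            theta, "log_noise_scale"
        )[:, 0]
        lp += normal_logpdf(p["r_mu"], *pr.r_mu_prior)
        lp += invgamma_logpdf(p["r_sigma"], *pr.r_sigma_prior) + ix(theta, "log_r_sigma")[:, 0]
        lp += halfnormal_logpdf(p["l_sigma"], pr.l_sigma_prior) + ix(theta, "log_l_sigma")[:, 0]
        lp += halfnormal_logpdf(p["sigma_sigma"], pr.sigma_sigma_prior) + ix(
            theta, "log_sigma_sigma"
        )[:, 0]
        for name in ("s_mu_g", "s_mu_h"):
            lp += halfnormal_logpdf(p[name], pr.fov_mean_scale_prior) + ix(
                theta, f"log_{name}"
            )[:, 0]
        lp += studentt_prior_logpdf(p["alpha_mu_g"], *pr.alpha_mu_g_prior).sum(axis=1)
        lp += (
            halfnormal_logpdf(p["alpha_sigma_g"], pr.alpha_sigma_g_prior)
            + ix(theta, "log_alpha_sigma_g")
        ).sum(axis=1)
        lp += normal_logpdf(p["alpha_mu_h"], *pr.alpha_mu_h_prior).sum(axis=1)
        lp += (
            halfnormal_logpdf(p["alpha_sigma_h"], pr.alpha_sigma_h_prior)
            + ix(theta, "log_alpha_sigma_h")
        ).sum(axis=1)
        lp += normal_logpdf(p["M_g"], *pr.mu_gstar_prior).sum(axis=1)
        lp += normal_logpdf(p["M_h"], *pr.mu_phi_prior).sum(axis=1)
        z_names = ["z_alpha_g", "z_alpha_h", "z_mu_g", "z_mu_h", "u_g", "u_h", "z_log_sigma"]
        if not self.priors.radius_fixed:
            z_names.append("z_r")
        for name in z_names:
            lp += normal_logpdf(ix(theta, name), 0.0, 1.0).sum(axis=1)
        for kind in ("g", "h"):
            l = p[f"l_{kind}"].reshape(theta.shape[0], -1)
            lp += (
                gig_logpdf(l, pr.gig_p, pr.gig_a, p["l_sigma"][:, None])
                + np.log(l)
            ).sum(axis=1)
        return lp

    def log_likelihood(self, p: dict) -> np.ndarray:
        pr = self.priors
        # radius measurements
        if self.priors.radius_fixed:
            ll = np.zeros(p["r_star"].shape[0])
        else:
            ll = normal_logpdf(self.r_meas[None, :], p["r_star"], pr.radius_tau).sum(axis=1)
        # displacement signals, Student-t
        amp = 2.0 * p["fv"][:, None] * (p["r_star"] * UM) ** 2 / (9.0 * p["g"]) / NM
        cos_h = np.cos(p["h"])
        sin_h = np.sin(p["h"])
        mean = amp[:, self.p_of_t] * (
            self.sin_t[None, :] * cos_h[:, self.p_of_t]
            - self.cos_t[None, :] * sin_h[:, self.p_of_t]
        )
        sigma = p["sigma_i"]
        z2 = ((self.y[None, :] - mean) / sigma[:, self.p_of_t]) ** 2
        nu = p["nu"][:, None]
        ll += np.sum(-(nu + 1.0) / 2.0 * np.log1p(z2 / nu), axis=1)
        const = (
            gammaln((p["nu"] + 1.0) / 2.0)
            - gammaln(p["nu"] / 2.0)
            - 0.5 * np.log(p["nu"] * np.pi)
        )
        ll += self.t.size * const
        ll -= np.sum(self.n_samples_per_probe[None, :] * np.log(sigma), axis=1)
        return ll

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            p = self.unpack(theta)
            bad = (p["fv"] <= 0) | np.any(p["r_star"] <= 0, axis=1) | ~p["chol_ok"]
            lp = self.log_prior(theta, p) + self.log_likelihood(p)
        lp = np.where(np.isfinite(lp) & ~bad, lp, -np.inf)
        return lp

    # -- initialisation and prior simulation --------------------------------
    def initial_point(self) -> np.ndarray:
        """Data-driven start from the deterministic baseline fits."""
        x0 = np.zeros(self.dim)
        ix = self.index
        sl = ix.slices
        gstars, phis, rms = [], [], []
        for fov in self.fovs:
            ests = baseline_estimates(fov.signals, fov.probes, fv=self.fv_mean)
            for e in ests:
                gstars.append(max(e.gstar, 0.5))
                phis.append(min(max(e.phi, 0.01), np.pi / 2 - 0.01))
                rms.append(max(e.residual_rms, 0.2))
        g_link = inv_softplus(np.asarray(gstars))
        x0[sl["log_nu"]] = np.log(5.0)
        x0[sl["noise_mu"]] = np.log(np.median(rms))
        x0[sl["log_noise_scale"]] = np.log(0.5)
        x0[sl["r_mu"]] = float(np.mean(self.r_meas))
        x0[sl["log_r_sigma"]] = np.log(max(float(np.std(self.r_meas)), 0.1))
        x0[sl["log_l_sigma"]] = 0.0
        x0[sl["log_sigma_sigma"]] = np.log(0.1)
        x0[sl["log_s_mu_g"]] = np.log(0.5)
        x0[sl["log_s_mu_h"]] = np.log(0.5)
        x0[sl["alpha_mu_g"]] = max(float(np.std(g_link)), 1.0)
        x0[sl["log_alpha_sigma_g"]] = np.log(0.5)
        x0[sl["alpha_mu_h"]] = 0.0
        x0[sl["log_alpha_sigma_h"]] = np.log(0.3)
        x0[sl["M_g"]] = float(np.mean(g_link))
        phi_med = float(np.median(phis))
        s = np.clip(np.sin(phi_med), 1e-3, 1 - 1e-3)
        x0[sl["M_h"]] = np.log(s) - np.log1p(-s)
        x0[sl["log_l_g"]] = np.log(0.75)
        x0[sl["log_l_h"]] = np.log(0.75)
        noise_mu0 = float(np.log(np.median(rms)))
        x0[sl["z_log_sigma"]] = (np.log(np.asarray(rms)) - noise_mu0) / 0.5
        r_sigma0 = max(float(np.std(self.r_meas)), 0.1)
        if not self.priors.radius_fixed:
            x0[sl["z_r"]] = (self.r_meas - np.mean(self.r_meas)) / r_sigma0
        return x0

    def sample_prior_vector(self, seed=0) -> np.ndarray:
        """One unconstrained parameter vector drawn from the joint prior."""
        from scipy import stats

        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        pr = self.priors
        x = np.zeros(self.dim)
        sl = self.index.slices

        def hn(scale):
            return abs(rng.normal(0.0, scale))

        x[sl["log_nu"]] = np.log(
            stats.invgamma.rvs(pr.nu_prior[0], scale=pr.nu_prior[1], random_state=rng)
        )
        if self.fv_sd > 0:
            x[sl["z_fv"]] = rng.standard_normal()
        x[sl["noise_mu"]] = rng.normal(*pr.noise_mu_prior)
        x[sl["log_noise_scale"]] = np.log(hn(pr.noise_scale_prior))
        x[sl["r_mu"]] = rng.normal(*pr.r_mu_prior)
        x[sl["log_r_sigma"]] = np.log(
            stats.invgamma.rvs(pr.r_sigma_prior[0], scale=pr.r_sigma_prior[1], random_state=rng)
        )
        l_sigma = hn(pr.l_sigma_prior)
        x[sl["log_l_sigma"]] = np.log(l_sigma)
        x[sl["log_sigma_sigma"]] = np.log(hn(pr.sigma_sigma_prior))
        x[sl["log_s_mu_g"]] = np.log(hn(pr.fov_mean_scale_prior))
        x[sl["log_s_mu_h"]] = np.log(hn(pr.fov_mean_scale_prior))
        df, loc, scale = pr.alpha_mu_g_prior
        x[sl["alpha_mu_g"]] = loc + scale * rng.standard_t(df, size=self.n_cond)
        x[sl["log_alpha_sigma_g"]] = np.log(
            [hn(pr.alpha_sigma_g_prior) for _ in range(self.n_cond)]
        )
        x[sl["alpha_mu_h"]] = rng.normal(*pr.alpha_mu_h_prior, size=self.n_cond)
        x[sl["log_alpha_sigma_h"]] = np.log(
            [hn(pr.alpha_sigma_h_prior) for _ in range(self.n_cond)]
        )
        x[sl["M_g"]] = rng.normal(*pr.mu_gstar_prior, size=self.n_cond)
        x[sl["M_h"]] = rng.normal(*pr.mu_phi_prior, size=self.n_cond)
        for name in ("z_alpha_g", "z_alpha_h", "z_mu_g", "z_mu_h"):
            x[sl[name]] = rng.standard_normal(self.n_fov)
        # GIG(p, a, b): scipy geninvgauss(p, sqrt(ab)) scaled by sqrt(b/a)
        b = max(l_sigma, 1e-6)
        gig = stats.geninvgauss.rvs(
            pr.gig_p,
            np.sqrt(pr.gig_a * b),
            scale=np.sqrt(b / pr.gig_a),
            size=4 * self.n_fov,
            random_state=rng,
        )
        x[sl["log_l_g"]] = np.log(gig[: 2 * self.n_fov])
        x[sl["log_l_h"]] = np.log(gig[2 * self.n_fov :])
        x[sl["u_g"]] = rng.standard_normal(self.n_probes)
        x[sl["u_h"]] = rng.standard_normal(self.n_probes)
        x[sl["z_log_sigma"]] = rng.standard_normal(self.n_probes)
        if not self.priors.radius_fixed:
            x[sl["z_r"]] = rng.standard_normal(self.n_probes)
        return x

    def simulate_from_prior(self, seed=0) -> tuple[np.ndarray, list, dict]:
        """Draw parameters from the prior and synthesize matching data.

        Returns (theta, new FOV datasets, truth dict).  The datasets reuse
        this model's probe layouts and signal time grids but carry freshly
        generated measured radii and displacements, so fitting a new model to
        them is a draw from the Bayesian joint distribution (the basis of
        simulation-based-calibration checks).
        """
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        theta = self.sample_prior_vector(rng)
        p = self.unpack(theta[None, :])
        r_star = p["r_star"][0]
        r_meas = r_star + self.priors.radius_tau * rng.standard_normal(self.n_probes)
        g, h = p["g"][0], p["h"][0]
        sigma_i, nu, fv = p["sigma_i"][0], float(p["nu"][0]), float(p["fv"][0])

        new_fovs = []
        for j, fov in enumerate(self.fovs):
            sl = self.fov_probe_slices[j]
            idx_of = {pid: i for i, pid in enumerate(self.probe_ids)}
            probes = []
            for q in fov.probes:
                if q.is_magnetic:
                    i = idx_of[q.id]
                    probes.append(
                        Probe(
                            id=q.id,
                            kind=q.kind,
                            location=q.location.copy(),
                            measured_radius=float(max(r_meas[i], 1e-3)),
                            true_radius=float(r_star[i]),
                        )
                    )
                else:
                    probes.append(q)
            signals = []
            for s in fov.signals:
                i = idx_of[s.magnetic_probe_id]
                mean = signal_mean(
                    s.times, fv, r_star[i], g[i], h[i], self.drive_frequency
                )
                y = mean + sigma_i[i] * rng.standard_t(nu, size=len(s))
                signals.append(
                    DisplacementSignal(
                        magnetic_probe_id=s.magnetic_probe_id,
                        reference_probe_id=s.reference_probe_id,
                        times=s.times.copy(),
                        displacements=y,
                        drive_frequency=s.drive_frequency,
                    )
                )
            new_fovs.append(
                FOVDataset(
                    fov_id=fov.fov_id,
                    condition=fov.condition,
                    day=fov.day,
                    probes=probes,
                    signals=signals,
                )
            )
        truth = {
            "g": g,
            "h": h,
            "r_star": r_star,
            "sigma_i": sigma_i,
            "nu": nu,
            "fv": fv,
            "alpha_g": p["alpha_g"][0],
            "alpha_h": p["alpha_h"][0],
            "mu_g": p["mu_g"][0],
            "mu_h": p["mu_h"][0],
        }
        return theta, new_fovs, truth


@dataclass
class SpatialPosterior:
    """Posterior draws over every random variable, plus layout metadata."""

    draws: dict  # name -> (chains, draws, ...) on the constrained scale
    probe_ids: list
    locations_um: np.ndarray
    fov_ids: list
    fov_of_probe: np.ndarray
    conditions: list  # unique condition labels
    condition_of_fov: np.ndarray
    coord_scale: float
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True
    warnings: list = field(default_factory=list)

    def flat(self, name: str) -> np.ndarray:
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])

    @property
    def n_draws_total(self) -> int:
        return self.draws["nu"].shape[0] * self.draws["nu"].shape[1]

    def probe_indices(self, fov_id: str) -> np.ndarray:
        j = self.fov_ids.index(fov_id)
        return np.where(self.fov_of_probe == j)[0]


def build_spatial_model(
    data: Sequence[FOVDataset],
    fv_source: Union[CalibrationPosterior, float, tuple],
    priors: Optional[PriorConfig] = None,
) -> SpatialModel:
    """Assemble the joint model; see the module docstring for its structure."""
    return SpatialModel(data, fv_source, priors)


def fit_spatial(
    model: SpatialModel,
    mcmc: Optional[MCMCSettings] = None,
    map_maxiter: int = 500,
) -> SpatialPosterior:
    """MAP-initialised ensemble sampling of the spatial posterior."""
    mcmc = mcmc or MCMCSettings(chains=4, draws=1000, warmup=1500)
    x0 = find_map(model, model.initial_point(), maxiter=map_maxiter)
    cov = initial_cov(model, x0)
    extra = None if model.priors.radius_fixed else model.ridge_move
    result = run_ensemble(model, x0, mcmc, init_cov=cov, extra_move=extra)

    chains, ndraws, _ = result.chain.shape
    p = model.unpack(result.flat)

    def shp(a):
        return a.reshape(chains, ndraws, *a.shape[1:])

    keep = (
        "nu fv r_mu r_sigma sigma_sigma l_sigma noise_mu noise_scale "
        "alpha_mu_g alpha_sigma_g alpha_mu_h alpha_sigma_h M_g M_h "
        "alpha_g alpha_h mu_g mu_h sigma_i r_star g h latent_g latent_h"
    ).split()
    draws = {k: shp(p[k]) for k in keep}
    draws["l_g"] = shp(p["l_g"] * model.priors.coord_scale)  # um
    draws["l_h"] = shp(p["l_h"] * model.priors.coord_scale)

    diag_vars = {
        k: draws[k]
        for k in ("nu", "g", "h", "alpha_g", "alpha_h", "M_g", "M_h", "r_star", "sigma_i")
    }
    report = diagnostics_from_draws(diag_vars)
    report["acceptance"] = result.acceptance
    converged, warns = convergence_flags(report)
    return SpatialPosterior(
        draws=draws,
        probe_ids=model.probe_ids,
        locations_um=model.locations_um,
        fov_ids=[f.fov_id for f in model.fovs],
        fov_of_probe=model._fov_of_probe(),
        conditions=model.conditions,
        condition_of_fov=model.cond_of_fov,
        coord_scale=model.priors.coord_scale,
        diagnostics=report,
        converged=converged,
        warnings=warns,
    )


def mcmc_diagnostics(posterior: SpatialPosterior | CalibrationPosterior) -> dict:
    """R-hat, bulk/tail ESS and sampler acceptance for a fitted posterior."""
    return dict(posterior.diagnostics)
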