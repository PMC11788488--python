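"""Ensemble-MCMC driver shared by the calibration and spatial models.

Both posteriors are sampled with an affine-invariant / differential-evolution
ensemble (emcee) over a vectorised log density: the log posterior accepts a
(walkers, dim) array and returns (walkers,).  Walkers are initialised in a
tight ball around a MAP point found by L-BFGS with batched finite-difference
gradients; after warmup the retained steps are regrouped into pseudo-chains
for split-R-hat and effective-sample-size diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import emcee
import numpy as np
from scipy.optimize import minimize


@dataclass
class MCMCSettings:
    """Sampler settings.

    ``draws`` is the number of retained draws per diagnostic chain, so the
    pooled posterior holds ``chains * draws`` samples.  ``warmup`` counts
    ensemble steps discarded before retention.
    """

    chains: int = 4
    draws: int = 500
    warmup: int = 500
    seed: int = 0
    walkers: Optional[int] = None
    thin: int = 1


@dataclass
class EnsembleResult:
    chain: np.ndarray  # (chains, draws, dim), unconstrained scale
    acceptance: float
    settings: MCMCSettings = field(default_factory=MCMCSettings)

    @property
    def flat(self) -> np.ndarray:
        return self.chain.reshape(-1, self.chain.shape[-1])


def find_map(
    log_prob_batched: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    maxiter: int = 300,
    fd_eps: float = 1e-6,
) -> np.ndarray:
    """MAP point via L-BFGS-B with forward-difference gradients.

    The gradient is computed with one batched call of shape (dim + 1, dim),
    exploiting the vectorised log density instead of scipy's serial
    finite differences.
    """
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    eye = np.eye(dim)

    def neg_lp_and_grad(x):
        h = fd_eps * np.maximum(1.0, np.abs(x))
        batch = np.vstack([x[None, :], x[None, :] + h * eye])
        vals = log_prob_batched(batch)
        f0 = vals[0]
        with np.errstate(invalid="ignore"):
            grad = (vals[1:] - f0) / h
        if not np.isfinite(f0):
            return 1e300, np.zeros(dim)
        grad = np.where(np.isfinite(grad), grad, 0.0)
        return -f0, -grad

    res = minimize(
        neg_lp_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "maxcor": 25},
    )
    return np.asarray(res.x, dtype=float)


def laplace_cov(
    log_prob_batched: Callable[[np.ndarray], np.ndarray],
    x_map: np.ndarray,
    fd_eps: float = 1e-4,
    grad_eps: float = 1e-5,
) -> np.ndarray:
    """Covariance of the Laplace (Gaussian) approximation at the MAP.

    The Hessian is assembled from batched central-difference gradients; it is
    symmetrised and its spectrum clipped away from zero so the result is
    always a usable positive-definite matrix even when the posterior has
    nearly flat directions.  Used only to give the ensemble a well-dispersed
    starting cloud — the sampler, not this Gaussian, produces the posterior.
    """
    x_map = np.asarray(x_map, dtype=float)
    dim = x_map.size
    eye = np.eye(dim)

    def grad(x):
        h = grad_eps * np.maximum(1.0, np.abs(x))
        batch = np.vstack([x[None, :] + h * eye, x[None, :] - h * eye])
        vals = log_prob_batched(batch)
        return (vals[:dim] - vals[dim:]) / (2.0 * h)

    h = fd_eps * np.maximum(1.0, np.abs(x_map))
    g0 = grad(x_map)
    hess = np.empty((dim, dim))
    for i in range(dim):
        xp = x_map.copy()
        xp[i] += h[i]
        hess[:, i] = (grad(xp) - g0) / h[i]
    hess = -(hess + hess.T) / 2.0
    hess = np.where(np.isfinite(hess), hess, 0.0)
    evals, evecs = np.linalg.eigh(hess)
    # precision floor: flat/negative directions get variance at most ~4
    floor = max(np.max(np.abs(evals)) * 1e-8, 0.25)
    evals = np.clip(evals, floor, None)
    return (evecs / evals) @ evecs.T


def _diag_hessian_cov(log_prob_batched, x_map, fd_eps: float = 1e-4) -> np.ndarray:
    """Diagonal-Hessian covariance: robust per-coordinate curvatures only."""
    x_map = np.asarray(x_map, dtype=float)
    dim = x_map.size
    h = fd_eps * np.maximum(1.0, np.abs(x_map))
    eye = np.eye(dim)
    batch = np.vstack([x_map[None, :], x_map[None, :] + h * eye, x_map[None, :] - h * eye])
    vals = log_prob_batched(batch)
    d2 = (vals[1 : dim + 1] + vals[dim + 1 :] - 2.0 * vals[0]) / h**2
    prec = np.where(np.isfinite(d2), -d2, 4e-2)
    prec = np.clip(prec, 4e-2, None)
    return np.diag(1.0 / prec)


def initial_cov(
    log_prob_batched: Callable[[np.ndarray], np.ndarray],
    x_map: np.ndarray,
    seed: int = 0,
    n_check: int = 16,
) -> np.ndarray:
    """Self-checking walker-initialisation covariance at the MAP.

    Tries the full Laplace covariance first; if draws from it fall implausibly
    far below the MAP density (a symptom of finite-difference noise on very
    sharp posteriors), falls back to the diagonal Hessian, then shrinks until
    the median log-density drop of test draws is of the order dim/2 expected
    for a Gaussian.  Only the *starting cloud* depends on this; the sampler
    determines the posterior.
    """
    x_map = np.asarray(x_map, dtype=float)
    dim = x_map.size
    rng = np.random.default_rng(seed)
    lp_map = float(log_prob_batched(x_map[None, :])[0])

    def median_drop(cov):
        chol = np.linalg.cholesky(cov + 1e-12 * np.trace(cov) / dim * np.eye(dim))
        draws = x_map[None, :] + rng.standard_normal((n_check, dim)) @ chol.T
        lps = log_prob_batched(draws)
        lps = np.where(np.isfinite(lps), lps, -np.inf)
        return lp_map - float(np.median(lps))

    budget = 2.0 * dim
    for base in (
        laplace_cov(log_prob_batched, x_map),
        _diag_hessian_cov(log_prob_batched, x_map),
    ):
        cov = base
        for _ in range(6):
            if median_drop(cov) <= budget:
                return cov
            cov = cov / 4.0
    return cov


def run_ensemble(
    log_prob_batched: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    settings: MCMCSettings,
    init_scale: float | np.ndarray = 1e-2,
    init_cov: Optional[np.ndarray] = None,
    extra_move: Optional[Callable[[np.ndarray, np.random.Generator], np.ndarray]] = None,
) -> EnsembleResult:
    """Sample with a DE/snooker move mixture and regroup into pseudo-chains.

    With ``init_cov`` (typically a Laplace covariance) the walkers start from
    a draw of N(x0, init_cov); otherwise from a ball of width ``init_scale``.
    ``extra_move`` is an optional model-specific Metropolis kernel (taking and
    returning walker coordinates, posterior-invariant) interleaved with the
    ensemble moves to handle geometry they traverse poorly.
    """
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    nwalkers = settings.walkers or max(2 * dim + 2, 8 * settings.chains)
    nwalkers += (-nwalkers) % (2 * settings.chains)  # even and divisible by chains
    rng = np.random.default_rng(settings.seed)

    scale = np.broadcast_to(np.asarray(init_scale, dtype=float), (dim,))
    if init_cov is not None:
        chol = np.linalg.cholesky(init_cov + 1e-12 * np.trace(init_cov) / dim * np.eye(dim))
        p0 = x0[None, :] + rng.standard_normal((nwalkers, dim)) @ chol.T
    else:
        p0 = x0[None, :] + scale[None, :] * rng.standard_normal((nwalkers, dim))
    lp0 = log_prob_batched(p0)
    bad = ~np.isfinite(lp0)
    tries = 0
    while np.any(bad) and tries < 50:
        n_bad = int(bad.sum())
        if init_cov is not None:
            shrink = 0.5 ** (tries + 1)
            p0[bad] = x0[None, :] + shrink * rng.standard_normal((n_bad, dim)) @ chol.T
        else:
            p0[bad] = x0[None, :] + 0.5 * scale[None, :] * rng.standard_normal((n_bad, dim))
        lp0 = log_prob_batched(p0)
        bad = ~np.isfinite(lp0)
        tries += 1
    if np.any(bad):
        raise RuntimeError("could not initialise all walkers at finite log density")

    # number of post-warmup ensemble steps so that chains*draws total are kept
    keep_steps = max(1, int(np.ceil(settings.draws * settings.chains / nwalkers))) * settings.thin

    def make_sampler(gamma, seed, beta=1.0):
        # scale both differential-evolution move families together
        rel = gamma / (2.38 / np.sqrt(2.0 * dim))
        lp = log_prob_batched if beta == 1.0 else (lambda x: beta * log_prob_batched(x))
        sampler = emcee.EnsembleSampler(
            nwalkers,
            dim,
            lp,
            vectorize=True,
            moves=[
                (emcee.moves.DEMove(gamma0=gamma), 0.8),
                (emcee.moves.DESnookerMove(gammas=1.7 * rel), 0.2),
            ],
        )
        # emcee inherits the *global* numpy random state by default; pin it so
        # a fit is a pure function of (data, settings.seed)
        sampler._random.seed(seed)
        return sampler

    # Warmup combines a tempering ramp with step-size adaptation: early blocks
    # sample a flattened density (beta < 1) so the walker cloud approaches the
    # posterior from an overdispersed state rather than expanding out of the
    # narrow Laplace ball, while the DE scale is tuned towards a ~25%
    # acceptance rate.  Both are frozen before any draws are retained.
    gamma = 2.38 / np.sqrt(2.0 * dim)
    n_blocks = 8
    # a tempering ramp only pays off when the warmup is long enough to both
    # explore the flattened density and re-equilibrate at beta = 1
    if settings.warmup >= 1500:
        betas = [0.3, 0.5, 0.7, 0.85, 1.0, 1.0, 1.0, 1.0]
    else:
        betas = [1.0] * n_blocks
    block = max(50, settings.warmup // n_blocks)
    move_rng = np.random.default_rng(settings.seed + 7)
    coords, used = p0, 0
    b = 0
    while used < settings.warmup:
        steps = min(block, settings.warmup - used)
        beta = betas[min(b, n_blocks - 1)]
        sampler = make_sampler(gamma, settings.seed + 1 + b, beta=beta)
        # pass bare coordinates: a cached log-prob from a different beta (or
        # sampler) must never be reused in the acceptance ratio
        state = sampler.run_mcmc(coords, steps, skip_initial_state_check=True)
        coords = state.coords
        if extra_move is not None and beta == 1.0:
            for _ in range(3):
                coords = extra_move(coords, move_rng)
        acc = float(np.mean(sampler.acceptance_fraction))
        if used + steps < settings.warmup:  # freeze for the final block
            gamma *= float(np.exp(1.5 * (acc - 0.25)))
            gamma = float(np.clip(gamma, 1e-3, 3.0))
        used += steps
        b += 1

    # retention, in chunks so the extra move keeps acting between them
    chunk = keep_steps if extra_move is None else max(2, settings.thin)
    pieces = []
    done = 0
    c = 0
    accs = []
    while done < keep_steps:
        steps = min(chunk, keep_steps - done)
        sampler = make_sampler(gamma, settings.seed + 1000 + c)
        state = sampler.run_mcmc(coords, steps, skip_initial_state_check=True)
        pieces.append(sampler.get_chain())
        accs.append(float(np.mean(sampler.acceptance_fraction)))
        coords = state.coords
        if extra_move is not None:
            coords = extra_move(coords, move_rng)
            pieces[-1][-1] = coords  # record the post-move positions
        done += steps
        c += 1
    full = np.concatenate(pieces, axis=0)  # (keep_steps, walkers, dim)
    raw = full[settings.thin - 1 :: settings.thin]

    # regroup: walkers split into `chains` groups; draws ordered step-major
    steps = raw.shape[0]
    per_chain_walkers = nwalkers // settings.chains
    grouped = raw.reshape(steps, settings.chains, per_chain_walkers, dim)
    chain = grouped.transpose(1, 0, 2, 3).reshape(settings.chains, steps * per_chain_walkers, dim)
    # trim to exactly `draws` per chain (keep the most recent draws)
    if chain.shape[1] > settings.draws:
        chain = chain[:, -settings.draws :, :]
    return EnsembleResult(
        chain=chain,
        acceptance=float(np.mean(accs)),
        settings=settings,
    )


def diagnostics_from_draws(draws: dict[str, np.ndarray]) -> dict:
    """R-hat, bulk/tail ESS per variable from (chains, draws, ...) arrays."""
    import arviz as az

    idata = az.from_dict(posterior=draws)
    rhat = az.rhat(idata)
    ess_bulk = az.ess(idata, method="bulk")
    ess_tail = az.ess(idata, method="tail")
    report = {}
    for name in draws:
        # constant draws (e.g. a fixed-radius ablation) yield NaN R-hat/ESS;
        # they carry no convergence information and are excluded
        with np.errstate(invalid="ignore"):
            r = np.atleast_1d(rhat[name].values).astype(float)
            eb = np.atleast_1d(ess_bulk[name].values).astype(float)
            et = np.atleast_1d(ess_tail[name].values).astype(float)
        report[name] = {
            "rhat": float(np.nanmax(r)) if np.any(np.isfinite(r)) else 1.0,
            "ess_bulk": float(np.nanmin(eb)) if np.any(np.isfinite(eb)) else float("nan"),
            "ess_tail": float(np.nanmin(et)) if np.any(np.isfinite(et)) else float("nan"),
        }
    report["max_rhat"] = max(v["rhat"] for k, v in report.items() if isinstance(v, dict))
    report["min_ess_bulk"] = np.nanmin(
        [v["ess_bulk"] for k, v in report.items() if isinstance(v, dict)]
    )
    return report


def convergence_flags(report: dict, rhat_threshold: float = 1.05) -> tuple[bool, list[str]]:
    warnings = []
    if report.get("max_rhat", 1.0) > rhat_threshold:
        warnings.append(f"max R-hat {report['max_rhat']:.3f} exceeds {rhat_threshold}")
    return (not warnings), warnings
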