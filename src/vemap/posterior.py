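"""Posterior products: field maps, cross-sections, population means, contrasts.

Grid prediction conditions each posterior draw's *latent* (pre-link) field on
that draw's latent values at the probe locations, samples the conditional
Gaussian at the grid nodes, and only then applies the link — transforming
after conditioning avoids the bias a nonlinear link would introduce if means
were transformed directly.  Heterogeneity and between-FOV-variability
contrasts are paired differences of condition-level kernel hyperparameters on
the link scale, summarised by their exceedance probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .links import phase_link, stiffness_link
from .spatial import SpatialPosterior

FIELD_KINDS = ("stiffness", "phase")
_KIND_KEY = {"stiffness": "g", "phase": "h"}


@dataclass
class FieldMap:
    """Gridded posterior mean and SD of one viscoelastic field."""

    x: np.ndarray  # (nx,) um
    y: np.ndarray  # (ny,) um
    mean: np.ndarray  # (ny, nx), Pa or rad
    sd: np.ndarray  # (ny, nx)
    kind: str
    fov_id: str


@dataclass
class CrossSection:
    coords: np.ndarray  # (n,) um along the chosen axis
    mean: np.ndarray
    lo: np.ndarray  # 2.5th percentile
    hi: np.ndarray  # 97.5th percentile
    kind: str
    axis: str
    at: float
    probe_projections: np.ndarray = field(default_factory=lambda: np.empty(0))
    probe_values: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ContrastResult:
    """Draws of a condition difference and its exceedance probability."""

    difference_draws: np.ndarray  # link-scale units
    probability_positive: float
    mean: float
    ci95: tuple

    @classmethod
    def from_draws(cls, draws: np.ndarray) -> "ContrastResult":
        draws = np.ravel(draws)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return cls(
            difference_draws=draws,
            probability_positive=float(np.mean(draws > 0)),
            mean=float(np.mean(draws)),
            ci95=(float(lo), float(hi)),
        )


def _kind_to_suffix(kind: str) -> str:
    if kind not in FIELD_KINDS:
        raise ValueError(f"kind must be one of {FIELD_KINDS}")
    return _KIND_KEY[kind]


def _linked_conditional_draws(
    posterior: SpatialPosterior,
    fov_id: str,
    points_um: np.ndarray,
    kind: str,
    max_draws: int = 400,
    seed: int = 0,
) -> np.ndarray:
    """(draws, n_points) samples of the linked field at arbitrary locations.

    For each retained posterior draw the latent GP is conditioned on that
    draw's latent values at the probe locations; the conditional at the
    requested points is sampled node-wise (marginal variances) and the link
    applied.  The kernel's white-noise term is treated as observation-side
    noise on the latents, not as part of the smooth field being mapped.
    """
    k = _kind_to_suffix(kind)
    j = posterior.fov_ids.index(fov_id)
    idx = posterior.probe_indices(fov_id)
    if idx.size == 0:
        raise ValueError(f"unknown or empty FOV {fov_id!r}")
    points = np.atleast_2d(np.asarray(points_um, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("empty prediction grid")

    rng = np.random.default_rng(seed)
    latent = posterior.flat(f"latent_{k}")[:, idx]
    alpha = posterior.flat(f"alpha_{k}")[:, j]
    ls = posterior.flat(f"l_{k}")[:, j, :]  # um
    mu = posterior.flat(f"mu_{k}")[:, j]
    sig2 = posterior.flat("sigma_sigma") ** 2
    n_total = latent.shape[0]
    if n_total > max_draws:
        sel = rng.choice(n_total, size=max_draws, replace=False)
        latent, alpha, ls, mu, sig2 = latent[sel], alpha[sel], ls[sel], mu[sel], sig2[sel]

    xp = posterior.locations_um[idx]  # (n, 2)
    d_pp = (xp[:, None, :] - xp[None, :, :]) ** 2  # (n, n, 2)
    d_gp = (points[:, None, :] - xp[None, :, :]) ** 2  # (m, n, 2)

    quad_pp = np.sum(d_pp[None] / (2.0 * ls[:, None, None, :] ** 2), axis=-1)
    kmat = alpha[:, None, None] ** 2 * np.exp(-quad_pp)
    kmat = kmat + (sig2[:, None, None] + 1e-9 * alpha[:, None, None] ** 2) * np.eye(xp.shape[0])
    quad_gp = np.sum(d_gp[None] / (2.0 * ls[:, None, None, :] ** 2), axis=-1)
    kstar = alpha[:, None, None] ** 2 * np.exp(-quad_gp)  # (D, m, n)

    sol = np.linalg.solve(kmat, latent[..., None])[..., 0]  # (D, n)
    cond_mean = np.einsum("dmn,dn->dm", kstar, sol)
    kinv_kstar = np.linalg.solve(kmat, kstar.transpose(0, 2, 1))  # (D, n, m)
    cond_var = alpha[:, None] ** 2 - np.einsum("dmn,dnm->dm", kstar, kinv_kstar)
    cond_var = np.clip(cond_var, 0.0, None)
    lat_draw = cond_mean + np.sqrt(cond_var) * rng.standard_normal(cond_mean.shape)
    if k == "g":
        return stiffness_link(lat_draw, mu[:, None])
    return phase_link(lat_draw, mu[:, None])


def predict_field(
    posterior: SpatialPosterior,
    fov_id: str,
    grid: Optional[tuple] = None,
    kind: str = "stiffness",
    n_grid: int = 50,
    max_draws: int = 400,
    seed: int = 0,
) -> FieldMap:
    """Gridded posterior mean and SD of the stiffness or phase field.

    ``grid`` is an optional (x_coords, y_coords) pair in um; by default a
    ``n_grid`` x ``n_grid`` lattice over the FOV's probe bounding box padded
    by the posterior-median length scale is used.
    """
    j = posterior.fov_ids.index(fov_id)
    idx = posterior.probe_indices(fov_id)
    if grid is None:
        k = _kind_to_suffix(kind)
        pad = float(np.median(posterior.flat(f"l_{k}")[:, j, :]))
        xp = posterior.locations_um[idx]
        x = np.linspace(xp[:, 0].min() - pad, xp[:, 0].max() + pad, n_grid)
        y = np.linspace(xp[:, 1].min() - pad, xp[:, 1].max() + pad, n_grid)
    else:
        x, y = np.asarray(grid[0], dtype=float), np.asarray(grid[1], dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty prediction grid")
    gx, gy = np.meshgrid(x, y)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    draws = _linked_conditional_draws(posterior, fov_id, pts, kind, max_draws, seed)
    return FieldMap(
        x=x,
        y=y,
        mean=draws.mean(axis=0).reshape(gy.shape),
        sd=draws.std(axis=0, ddof=1).reshape(gy.shape),
        kind=kind,
        fov_id=fov_id,
    )


def cross_section(
    posterior: SpatialPosterior,
    fov_id: str,
    axis: str = "x",
    at: Optional[float] = None,
    kind: str = "stiffness",
    n_points: int = 60,
    max_draws: int = 400,
    seed: int = 0,
) -> CrossSection:
    """1-D profile of the field along one axis with a 95% credible band.

    ``at`` fixes the off-axis coordinate (um); it defaults to the FOV centre.
    Probe locations are projected onto the section for annotation.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    idx = posterior.probe_indices(fov_id)
    xp = posterior.locations_um[idx]
    ax_i = 0 if axis == "x" else 1
    off_i = 1 - ax_i
    if at is None:
        at = float(xp[:, off_i].min() + xp[:, off_i].max()) / 2.0
    coords = np.linspace(xp[:, ax_i].min(), xp[:, ax_i].max(), n_points)
    pts = np.zeros((n_points, 2))
    pts[:, ax_i] = coords
    pts[:, off_i] = at
    draws = _linked_conditional_draws(posterior, fov_id, pts, kind, max_draws, seed)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    k = _kind_to_suffix(kind)
    probe_vals = posterior.flat(k)[:, idx].mean(axis=0)
    return CrossSection(
        coords=coords,
        mean=draws.mean(axis=0),
        lo=lo,
        hi=hi,
        kind=kind,
        axis=axis,
        at=at,
        probe_projections=xp[:, ax_i],
        probe_values=probe_vals,
    )


def population_means(posterior: SpatialPosterior, condition: str) -> dict:
    """Condition-level mean stiffness and phase, heterogeneity removed.

    The condition-level mean parameters are transformed draw-wise through the
    links; kernel amplitudes (within-FOV heterogeneity) and FOV-level
    variability are deliberately excluded so the summary reflects the
    material's average viscoelasticity alone.
    """
    if condition not in posterior.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    c = posterior.conditions.index(condition)
    g_draws = stiffness_link(posterior.flat("M_g")[:, c], 0.0)
    h_draws = phase_link(posterior.flat("M_h")[:, c], 0.0)

    def summarize(d):
        lo, hi = np.percentile(d, [2.5, 97.5])
        return {
            "mean": float(np.mean(d)),
            "sd": float(np.std(d, ddof=1)),
            "ci95": (float(lo), float(hi)),
            "draws": d,
        }

    return {"stiffness": summarize(g_draws), "phase": summarize(h_draws)}


def _condition_contrast(posterior, condition_a, condition_b, param_prefix):
    for cond in (condition_a, condition_b):
        if cond not in posterior.conditions:
            raise ValueError(f"unknown condition {cond!r}")
    a = posterior.conditions.index(condition_a)
    b = posterior.conditions.index(condition_b)
    out = {}
    for kind in FIELD_KINDS:
        k = _KIND_KEY[kind]
        draws = posterior.flat(f"{param_prefix}_{k}")
        out[kind] = ContrastResult.from_draws(draws[:, a] - draws[:, b])
    return out


def heterogeneity_contrast(
    posterior: SpatialPosterior, condition_a: str, condition_b: str
) -> dict:
    """Difference in average within-FOV heterogeneity (kernel amplitude mean).

    Paired draws of alpha_mu(A) - alpha_mu(B) per field kind, on the link
    scale; ``probability_positive`` is the fraction of positive draws.
    """
    return _condition_contrast(posterior, condition_a, condition_b, "alpha_mu")


def fov_variability_contrast(
    posterior: SpatialPosterior, condition_a: str, condition_b: str
) -> dict:
    """Difference in FOV-to-FOV variability of heterogeneity (alpha_sigma)."""
    return _condition_contrast(posterior, condition_a, condition_b, "alpha_sigma")


def exceedance_probability(draws_a, draws_b) -> float:
    """P(A > B): paired when lengths match, all-pairs average otherwise."""
    a = np.ravel(np.asarray(draws_a, dtype=float))
    b = np.ravel(np.asarray(draws_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("draw sets must be non-empty")
    if a.size == b.size:
        return float(np.mean(a > b))
    b_sorted = np.sort(b)
    counts = np.searchsorted(b_sorted, a, side="left")
    return float(np.mean(counts / b.size))
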