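"""Link functions and covariance kernels for the latent viscoelastic fields.

The stiffness field is kept positive through a softplus link and the phase
angle is confined to [0, pi/2] through arcsin(sigmoid(.)).  Both links and
their inverses are numerically stable over the full double range.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "softplus",
    "inv_softplus",
    "sigmoid",
    "stiffness_link",
    "inv_stiffness_link",
    "phase_link",
    "inv_phase_link",
    "exp_quad_cov",
    "chol_with_jitter",
]


def softplus(x):
    """ln(1 + exp(x)), stable for large |x|."""
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def inv_softplus(y):
    """Inverse of softplus: x = ln(exp(y) - 1), stable for large y."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("softplus output is strictly positive")
    # log(e^y - 1) = y + log(1 - e^-y)
    return y + np.log(-np.expm1(-y))


def sigmoid(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def stiffness_link(latent, mu):
    """Map latent + mean to a positive stiffness (Pa): softplus(latent + mu)."""
    return softplus(np.asarray(latent, dtype=float) + mu)


def inv_stiffness_link(gstar, mu):
    return inv_softplus(gstar) - mu


def phase_link(latent, mu):
    """Map latent + mean to a phase angle in (0, pi/2): arcsin(sigmoid(.))."""
    return np.arcsin(sigmoid(np.asarray(latent, dtype=float) + mu))


def inv_phase_link(phi, mu):
    phi = np.asarray(phi, dtype=float)
    s = np.sin(phi)
    if np.any((s <= 0) | (s >= 1)):
        raise ValueError("phase must lie strictly inside (0, pi/2)")
    return np.log(s) - np.log1p(-s) - mu


def exp_quad_cov(x, amplitude, length_scales, white_noise_sd=0.0):
    """Exponentiated-quadratic covariance with per-dimension length scales.

    K[i, j] = amplitude^2 * exp(-sum_d (x_id - x_jd)^2 / (2 l_d^2))
              + white_noise_sd^2 * 1[i == j]

    ``x`` is (n, d) in micrometres (or any consistent unit shared with the
    length scales).  Supports batched parameters: ``amplitude`` of shape (...,)
    and ``length_scales`` of shape (..., d) produce a (..., n, n) stack.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ValueError("coordinates must be finite")
    amplitude = np.asarray(amplitude, dtype=float)
    ls = np.asarray(length_scales, dtype=float)
    if ls.ndim == 0:
        ls = np.full(x.shape[1], float(ls))
    if np.any(amplitude <= 0) or np.any(ls <= 0):
        raise ValueError("kernel amplitude and length scales must be positive")
    diff = x[:, None, :] - x[None, :, :]  # (n, n, d)
    # (..., n, n) = sum over d of diff^2 / (2 l_d^2)
    quad = np.sum(diff[..., :, :, :] ** 2 / (2.0 * ls[..., None, None, :] ** 2), axis=-1)
    k = amplitude[..., None, None] ** 2 * np.exp(-quad)
    if np.any(np.asarray(white_noise_sd) != 0):
        wn = np.asarray(white_noise_sd, dtype=float) ** 2
        k = k + wn[..., None, None] * np.eye(x.shape[0])
    return k


def exp_quad_cross_cov(x1, x2, amplitude, length_scales):
    """Cross-covariance between two point sets (no white-noise term)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.ndim == 1:
        x1 = x1[:, None]
    if x2.ndim == 1:
        x2 = x2[:, None]
    amplitude = np.asarray(amplitude, dtype=float)
    ls = np.asarray(length_scales, dtype=float)
    if ls.ndim == 0:
        ls = np.full(x1.shape[1], float(ls))
    diff = x1[:, None, :] - x2[None, :, :]
    quad = np.sum(diff[..., :, :, :] ** 2 / (2.0 * ls[..., None, None, :] ** 2), axis=-1)
    return amplitude[..., None, None] ** 2 * np.exp(-quad)


def chol_with_jitter(k, max_tries: int = 6, rel_jitter: float = 1e-10):
    """Cholesky factor of a (stack of) covariance matrices, adding diagonal
    jitter geometrically up to 1e-6 times the mean diagonal if needed."""
    k = np.asarray(k, dtype=float)
    n = k.shape[-1]
    scale = float(np.mean(np.diagonal(k, axis1=-2, axis2=-1)))
    jitter = rel_jitter * scale
    for _ in range(max_tries):
        try:
            return np.linalg.cholesky(k + jitter * np.eye(n))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise np.linalg.LinAlgError(
        "covariance not positive definite even with jitter %.2e" % jitter
    )
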