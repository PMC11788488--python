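"""Log-density building blocks used by the hand-written posteriors.

All functions broadcast over leading (walker) axes and return unnormalised or
normalised log densities as noted.  Normalisation is kept wherever the
parameter it depends on is itself sampled (e.g. the GIG's dependence on its
scale hyperparameter), and dropped only where it is a true constant.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, kv

LOG_2PI = float(np.log(2.0 * np.pi))


def normal_logpdf(x, loc, scale):
    z = (np.asarray(x, dtype=float) - loc) / scale
    return -0.5 * z**2 - np.log(scale) - 0.5 * LOG_2PI


def halfnormal_logpdf(x, scale):
    """Half-normal on x > 0 (support not checked; use with log transforms)."""
    x = np.asarray(x, dtype=float)
    return 0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2


def invgamma_logpdf(x, alpha, beta):
    x = np.asarray(x, dtype=float)
    return alpha * np.log(beta) - gammaln(alpha) - (alpha + 1.0) * np.log(x) - beta / x


def studentt_logpdf(x, df, loc, scale):
    """Student-t log density; ``df`` may broadcast against ``x``."""
    z = (np.asarray(x, dtype=float) - loc) / scale
    df = np.asarray(df, dtype=float)
    return (
        gammaln((df + 1.0) / 2.0)
        - gammaln(df / 2.0)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
        - (df + 1.0) / 2.0 * np.log1p(z**2 / df)
    )


def studentt_prior_logpdf(x, df, loc, scale):
    """Alias for readability when a Student-t is used as a prior."""
    return studentt_logpdf(x, df, loc, scale)


def gig_logpdf(x, p, a, b):
    """Generalized inverse Gaussian log density, fully normalised.

    f(x) = (a/b)^{p/2} / (2 K_p(sqrt(ab))) x^{p-1} exp(-(a x + b/x)/2),
    x > 0.  The normaliser is kept because ``b`` is a sampled hyperparameter.
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    norm = 0.5 * p * (np.log(a) - np.log(b)) - np.log(2.0 * kv(p, np.sqrt(a * b)))
    return norm + (p - 1.0) * np.log(x) - 0.5 * (a * x + b / x)
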