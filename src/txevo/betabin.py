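"""Beta-binomial tail probabilities for allelic read counts.

Allele-specific read counts at a heterozygous SNP are overdispersed relative
to a binomial: technical and biological variation makes the per-site allelic
fraction itself random.  We model the major-allele count as

    X | q ~ Binomial(t, q),    q ~ Beta(alpha, beta)

parameterised by the mean allelic fraction ``p`` and the intra-class
correlation (overdispersion) ``rho``:

    alpha = p (1 - rho) / rho,    beta = (1 - p) (1 - rho) / rho

so that Var(X) = t p (1-p) (1 + (t-1) rho).  ``rho = 0`` degenerates
continuously to the plain binomial.  The cohort-level default used throughout
the ASE framework is ``rho = 0.05``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["betabin_params", "betabin_tail", "betabin_lower"]


def betabin_params(p: float, rho: float) -> tuple[float, float]:
    """Return the (alpha, beta) shape parameters for mean ``p`` and
    overdispersion ``rho`` (must satisfy 0 < p < 1 and 0 < rho < 1)."""
    return p * (1.0 - rho) / rho, (1.0 - p) * (1.0 - rho) / rho


def _validate(m, t, p, rho):
    m = np.asarray(m)
    t = np.asarray(t)
    if np.any(m < 0) or np.any(m > t):
        raise ValueError("require 0 <= m <= t")
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p must lie strictly inside (0, 1)")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    return m, t, p


def betabin_tail(m, t, p, rho: float = 0.05):
    """Upper-tail probability P(X >= m) of the beta-binomial.

    Parameters
    ----------
    m, t : int or array-like
        Observed count and number of trials (0 <= m <= t).
    p : float or array-like
        Mean allelic fraction, strictly inside (0, 1).
    rho : float
        Overdispersion; ``rho = 0`` gives the exact binomial tail.

    Returns
    -------
    float or ndarray
        Exact upper-tail probability; monotonically non-increasing in ``m``.
    """
    m, t, p = _validate(m, t, p, rho)
    if rho == 0.0:
        out = stats.binom.sf(m - 1, t, p)
    else:
        alpha, beta = betabin_params(p, rho)
        out = stats.betabinom.sf(m - 1, t, alpha, beta)
    return out if np.ndim(out) else float(out)


def betabin_lower(m, t, p, rho: float = 0.05):
    """Lower-tail probability P(X < m); complements :func:`betabin_tail`
    exactly: ``betabin_tail(m,...) + betabin_lower(m,...) == 1``."""
    m, t, p = _validate(m, t, p, rho)
    if rho == 0.0:
        out = stats.binom.cdf(m - 1, t, p)
    else:
        alpha, beta = betabin_params(p, rho)
        out = stats.betabinom.cdf(m - 1, t, alpha, beta)
    return out if np.ndim(out) else float(out)
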