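"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: the
beta-binomial oracle sums the pmf via the log-beta function, the distance
correlation oracle double-centres with explicit loops, and the hairpin
oracle enumerates base pairings one position at a time.
"""

import numpy as np
from scipy import special

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def betabin_pmf_oracle(k, t, p, rho):
    if rho == 0.0:
        return float(special.comb(t, k) * p ** k * (1 - p) ** (t - k))
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    log_pmf = (special.gammaln(t + 1) - special.gammaln(k + 1)
               - special.gammaln(t - k + 1)
               + special.betaln(k + a, t - k + b) - special.betaln(a, b))
    return float(np.exp(log_pmf))


def betabin_tail_oracle(m, t, p, rho):
    """P(X >= m) by direct summation of the pmf."""
    return sum(betabin_pmf_oracle(k, t, p, rho) for k in range(m, t + 1))


def betabin_tail_grid_oracle(t, p, rho):
    """P(X >= m) for every m in 0..t, by a reverse cumulative sum of the
    pmf (vectorised log-beta evaluation)."""
    k = np.arange(t + 1)
    if rho == 0.0:
        logpmf = (special.gammaln(t + 1) - special.gammaln(k + 1)
                  - special.gammaln(t - k + 1)
                  + k * np.log(p) + (t - k) * np.log1p(-p))
    else:
        a = p * (1 - rho) / rho
        b = (1 - p) * (1 - rho) / rho
        logpmf = (special.gammaln(t + 1) - special.gammaln(k + 1)
                  - special.gammaln(t - k + 1)
                  + special.betaln(k + a, t - k + b) - special.betaln(a, b))
    pmf = np.exp(logpmf)
    return np.cumsum(pmf[::-1])[::-1]


def dcor_oracle(x, y):
    """Distance correlation by explicit double-centring loops."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    a = np.zeros((n, n))
    b = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a[i, j] = abs(x[i] - x[j])
            b[i, j] = abs(y[i] - y[j])
    A = np.zeros((n, n))
    B = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = a[i, j] - a[i, :].mean() - a[:, j].mean() + a.mean()
            B[i, j] = b[i, j] - b[i, :].mean() - b[:, j].mean() + b.mean()
    dcov2 = (A * B).mean()
    vx = (A * A).mean()
    vy = (B * B).mean()
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(vx * vy)))


def hairpin_oracle(seq, offset, loop_range=(3, 5), min_stem=3):
    """Exhaustive pairing enumeration: for every candidate loop containing
    the variant, check position-by-position Watson-Crick pairing of the
    immediately flanking bases."""
    seq = seq.upper()
    n = len(seq)
    for loop_len in range(loop_range[0], loop_range[1] + 1):
        for start in range(0, n - loop_len + 1):
            end = start + loop_len
            if not (start <= offset < end):
                continue
            if start - min_stem < 0 or end + min_stem > n:
                continue
            paired = all(
                _COMPLEMENT.get(seq[start - 1 - j]) == seq[end + j]
                for j in range(min_stem))
            if paired:
                return True
    return False
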