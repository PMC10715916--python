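"""Numba-compiled inner loop of the asynchronous update dynamics.

The update rule is inherently sequential (a listener reads the messenger's
current, possibly already-updated-this-step opinion), so the hot loop is a
scalar kernel rather than vectorised numpy.  All randomness is drawn outside
the kernel (see :mod:`opinionet.dynamics` for the contract), which makes the
kernel a deterministic function of its inputs and lets a pure-Python
reference path consume the identical stream.

The diffusion solve exploits that the BTCS tridiagonal matrix is constant
within a run: the forward-elimination coefficients of the Thomas algorithm
are precomputed once, leaving two O(m) sweeps per solve.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["thomas_coefficients", "simulate_kernel"]


def thomas_coefficients(r: float, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Precompute Thomas-algorithm sweep coefficients for (I - r·L).

    The system has sub/super-diagonal ``-r`` and diagonal ``1 + 2r`` (zero
    Dirichlet ghost points).  Returns ``(cp, inv_denom)`` such that the
    forward sweep is ``dp[k] = (d[k] + r·dp[k-1]) · inv_denom[k]`` and the
    back substitution ``x[k] = dp[k] - cp[k]·x[k+1]``.
    """
    b0 = 1.0 + 2.0 * r
    cp = np.empty(m)
    inv_denom = np.empty(m)
    cp[0] = -r / b0
    inv_denom[0] = 1.0 / b0
    for k in range(1, m):
        denom = b0 + r * cp[k - 1]
        inv_denom[k] = 1.0 / denom
        cp[k] = -r / denom
    return cp, inv_denom


@njit(cache=True)
def simulate_kernel(
    x,  # (n, m) opinions, modified in place
    points,  # (m,) belief grid
    group,  # (n,) int8 identity labels
    indptr,  # (n+1,) CSR neighbour pointers
    indices,  # (E2,) CSR neighbour indices
    alpha_in,
    alpha_out,
    q,
    r,  # kappa / db^2
    cp,  # Thomas coefficients
    inv_denom,
    perms,  # (T, n) int32 visit order per step
    u_int,  # (T, n) interaction uniforms, by visit position
    u_nb,  # (T, n) neighbour-choice uniforms, by visit position
    sigma_cons,
    stop_at_consensus,
    sigma_out,  # (T+1,) written in place
    means_out,  # (n_records, n) written in place
    record_stride,
):
    """Run up to T asynchronous steps; returns (steps_done, consensus_step).

    ``consensus_step`` is the first step at which the population SD of mean
    opinions falls strictly below ``sigma_cons`` (-1 if never reached).
    """
    n, m = x.shape
    n_steps = perms.shape[0]
    uniform_mass = 1.0 / m

    means = np.empty(n)
    for i in range(n):
        s = 0.0
        for b in range(m):
            s += x[i, b] * points[b]
        means[i] = s

    mu = 0.0
    for i in range(n):
        mu += means[i]
    mu /= n
    var = 0.0
    for i in range(n):
        var += (means[i] - mu) ** 2
    sigma = np.sqrt(var / n)
    sigma_out[0] = sigma
    if means_out.shape[0] > 0:
        for i in range(n):
            means_out[0, i] = means[i]

    consensus_step = -1
    if sigma < sigma_cons:
        consensus_step = 0
        if stop_at_consensus:
            return 0, 0

    dp = np.empty(m)
    for t in range(n_steps):
        for pos in range(n):
            i = perms[t, pos]
            deg = indptr[i + 1] - indptr[i]
            if u_int[t, pos] < q and deg > 0:
                j = indices[indptr[i] + int(u_nb[t, pos] * deg)]
                alpha = alpha_in if group[i] == group[j] else alpha_out
                base = (1.0 - alpha) * uniform_mass
                s = 0.0
                for b in range(m):
                    v = x[i, b] * (alpha * x[j, b] + base)
                    x[i, b] = v
                    s += v
                inv = 1.0 / s
                mean = 0.0
                for b in range(m):
                    x[i, b] *= inv
                    mean += x[i, b] * points[b]
                means[i] = mean
            elif r > 0.0:
                dp[0] = x[i, 0] * inv_denom[0]
                for b in range(1, m):
                    dp[b] = (x[i, b] + r * dp[b - 1]) * inv_denom[b]
                v = dp[m - 1]
                x[i, m - 1] = v
                s = v
                for b in range(m - 2, -1, -1):
                    v = dp[b] - cp[b] * x[i, b + 1]
                    x[i, b] = v
                    s += v
                inv = 1.0 / s
                mean = 0.0
                for b in range(m):
                    x[i, b] *= inv
                    mean += x[i, b] * points[b]
                means[i] = mean
        mu = 0.0
        for i in range(n):
            mu += means[i]
        mu /= n
        var = 0.0
        for i in range(n):
            var += (means[i] - mu) ** 2
        sigma = np.sqrt(var / n)
        sigma_out[t + 1] = sigma
        if means_out.shape[0] > 0 and (t + 1) % record_stride == 0:
            row = (t + 1) // record_stride
            if row < means_out.shape[0]:
                for i in range(n):
                    means_out[row, i] = means[i]
        if consensus_step < 0 and sigma < sigma_cons:
            consensus_step = t + 1
            if stop_at_consensus:
                return t + 1, consensus_step
    return n_steps, consensus_step
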