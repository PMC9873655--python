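"""Hot likelihood kernels, JIT-compiled when numba is available.

Nested sampling spends essentially all of its time in these three functions
(tens of thousands of calls per fit), so they are written as fused loops and
compiled; the pure-numpy fallbacks compute identical values.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]

_LOG2PI = float(np.log(2 * np.pi))


@njit(cache=True, fastmath=True)
def fractal_loglike(logf, data, A, beta, gamma, kappa):
    """Gaussian log-likelihood of data against A f^-beta + gamma^2, var kappa*A."""
    n = data.size
    var = kappa * A
    lnA = np.log(A)
    g2 = gamma * gamma
    ss = 0.0
    for i in range(n):
        m = np.exp(lnA - beta * logf[i]) + g2
        r = data[i] - m
        ss += r * r
    return -0.5 * n * (_LOG2PI + np.log(var)) - ss / (2.0 * var)


@njit(cache=True, fastmath=True)
def arma_loglike(twopif, data, A, theta, phi, tau, kappa, as_printed):
    """Gaussian log-likelihood against the rational short-memory spectrum."""
    n = data.size
    var = kappa * A
    t2 = theta * theta
    p2 = phi * phi
    ss = 0.0
    for i in range(n):
        c = np.cos(twopif[i] * tau)
        num = 1.0 + 2.0 * theta * c + t2
        if as_printed:
            den = 1.0 - 2.0 * theta * c + p2
        else:
            den = 1.0 - 2.0 * phi * c + p2
        if den < 1e-12:
            den = 1e-12
        r = data[i] - A * num / den
        ss += r * r
    return -0.5 * n * (_LOG2PI + np.log(var)) - ss / (2.0 * var)


@njit(cache=True, fastmath=True)
def mixture_loglike(x, mus, sds, ws):
    """Log-likelihood of points under a normalized normal mixture."""
    nm = mus.size
    wsum = 0.0
    for k in range(nm):
        wsum += ws[k]
    total = 0.0
    for i in range(x.size):
        dens = 0.0
        for k in range(nm):
            z = (x[i] - mus[k]) / sds[k]
            dens += ws[k] / wsum * np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sds[k])
        if dens <= 0.0:
            return -1e300
        total += np.log(dens)
    return total
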