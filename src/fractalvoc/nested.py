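"""A compact static nested sampler.

Computes the Bayesian evidence Z = integral of L over the prior while
accumulating weighted posterior samples, using the classic scheme: maintain
``nlive`` live points drawn from the prior, repeatedly replace the
lowest-likelihood point with a new prior draw subject to L > L_worst, and
shrink the enclosed prior volume geometrically (ln X_i = -i / nlive).

New constrained draws come from rejection sampling inside the enlarged
bounding ellipsoid of the live points (the strategy behind multimodal
ellipsoidal samplers), with an adaptive random-walk fallback when the
ellipsoid becomes inefficient. Everything is driven by a single seeded
generator, so identical inputs and seed give identical output.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConvergenceError, DomainError

__all__ = ["NestedResult", "nested_sample"]


@dataclass
class NestedResult:
    """Output of one nested-sampling run.

    ``logwt`` are unnormalized ln(w_i L_i); subtracting ``logz`` gives
    normalized posterior log-weights.
    """

    samples_u: np.ndarray  # (n, ndim) unit-cube coordinates
    samples: np.ndarray  # (n, ndim) transformed parameters
    logl: np.ndarray  # (n,) log-likelihoods
    logwt: np.ndarray  # (n,) unnormalized posterior log-weights
    logz: float
    logzerr: float
    h: float  # information (KL divergence posterior || prior), nats
    niter: int
    ncall: int

    @property
    def weights(self) -> np.ndarray:
        """Normalized posterior weights."""
        w = np.exp(self.logwt - self.logwt.max())
        return w / w.sum()

    def ess(self) -> float:
        """Kish effective sample size of the weighted posterior."""
        w = self.weights
        return float(1.0 / np.sum(w**2))


def _logsubexp(a: float, b: float) -> float:
    """ln(e^a - e^b) for a > b."""
    return a + np.log1p(-np.exp(b - a))


class _Ellipsoid:
    """Enlarged bounding ellipsoid of a point cloud in the unit cube."""

    def __init__(self, points: np.ndarray, enlarge: float):
        n, ndim = points.shape
        self.mean = points.mean(axis=0)
        cov = np.cov(points.T) if ndim > 1 else np.atleast_2d(np.var(points))
        cov = np.atleast_2d(cov) + 1e-12 * np.eye(ndim)
        # scale so every point is inside, then enlarge
        try:
            inv = np.linalg.inv(cov)
            d = points - self.mean
            dmax2 = np.einsum("ij,jk,ik->i", d, inv, d).max()
        except np.linalg.LinAlgError:
            inv = None
            dmax2 = 1.0
        if not np.isfinite(dmax2) or dmax2 <= 0:
            dmax2 = 1.0
        self.chol = np.linalg.cholesky(cov * dmax2 * enlarge**2)
        self.ndim = ndim

    def sample_batch(self, rng: np.random.Generator, k: int) -> np.ndarray:
        """k points uniform in the ellipsoid (rows)."""
        z = rng.standard_normal((k, self.ndim))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        r = rng.uniform(size=(k, 1)) ** (1.0 / self.ndim)
        return self.mean + (z * r) @ self.chol.T


def _rwalk(
    u_start: np.ndarray,
    logl_star: float,
    loglike_u: Callable,
    live_std: np.ndarray,
    rng: np.random.Generator,
    steps: int = 25,
):
    """Metropolis random walk under the hard constraint L > L_star."""
    u = u_start.copy()
    logl = None
    scale = 1.0
    ncall = 0
    naccept = 0
    noise = rng.standard_normal((steps, u.size)) * live_std
    for i in range(steps):
        prop = u + scale * noise[i]
        if np.any(prop < 0) or np.any(prop > 1):
            scale *= 0.9
            continue
        ncall += 1
        ll = loglike_u(prop)
        if ll > logl_star:
            u, logl = prop, ll
            naccept += 1
            scale *= 1.1
        else:
            scale *= 0.9
    return u, logl, ncall, naccept


def nested_sample(
    loglike: Callable[[np.ndarray], float],
    prior_transform: Callable[[np.ndarray], np.ndarray],
    ndim: int,
    nlive: int = 400,
    dlogz: float = 0.1,
    seed: int | np.random.Generator = 0,
    max_iter: int = 500_000,
    enlarge: float = 1.25,
    update_interval: int | None = None,
) -> NestedResult:
    """Run static nested sampling.

    Parameters
    ----------
    loglike : callable
        Log-likelihood of a transformed parameter vector.
    prior_transform : callable
        Maps a unit-cube point to parameter space (must be the inverse CDF of
        the prior, applied per coordinate or jointly).
    ndim : int
        Dimensionality of the parameter space.
    nlive : int
        Number of live points; the evidence uncertainty scales as
        sqrt(H / nlive).
    dlogz : float
        Stop when the remaining prior volume can contribute less than this to
        ln Z.
    seed : int or numpy Generator
        Seed for all randomness in the run.
    max_iter : int
        Hard iteration cap; exceeding it raises :class:`ConvergenceError`
        carrying the partial state.
    enlarge : float
        Linear enlargement factor of the bounding ellipsoid.
    """
    if nlive < 2 * ndim:
        raise DomainError("nlive should be at least 2 * ndim")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def loglike_u(u: np.ndarray) -> float:
        return float(loglike(prior_transform(u)))

    live_u = rng.uniform(size=(nlive, ndim))
    live_logl = np.array([loglike_u(u) for u in live_u])
    ncall = nlive

    dead_u: list[np.ndarray] = []
    dead_logl: list[float] = []
    dead_logwt: list[float] = []

    logz = -np.inf
    h = 0.0
    logx_prev = 0.0
    ell: _Ellipsoid | None = None
    since_update = np.inf
    interval = update_interval or max(1, nlive // 5)
    eff_window = [1, 1]  # [accepts, likelihood calls] under the current ellipsoid
    use_rwalk = False  # fallback mode for multimodal/ridged constraint regions
    retry_at = 0  # iteration at which to retry the ellipsoid after a switch

    it = 0
    while True:
        it += 1
        if it > max_iter:
            raise ConvergenceError(
                f"nested sampling exceeded {max_iter} iterations",
                partial={"logz": logz, "niter": it - 1, "ncall": ncall},
            )
        worst = int(np.argmin(live_logl))
        logl_star = float(live_logl[worst])
        logx = -it / nlive
        logwt = _logsubexp(logx_prev, logx) + logl_star

        logz_new = np.logaddexp(logz, logwt)
        old_term = 0.0 if logz == -np.inf else np.exp(logz - logz_new) * (h + logz)
        h = np.exp(logwt - logz_new) * logl_star + old_term - logz_new
        logz = float(logz_new)

        dead_u.append(live_u[worst].copy())
        dead_logl.append(logl_star)
        dead_logwt.append(float(logwt))

        # draw the replacement: ellipsoid rejection, rwalk when inefficient
        if use_rwalk and it >= retry_at:
            use_rwalk = False  # periodically give the ellipsoid another chance
            ell = None
        if not use_rwalk and (since_update >= interval or ell is None):
            if eff_window[1] > 4 * interval and eff_window[0] / eff_window[1] < 0.05:
                # the bound leaks badly (ridged or multimodal region): walk
                use_rwalk = True
                retry_at = it + 5 * interval
            else:
                ell = _Ellipsoid(live_u, enlarge)
                since_update = 0
                eff_window = [0, 0]
        new_u = None
        new_logl = None
        if not use_rwalk:
            max_tries = 60
            tries = 0
            while tries < max_tries and new_u is None:
                batch = ell.sample_batch(rng, 10)
                ok = np.all((batch >= 0) & (batch <= 1), axis=1)
                for u, valid in zip(batch, ok):
                    tries += 1
                    if tries > max_tries:
                        break
                    if not valid:
                        continue
                    ncall += 1
                    eff_window[1] += 1
                    ll = loglike_u(u)
                    if ll > logl_star:
                        new_u, new_logl = u, ll
                        eff_window[0] += 1
                        break
        if new_u is None:
            # constraint region oddly shaped, or in rwalk mode: walk instead
            start = int(rng.integers(nlive))
            std = live_u.std(axis=0) * 2.38 / np.sqrt(ndim) + 1e-9
            u, ll, nc, nacc = _rwalk(live_u[start], logl_star, loglike_u, std, rng)
            ncall += nc
            if ll is None:
                # keep a copy of the start point; harmless duplication
                new_u, new_logl = live_u[start].copy(), float(live_logl[start])
            else:
                new_u, new_logl = u, ll
            if not use_rwalk:
                eff_window[1] += nc
                ell = None  # force a refresh next iteration
        live_u[worst] = new_u
        live_logl[worst] = new_logl
        since_update += 1
        logx_prev = logx

        remaining = float(np.max(live_logl)) + logx
        if np.logaddexp(logz, remaining) - logz < dlogz:
            break

    # sweep in the final live points, each carrying volume X_final / nlive
    logx_live = logx_prev - np.log(nlive)
    order = np.argsort(live_logl)
    for idx in order:
        logwt = logx_live + float(live_logl[idx])
        logz_new = np.logaddexp(logz, logwt)
        old_term = 0.0 if logz == -np.inf else np.exp(logz - logz_new) * (h + logz)
        h = np.exp(logwt - logz_new) * float(live_logl[idx]) + old_term - logz_new
        logz = float(logz_new)
        dead_u.append(live_u[idx].copy())
        dead_logl.append(float(live_logl[idx]))
        dead_logwt.append(float(logwt))

    samples_u = np.array(dead_u)
    samples = np.array([np.asarray(prior_transform(u), dtype=float) for u in samples_u])
    h = max(h, 0.0)
    return NestedResult(
        samples_u=samples_u,
        samples=samples,
        logl=np.array(dead_logl),
        logwt=np.array(dead_logwt),
        logz=logz,
        logzerr=float(np.sqrt(h / nlive)),
        h=float(h),
        niter=it,
        ncall=ncall,
    )
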