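"""Numerically stable ex-Gaussian distribution functions.

The ex-Gaussian law is the distribution of ``Z = X + Y`` where ``X`` is
Gaussian with location ``mu`` and spread ``sigma`` and ``Y`` is exponential
with mean ``tau``.  It is the standard model for positively skewed
reaction-time data: the Gaussian component captures transduction/motor
noise, the exponential component the decision tail.

Two parameterizations are supported:

* the canonical triple ``(mu, sigma, tau)`` (:class:`ExGParams`);
* the moment triple ``(M, S, K)`` — mean, standard deviation, skewness
  (:class:`ExGStats`) — linked through ``M = mu + tau``,
  ``S^2 = sigma^2 + tau^2`` and ``K = 2 (tau/S)^3``.

The asymmetry ``lamb = tau / S = (K/2)**(1/3)`` indexes the standardized
family (mean 0, variance 1) between the Gaussian (``lamb -> 0``) and
exponential (``lamb -> 1``) limits.

All densities are evaluated in log space through the scaled complementary
error function ``erfcx`` so that likelihoods stay finite for observations
far into either tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy import special

__all__ = [
    "ExGParams",
    "ExGStats",
    "SkewnessRangeError",
    "BracketError",
    "gauss_pdf",
    "gauss_cdf",
    "exg_pdf",
    "exg_log_pdf",
    "exg_cdf",
    "exg_lamb_pdf",
    "exg_lamb_cdf",
    "pars_to_stats",
    "stats_to_pars",
    "exg_quantile",
    "find_zero",
    "integrate",
]

_SQRT2 = math.sqrt(2.0)
_LOG2 = math.log(2.0)


class SkewnessRangeError(ValueError):
    """Moment triple has no ex-Gaussian representation (needs 0 < K < 2)."""


class BracketError(ValueError):
    """Root-finding bracket does not enclose a sign change."""


@dataclass(frozen=True)
class ExGParams:
    """Canonical ex-Gaussian parameters.

    Parameters
    ----------
    mu : float
        Location of the Gaussian component (ms).
    sigma : float
        Spread of the Gaussian component (ms); must be positive.
    tau : float
        Mean of the exponential component (ms); must be positive.

    Notes
    -----
    ``mu`` and ``sigma`` are *not* the mean and standard deviation of the
    distribution itself; see :func:`pars_to_stats`.  The degenerate limits
    ``sigma = 0`` (pure exponential) and ``tau = 0`` (pure Gaussian) are
    excluded: both make the density formula singular.
    """

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        for name in ("mu", "sigma", "tau"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.sigma <= 0:
            raise ValueError(
                f"sigma must be > 0, got {self.sigma!r} "
                "(sigma = 0 is the degenerate pure-exponential limit)"
            )
        if self.tau <= 0:
            raise ValueError(
                f"tau must be > 0, got {self.tau!r} "
                "(tau = 0 is the degenerate pure-Gaussian limit)"
            )

    @property
    def lamb(self) -> float:
        """Asymmetry ``tau / sqrt(sigma^2 + tau^2)``, strictly in (0, 1)."""
        return self.tau / math.hypot(self.sigma, self.tau)

    def __iter__(self) -> Iterator[float]:
        return iter((self.mu, self.sigma, self.tau))


@dataclass(frozen=True)
class ExGStats:
    """Moment description of an ex-Gaussian: mean, SD, skewness.

    ``K`` must lie strictly in (0, 2) for the triple to be representable
    by an :class:`ExGParams`; construction itself only requires ``S > 0``
    so that sample statistics outside the representable range can still
    be reported.
    """

    M: float
    S: float
    K: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(float(v)) for v in (self.M, self.S, self.K)):
            raise ValueError("M, S, K must all be finite")
        if self.S <= 0:
            raise ValueError(f"S must be > 0, got {self.S!r}")

    def __iter__(self) -> Iterator[float]:
        return iter((self.M, self.S, self.K))


def _as_params(params) -> ExGParams:
    if isinstance(params, ExGParams):
        return params
    return ExGParams(*params)


def gauss_pdf(x, mu: float, sigma: float):
    """Gaussian density with location `mu` and spread `sigma`."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma!r}")
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    out = np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))
    return out if out.ndim else float(out)


def gauss_cdf(x, mu: float, sigma: float):
    """Gaussian cumulative distribution P(X <= x)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma!r}")
    x = np.asarray(x, dtype=float)
    out = special.ndtr((x - mu) / sigma)
    return out if out.ndim else float(out)


def _log_erfc(u):
    """log(erfc(u)), stable for large positive u via erfcx."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    neg = u <= 0.0
    # erfc in (1, 2] on the negative side: direct evaluation is safe
    out[neg] = np.log(special.erfc(u[neg]))
    pos = ~neg
    out[pos] = np.log(special.erfcx(u[pos])) - u[pos] * u[pos]
    return out


def exg_log_pdf(x, params):
    """Log of the ex-Gaussian density; finite wherever the density is positive.

    Evaluated as ``-log(2 tau) + (mu - x)/tau + sigma^2/(2 tau^2)
    + log erfc(u)`` with ``u = ((mu - x)/sigma + sigma/tau)/sqrt(2)``,
    where ``log erfc`` goes through ``erfcx`` for positive arguments so the
    exp·erfc product never under- or overflows.
    """
    p = _as_params(params)
    x = np.asarray(x, dtype=float)
    u = ((p.mu - x) / p.sigma + p.sigma / p.tau) / _SQRT2
    out = (
        -_LOG2
        - math.log(p.tau)
        + (p.mu - x) / p.tau
        + p.sigma * p.sigma / (2.0 * p.tau * p.tau)
        + _log_erfc(u)
    )
    return out if out.ndim else float(out)


def exg_pdf(x, params):
    """Ex-Gaussian probability density."""
    out = np.exp(exg_log_pdf(x, params))
    return out if np.ndim(out) else float(out)


def exg_cdf(x, params):
    """Ex-Gaussian cumulative distribution P(Z <= x).

    Both terms are assembled in log space; the result is clipped to
    [0, 1] against rounding at the extreme tails.
    """
    p = _as_params(params)
    x = np.asarray(x, dtype=float)
    v = (x - p.mu) / (_SQRT2 * p.sigma)
    w = -v + p.sigma / (_SQRT2 * p.tau)
    expo = p.sigma * p.sigma / (2.0 * p.tau * p.tau) - (x - p.mu) / p.tau
    term2 = 0.5 * np.exp(expo + _log_erfc(w))
    out = np.clip(0.5 * special.erfc(-v) - term2, 0.0, 1.0)
    return out if out.ndim else float(out)


def _lamb_params(lamb: float) -> ExGParams:
    if not (0.0 < lamb < 1.0):
        raise ValueError(
            f"lamb must lie strictly in (0, 1), got {lamb!r}; "
            "lamb = 0 is the Gaussian limit (use gauss_pdf/gauss_cdf) and "
            "lamb = 1 the pure-exponential limit"
        )
    return ExGParams(mu=-lamb, sigma=math.sqrt(1.0 - lamb * lamb), tau=lamb)


def exg_lamb_pdf(z, lamb: float):
    """Standardized (mean 0, SD 1) ex-Gaussian density with asymmetry `lamb`.

    Obtained from :func:`exg_pdf` under the substitution ``mu = -lamb``,
    ``sigma = sqrt(1 - lamb^2)``, ``tau = lamb``.
    """
    return exg_pdf(z, _lamb_params(lamb))


def exg_lamb_cdf(z, lamb: float):
    """Standardized ex-Gaussian cumulative distribution with asymmetry `lamb`."""
    return exg_cdf(z, _lamb_params(lamb))


def pars_to_stats(params) -> ExGStats:
    """Convert canonical parameters to the moment triple (M, S, K)."""
    p = _as_params(params)
    S = math.hypot(p.sigma, p.tau)
    return ExGStats(M=p.mu + p.tau, S=S, K=2.0 * (p.tau / S) ** 3)


def stats_to_pars(stats) -> ExGParams:
    """Invert (M, S, K) to (mu, sigma, tau).

    Raises
    ------
    SkewnessRangeError
        If ``K`` is not strictly inside (0, 2): for ``K >= 2`` no real
        ``sigma`` exists, and ``K <= 0`` has no exponential component.
    """
    s = stats if isinstance(stats, ExGStats) else ExGStats(*stats)
    if not (0.0 < s.K < 2.0):
        raise SkewnessRangeError(
            f"skewness K={s.K!r} is outside (0, 2): no ex-Gaussian has "
            "these moments (K >= 2 would require a non-real sigma)"
        )
    lamb = (s.K / 2.0) ** (1.0 / 3.0)
    return ExGParams(
        mu=s.M - s.S * lamb,
        sigma=s.S * math.sqrt(1.0 - lamb * lamb),
        tau=s.S * lamb,
    )


def find_zero(
    fn: Callable[[float], float],
    bracket: Sequence[float],
    tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Find a root of `fn` inside `bracket` by bisection with secant steps.

    Deterministic and derivative-free.  Stops when ``|fn(root)| <= tol``
    or the bracket width falls to ``tol``.

    Raises
    ------
    BracketError
        If ``fn`` has the same (nonzero) sign at both ends.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError(f"bracket must satisfy lo < hi, got ({lo}, {hi})")
    flo, fhi = float(fn(lo)), float(fn(hi))
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0.0:
        raise BracketError(
            f"no sign change on [{lo}, {hi}]: fn endpoints {flo}, {fhi}"
        )
    for _ in range(max_iter):
        # secant proposal, fall back to midpoint when outside or stagnant
        denom = fhi - flo
        mid = 0.5 * (lo + hi)
        if denom != 0.0:
            c = hi - fhi * (hi - lo) / denom
            margin = 0.01 * (hi - lo)
            if not (lo + margin < c < hi - margin):
                c = mid
        else:
            c = mid
        fc = float(fn(c))
        if abs(fc) <= tol or (hi - lo) <= tol:
            return c
        if flo * fc < 0.0:
            hi, fhi = c, fc
        else:
            lo, flo = c, fc
    return 0.5 * (lo + hi)


def exg_quantile(p: float, params) -> float:
    """Inverse CDF: the x with ``exg_cdf(x) = p``.

    A right-tail point with tail area ``alpha`` is ``exg_quantile(1 - alpha)``.
    Solved by bracketed root finding on the CDF, starting from
    ``[M - 10 S, M + 20 S]`` and doubling the bracket outward when needed.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1), got {p!r}")
    prm = _as_params(params)
    st = pars_to_stats(prm)
    lo, hi = st.M - 10.0 * st.S, st.M + 20.0 * st.S

    def fn(x: float) -> float:
        return exg_cdf(x, prm) - p

    flo, fhi = fn(lo), fn(hi)
    width = hi - lo
    n_expand = 0
    while flo > 0.0 and n_expand < 60:  # target is left of the bracket
        lo -= width
        width *= 2.0
        flo = fn(lo)
        n_expand += 1
    while fhi < 0.0 and n_expand < 60:  # target is right of the bracket
        hi += width
        width *= 2.0
        fhi = fn(hi)
        n_expand += 1
    return find_zero(fn, (lo, hi), tol=1e-11)


@lru_cache(maxsize=16)
def _leggauss(order: int):
    return np.polynomial.legendre.leggauss(order)


def integrate(
    fn: Callable,
    a: float,
    b: float,
    order: int = 64,
    panels: int = 16,
) -> float:
    """Composite fixed-order Gauss-Legendre integral of `fn` over [a, b].

    Exact for polynomials up to degree ``2*order - 1`` on each panel.
    `fn` may be vectorized over a numpy array; scalar-only callables are
    handled by a fallback loop.
    """
    if not a < b:
        raise ValueError(f"integration bounds must satisfy a < b, got ({a}, {b})")
    if order < 1 or panels < 1:
        raise ValueError("order and panels must be positive")
    nodes, weights = _leggauss(int(order))
    edges = np.linspace(float(a), float(b), panels + 1)
    half = 0.5 * (edges[1:] - edges[:-1])  # (panels,)
    mid = 0.5 * (edges[1:] + edges[:-1])
    pts = mid[:, None] + half[:, None] * nodes[None, :]
    flat = pts.ravel()
    try:
        vals = np.asarray(fn(flat), dtype=float)
        if vals.shape != flat.shape:
            raise TypeError
    except (TypeError, ValueError):
        vals = np.array([float(fn(t)) for t in flat])
    vals = vals.reshape(pts.shape)
    return float(np.sum(half[:, None] * weights[None, :] * vals))
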