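"""Seeded random variate generation for the ex-Gaussian toolkit.

Every draw is a pure function of its arguments and an explicit seed or
:class:`RandomState`; there is no hidden global stream.  The underlying
generator is numpy's PCG64 (via ``numpy.random.default_rng``): Gaussian
draws use numpy's ziggurat transform, exponential draws use the inverse
transform ``-tau * log(1 - u)``.  Bit-level stream identity across numpy
versions is not guaranteed, but identical seeds always reproduce identical
samples within one environment, which is what the bootstrap and the test
fixtures rely on.
"""

from __future__ import annotations

import numpy as np

from .distcore import _as_params

__all__ = [
    "RandomState",
    "uniform_rv",
    "exponential_rv",
    "gaussian_rv",
    "exgauss_rv",
    "exgauss_sample",
]


class RandomState:
    """A seedable stream of random variates.

    Identical seeds yield identical variate sequences across runs.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self._rng = np.random.default_rng(self.seed)

    @property
    def generator(self) -> np.random.Generator:
        return self._rng

    def spawn_seeds(self, n: int, cap: int = 2**31 - 1) -> np.ndarray:
        """Derive `n` child seeds (below `cap`) for subordinate streams."""
        return self._rng.integers(0, cap, size=n)


def _coerce_state(state) -> RandomState:
    if isinstance(state, RandomState):
        return state
    return RandomState(state)


def uniform_rv(state: RandomState) -> float:
    """One draw from the open interval (0, 1)."""
    rng = _coerce_state(state).generator
    u = rng.random()
    while u <= 0.0:  # random() is in [0, 1); exclude the zero endpoint
        u = rng.random()
    return float(u)


def exponential_rv(tau: float, state: RandomState) -> float:
    """One exponential draw with mean (and SD) `tau`, by inverse transform."""
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau!r}")
    return -float(tau) * np.log(uniform_rv(state))


def gaussian_rv(mu: float, sigma: float, state: RandomState) -> float:
    """One Gaussian draw with location `mu` and spread `sigma`."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma!r}")
    rng = _coerce_state(state).generator
    return float(mu + sigma * rng.standard_normal())


def exgauss_rv(params, state: RandomState) -> float:
    """One ex-Gaussian draw: Gaussian plus exponential from the same stream."""
    p = _as_params(params)
    st = _coerce_state(state)
    return gaussian_rv(p.mu, p.sigma, st) + exponential_rv(p.tau, st)


def exgauss_sample(n: int, params, seed: int = 0) -> np.ndarray:
    """A reproducible sample of `n` independent ex-Gaussian draws.

    Fully determined by ``(n, params, seed)``.  The Gaussian block is
    drawn first, then the exponential block, so the whole sample comes
    from a single stream in a fixed order.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    p = _as_params(params)
    rng = np.random.default_rng(int(seed))
    gauss = p.mu + p.sigma * rng.standard_normal(n)
    expo = -p.tau * np.log1p(-rng.random(n))  # 1 - u in (0, 1]
    return gauss + expo
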