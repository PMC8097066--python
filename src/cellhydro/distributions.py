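"""Scission distributions and their class-ladder parameter maps.

Where along a chain a cleavage occurs is modelled by a probability density
over the jump distance down the class ladder.  Two families are used:

* Gauss — breaking is most likely near the middle of the chain
  (endo-type attack);
* Weibull — breaking is biased toward the chain ends (exo-type attack),
  with shape ``beta`` controlling whether the breaking rate falls
  (``beta < 1``), stays constant (``beta = 1``) or grows (``beta > 1``).

The parameter maps tie the distribution to the size of the admissible jump
support: a chain ``x`` steps down an ``N``-class ladder can jump to
``N - x`` lower classes.  With ``k = N + 1 - x``, the Gauss variance is
exactly that of a discrete uniform variable on ``1 .. k`` and the mean is
the midpoint ``k/2``; the Weibull scale and shape are affine in those two
moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDistributionError, DomainError


@dataclass(frozen=True)
class GaussParams:
    """Mean and standard deviation of the Gauss scission distribution."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DomainError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def degenerate(self) -> bool:
        """True when sigma = 0: the density collapses to a point mass at mu."""
        return self.sigma == 0.0


@dataclass(frozen=True)
class WeibullParams:
    """Scale (lam) and shape (beta) of the Weibull scission distribution."""

    lam: float
    beta: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise DomainError(f"lam must be > 0, got {self.lam}")
        if self.beta <= 0.5:
            raise DomainError(f"beta must be > 0.5, got {self.beta}")


def gauss_pdf(x, params: GaussParams):
    """Gauss density ``exp(-(x - mu)^2 / (2 sigma^2)) / (sigma sqrt(2 pi))``."""
    if params.degenerate:
        raise DegenerateDistributionError(
            "sigma = 0: use point-mass handling (density undefined)"
        )
    x = np.asarray(x, dtype=float)
    z = (x - params.mu) / params.sigma
    out = np.exp(-0.5 * z * z) / (params.sigma * math.sqrt(2.0 * math.pi))
    return out if out.ndim else float(out)


def weibull_pdf(x, params: WeibullParams):
    """Weibull density ``(beta/lam) (x/lam)^(beta-1) exp(-(x/lam)^beta)``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("Weibull density is defined for x >= 0 only")
    scalar = x.ndim == 0
    t = np.atleast_1d(x) / params.lam
    out = np.empty_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = (
        (params.beta / params.lam) * tp ** (params.beta - 1.0) * np.exp(-(tp**params.beta))
    )
    out[~pos] = (
        1.0 / params.lam if params.beta == 1.0 else (np.inf if params.beta < 1.0 else 0.0)
    )
    return float(out[0]) if scalar else out


def _uniform_support_moments(x: int, N: int) -> tuple[float, float]:
    # printed moment maps: mu = k/2 (midpoint of 0..k), var = (k^2 - 1)/12
    # (the variance of the discrete uniform on 1..k; the mean map sits 1/2 below it)
    if not 0 <= x <= N:
        raise DomainError(f"x must be in [0, {N}], got {x}")
    k = N + 1 - x
    mu = k / 2.0
    var = (k * k - 1) / 12.0
    return mu, var


def gauss_params_for(x: int, N: int) -> GaussParams:
    """Gauss parameters for support index ``x`` on an ``N``-class ladder.

    ``mu = (N + 1 - x)/2`` and ``sigma^2 = ((N + 1 - x)^2 - 1)/12``.  The
    variance is that of the discrete uniform on ``1 .. N + 1 - x``; the
    mean is the midpoint of ``0 .. N + 1 - x`` (half a unit below the
    uniform mean).  At ``x = N`` the variance vanishes and the returned
    parameters are flagged degenerate.
    """
    mu, var = _uniform_support_moments(x, N)
    return GaussParams(mu=mu, sigma=math.sqrt(var))


def weibull_params_for(x: int, N: int) -> WeibullParams:
    """Weibull parameters ``lam = 1.4 + mu/N``, ``beta = 0.95 + sigma^2/N``."""
    mu, var = _uniform_support_moments(x, N)
    return WeibullParams(lam=1.4 + mu / N, beta=0.95 + var / N)
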