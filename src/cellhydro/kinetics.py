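"""Homogeneous first-order reference kinetics of acid cellulose hydrolysis.

The classical pseudo-homogeneous scheme treats the hydrolysis as two
consecutive irreversible first-order reactions,

    cellulose (C) --k1--> glucose (G) --k2--> HMF,

with closed-form solutions

    c_C(t)   = c_C0 exp(-k1 t)
    c_G(t)   = c_C0 (k1 / (k2 - k1)) (exp(-k1 t) - exp(-k2 t))
    c_HMF(t) = c_C0 - c_C - c_G.

Rate constants follow Arrhenius laws with an acid-concentration factor,
``k = k0 (c_a/c_a,ref)^n exp(-EA/(R T))``.  For enzymatic hydrolysis the
rate constants of the enzyme-bound steps follow a Langmuir adsorption
isotherm, ``k = kmax c_E1 / (K_L + c_E1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .transition import R_GAS

#: Relative rate difference below which the equal-rate limit is used.
_EQUAL_RATE_RTOL = 1e-10


@dataclass(frozen=True)
class KineticParams:
    """Constants of the deterministic two-step scheme.

    Either supply ``k1``/``k2`` directly, or pre-exponentials and
    activation energies plus conditions and call :meth:`at`.
    """

    k10: float
    k20: float
    EA1: float
    EA2: float
    n1: float = 1.0
    n2: float = 1.0

    def at(self, T: float, c_a: float, c_a_ref: float) -> tuple[float, float]:
        """Evaluate (k1, k2) at temperature T (K) and acid concentration."""
        k1 = arrhenius_rate(self.k10, self.EA1, self.n1, c_a, c_a_ref, T)
        k2 = arrhenius_rate(self.k20, self.EA2, self.n2, c_a, c_a_ref, T)
        return k1, k2


@dataclass(frozen=True)
class EnzymeParams:
    """Langmuir-modulated first-order constants for enzymatic hydrolysis."""

    kmax1: float
    kmax3: float
    KL: float
    cE1: float
    k2_enz: float = 0.0

    @property
    def k1(self) -> float:
        return langmuir_rate_constant(self.kmax1, self.cE1, self.KL)

    @property
    def k3(self) -> float:
        return langmuir_rate_constant(self.kmax3, self.cE1, self.KL)


@dataclass(frozen=True)
class CGHTrajectory:
    """Concentration trajectories of the C -> G -> HMF scheme (g/L)."""

    times: np.ndarray
    c_C: np.ndarray
    c_G: np.ndarray
    c_HMF: np.ndarray

    def species(self, name: str) -> np.ndarray:
        try:
            return {"C": self.c_C, "G": self.c_G, "HMF": self.c_HMF}[name]
        except KeyError:
            raise DomainError(f"unknown species {name!r}; use C, G or HMF") from None


def glucose_closed_form(c_C0: float, k1: float, k2: float, tau):
    """Glucose concentration of the consecutive first-order scheme.

    Uses the standard solution with denominator ``k2 - k1`` (which keeps
    ``c_G >= 0`` for every rate ordering) and the limit
    ``c_C0 k1 tau exp(-k1 tau)`` when the two rates coincide.
    """
    if k1 < 0 or k2 < 0:
        raise DomainError("rate constants must be non-negative")
    tau = np.asarray(tau, dtype=float)
    if abs(k2 - k1) <= _EQUAL_RATE_RTOL * max(k1, k2, 1e-300):
        out = c_C0 * k1 * tau * np.exp(-k1 * tau)
    else:
        out = c_C0 * (k1 / (k2 - k1)) * (np.exp(-k1 * tau) - np.exp(-k2 * tau))
    return out if out.ndim else float(out)


def peak_glucose_time(k1: float, k2: float) -> float:
    """Time of maximum glucose, ``ln(k1/k2) / (k1 - k2)``."""
    if k1 <= 0 or k2 <= 0:
        raise DomainError("peak time requires strictly positive rates")
    if k1 == k2:
        return 1.0 / k1
    return float(np.log(k1 / k2) / (k1 - k2))


def simulate_cgh(
    c_C0: float, k1: float, k2: float, t_end: float, dt: float
) -> CGHTrajectory:
    """Closed-form C -> G -> HMF trajectories sampled on a uniform grid."""
    if dt <= 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    if t_end < 0:
        raise DomainError(f"t_end must be >= 0, got {t_end}")
    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    c_C = c_C0 * np.exp(-k1 * times)
    c_G = np.asarray(glucose_closed_form(c_C0, k1, k2, times))
    c_HMF = c_C0 - c_C - c_G
    return CGHTrajectory(times=times, c_C=c_C, c_G=c_G, c_HMF=c_HMF)


def arrhenius_rate(
    k0: float, EA: float, n: float, c_a: float, c_a_ref: float, T: float
) -> float:
    """``k = k0 (c_a/c_a,ref)^n exp(-EA/(R T))`` in 1/s."""
    if T <= 0:
        raise DomainError(f"temperature must be > 0 K, got {T}")
    if c_a_ref <= 0:
        raise DomainError("reference acid concentration must be > 0")
    return float(k0 * (c_a / c_a_ref) ** n * np.exp(-EA / (R_GAS * T)))


def langmuir_rate_constant(kmax: float, cE1: float, KL: float) -> float:
    """Enzyme-saturation rate constant ``kmax c_E1 / (K_L + c_E1)``."""
    if kmax < 0 or cE1 < 0 or KL < 0:
        raise DomainError("Langmuir inputs must be non-negative")
    if KL + cE1 == 0:
        raise DomainError("KL + cE1 must be > 0")
    return float(kmax * cE1 / (KL + cE1))
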