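"""Assembly of the per-step transition-probability matrix.

The hydrolysate population is tracked over molecular-mass classes
``0 .. N``; during one time step ``dt`` a chain in class ``i`` either
survives (diagonal entry) or cleaves and moves to a lighter class ``j > i``
(sub-diagonal entry).  Columns are source classes and rows destinations, so
the matrix is lower triangular with an absorbing terminal class
(``P[N, N] = 1``) and the state update is ``omega_new = P @ omega``.

Off-diagonal entries come from a scission distribution (Gauss or Weibull)
evaluated at the jump distance ``j - i``.  Two conventions are provided for
binding the distribution parameters to the ladder geometry (see
:class:`ArgConvention`).  Column normalization follows one of two modes:

* ``strict_paper`` — the source formulation: the ``(0, 0)`` entry is the
  constant ``1/(N+1)`` (Gauss) or ``3.5/(N+1)`` (Weibull), which leaves
  column 0 unnormalized; the deviation is recorded on the matrix.
* ``conservative`` (default for simulation) — the ``(0, 0)`` entry is
  recomputed as one minus the column-0 off-diagonal sum so that every
  column is stochastic and total mass is conserved.

Temperature and acid-concentration modulation multiplies the off-diagonal
breaking probabilities by ``g(c_a) = (c_a/c_a,ref)^n`` and an activation
factor ``h(T)``; a separate activation energy applies to the glucose→HMF
step (the ``(N, N-1)`` entry).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import IO

import numpy as np

from .distributions import (
    GaussParams,
    gauss_params_for,
    gauss_pdf,
    weibull_params_for,
    weibull_pdf,
)
from .errors import DomainError, NormalizationError
from .ladder import MassClassLadder

logger = logging.getLogger(__name__)

#: Gas constant, J/(mol K).
R_GAS = 8.314

_COLSUM_TOL = 1e-12


class Distribution(str, Enum):
    GAUSS = "gauss"
    WEIBULL = "weibull"


class ArgConvention(str, Enum):
    """How the scission-distribution parameters are bound to the ladder.

    ``source_class`` — parameters depend on the source class ``i`` (the
    admissible jumps from class ``i`` are ``1 .. N - i``); the density is
    then evaluated at the jump distance ``j - i``.  ``jump_distance`` —
    parameters are taken at ``x = j - i`` itself, which yields a single
    jump profile shared by all columns.
    """

    SOURCE_CLASS = "source_class"
    JUMP_DISTANCE = "jump_distance"


class NormalizationMode(str, Enum):
    STRICT_PAPER = "strict_paper"
    CONSERVATIVE = "conservative"


@dataclass(frozen=True)
class TransitionMatrix:
    """Per-step transition probabilities, columns = source classes."""

    P: np.ndarray
    N: int
    distribution: Distribution
    normalization_mode: NormalizationMode
    arg_convention: ArgConvention
    dt: float
    #: 1 - column-0 sum in strict_paper mode (0 for conservative matrices).
    column0_defect: float = 0.0
    mass_weighted: bool = False
    #: True when the terminal class is HMF fed only from the glucose class.
    hmf_channel: bool = False

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        if P.shape != (self.N + 1, self.N + 1):
            raise DomainError(
                f"matrix shape {P.shape} does not match N = {self.N}"
            )


@dataclass(frozen=True)
class TransitionFrequencies:
    """Off-diagonal transition rates ``alpha[j, i] = P[j, i] / dt`` in 1/s."""

    alpha: np.ndarray
    N: int
    dt: float
    distribution: Distribution = Distribution.GAUSS
    arg_convention: ArgConvention = ArgConvention.SOURCE_CLASS
    hmf_channel: bool = False

    def breaking_probability(self, i: int) -> float:
        return float(self.alpha[:, i].sum() * self.dt)


class ArrheniusSign(str, Enum):
    """Sign convention of the activation factor ``h(T)``.

    ``as_printed`` uses ``exp[+(E/R)(1/T - 1/T_ref)]`` exactly as the model
    states it; ``physical`` flips the exponent so that rates increase with
    temperature for positive activation energy, consistent with the
    Arrhenius form of the deterministic rate constants.
    """

    AS_PRINTED = "as_printed"
    PHYSICAL = "physical"


@dataclass(frozen=True)
class ProcessConditions:
    """Temperature / acid conditions modulating the transition frequencies."""

    T: float
    T_ref: float
    c_a: float
    c_a_ref: float
    acid_order: float = 1.0
    E_Am: float = 0.0
    E_AG: float = 0.0
    arrhenius_sign: ArrheniusSign = ArrheniusSign.AS_PRINTED

    def __post_init__(self) -> None:
        if self.T <= 0 or self.T_ref <= 0:
            raise DomainError("temperatures must be positive (K)")
        if self.c_a <= 0 or self.c_a_ref <= 0:
            raise DomainError("acid concentrations must be positive")


@dataclass(frozen=True)
class ModulationFactors:
    """Multiplicative factors applied to off-diagonal breaking probabilities."""

    g: float
    h_bulk: float
    h_G: float


def _pdf_for(distribution: Distribution, x, params) -> np.ndarray:
    if distribution is Distribution.GAUSS:
        if isinstance(params, GaussParams) and params.degenerate:
            # sigma = 0 limit: point mass at the mean
            x = np.asarray(x, dtype=float)
            return np.where(np.isclose(x, params.mu), 1.0, 0.0)
        return np.asarray(gauss_pdf(x, params), dtype=float)
    return np.asarray(weibull_pdf(x, params), dtype=float)


def _params_for(distribution: Distribution, x: int, N: int):
    if distribution is Distribution.GAUSS:
        return gauss_params_for(x, N)
    return weibull_params_for(x, N)


def _offdiag_column(
    N: int, i: int, distribution: Distribution, arg_convention: ArgConvention
) -> np.ndarray:
    """Breaking probabilities pp_ji for j = i+1 .. N from source class i."""
    jumps = np.arange(1, N - i + 1)
    if arg_convention is ArgConvention.SOURCE_CLASS:
        params = _params_for(distribution, i, N)
        return _pdf_for(distribution, jumps, params)
    return np.array(
        [
            float(_pdf_for(distribution, d, _params_for(distribution, int(d), N)))
            for d in jumps
        ]
    )


def corner_constant(distribution: Distribution, N: int) -> float:
    """The fixed ``(0, 0)`` entry of the strict formulation."""
    return (1.0 if Distribution(distribution) is Distribution.GAUSS else 3.5) / (N + 1)


def raw_breaking_sum(
    N: int,
    distribution: Distribution | str = Distribution.GAUSS,
    arg_convention: ArgConvention | str = ArgConvention.SOURCE_CLASS,
    i: int = 0,
    hmf_channel: bool = False,
) -> float:
    """Unscaled off-diagonal density sum of column ``i``.

    This is the raw breaking "probability" implied by the scission density
    before any scaling; it can exceed 1 for sharply peaked Weibull shapes
    at large ``N``, in which case :func:`build_matrix` needs a
    ``breaking_scale`` (or modulation factors) below ``1 / sum`` to yield a
    stochastic column.
    """
    pp = _offdiag_column(
        N, i, Distribution(distribution), ArgConvention(arg_convention)
    )
    if hmf_channel:
        pp = pp[:1] if i == N - 1 else pp[:-1]
    return float(pp.sum())


def build_matrix(
    N: int,
    distribution: Distribution | str = Distribution.GAUSS,
    arg_convention: ArgConvention | str = ArgConvention.SOURCE_CLASS,
    normalization_mode: NormalizationMode | str = NormalizationMode.CONSERVATIVE,
    dt: float = 100.0,
    breaking_scale: float = 1.0,
    hmf_channel: bool = False,
    factors: "ModulationFactors | None" = None,
) -> TransitionMatrix:
    """Assemble the ``(N+1) x (N+1)`` per-step transition matrix.

    Entry rules: ``P[N, N] = 1`` (absorbing); for ``0 < i < N`` the
    diagonal is ``1 - sum_j pp_ji``; off-diagonals ``j > i`` are the
    scission density at the jump distance, multiplied by
    ``breaking_scale`` (a uniform per-step rate factor, 1 by default; the
    modulated construction multiplies the density the same way).  Entries
    above the diagonal are zero.  The ``(0, 0)`` entry follows
    ``normalization_mode`` (see module docstring).  A column whose scaled
    off-diagonal sum exceeds 1 raises :class:`NormalizationError` — the
    step ``dt`` (or the scale) is then too large for a probability
    interpretation.

    With ``hmf_channel=True`` the terminal class is HMF and class ``N - 1``
    is glucose: scission moves chain mass only among classes ``0 .. N - 1``
    (destination row ``N`` is closed to chains, since HMF forms from
    glucose, not from cleavage), and the single glucose→HMF entry
    ``(N, N - 1)`` takes the jump-1 density of the glucose column.

    ``factors`` applies acid/temperature modulation during construction —
    the density is multiplied by ``g * h_bulk`` (``g * h_G`` on the
    ``(N, N - 1)`` entry) before normalization, exactly as the modulated
    formulation writes its branches.  This also makes large-``N`` Weibull
    matrices constructible when ``g * h < 1`` even though the raw density
    sum exceeds 1.
    """
    distribution = Distribution(distribution)
    arg_convention = ArgConvention(arg_convention)
    normalization_mode = NormalizationMode(normalization_mode)
    if N < 1:
        raise DomainError(f"N must be >= 1, got {N}")
    if dt <= 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    if breaking_scale <= 0:
        raise DomainError(f"breaking_scale must be > 0, got {breaking_scale}")

    if hmf_channel and N < 2:
        raise DomainError("hmf_channel needs at least one chain class (N >= 2)")

    P = np.zeros((N + 1, N + 1))
    P[N, N] = 1.0
    for i in range(N):
        pp = breaking_scale * _offdiag_column(N, i, distribution, arg_convention)
        if hmf_channel:
            if i == N - 1:
                pp = pp[:1]  # glucose -> HMF, the only entry reaching row N
            else:
                pp = pp[:-1]  # chains never jump past the glucose row N - 1
        if factors is not None:
            pp = pp * (factors.g * factors.h_bulk)
            if i == N - 1 and pp.size:
                # column N-1's single off-diagonal is the (N, N-1) entry
                pp[-1] *= factors.h_G / factors.h_bulk
        s = pp.sum()
        if s > 1.0 + _COLSUM_TOL:
            raise NormalizationError(
                f"off-diagonal probabilities of column {i} sum to {s:.6f} > 1"
            )
        P[i + 1 : i + 1 + pp.size, i] = pp
        P[i, i] = diag_from_column(pp)

    defect = 0.0
    if normalization_mode is NormalizationMode.STRICT_PAPER:
        P[0, 0] = corner_constant(distribution, N)
        defect = 1.0 - P[:, 0].sum()
        if abs(defect) > _COLSUM_TOL:
            logger.warning(
                "strict_paper mode: column 0 sums to %.6f (defect %.3e)",
                P[:, 0].sum(),
                defect,
            )
    return TransitionMatrix(
        P=P,
        N=N,
        distribution=distribution,
        normalization_mode=normalization_mode,
        arg_convention=arg_convention,
        dt=dt,
        column0_defect=defect,
        hmf_channel=hmf_channel,
    )


def diag_from_column(subdiagonal_entries) -> float:
    """Survival probability ``1 - sum`` of a column's breaking probabilities."""
    entries = np.asarray(list(subdiagonal_entries), dtype=float)
    if entries.size == 0:
        return 1.0
    if np.any(entries < 0) or np.any(entries > 1):
        raise DomainError("breaking probabilities must lie in [0, 1]")
    s = float(entries.sum())
    if s > 1.0 + _COLSUM_TOL:
        raise NormalizationError(f"column off-diagonal sum {s:.6f} exceeds 1")
    return 1.0 - s


def breaking_probability(P: TransitionMatrix, i: int) -> float:
    """Probability that a class-``i`` chain cleaves during one step."""
    if not 0 <= i <= P.N:
        raise DomainError(f"class index {i} out of range [0, {P.N}]")
    col = P.P[:, i]
    return float(col.sum() - col[i])


def frequencies_from_matrix(
    P: TransitionMatrix, dt: float | None = None
) -> TransitionFrequencies:
    """Convert off-diagonal per-step probabilities to rates ``P/dt``."""
    dt = P.dt if dt is None else dt
    if dt <= 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    alpha = P.P / dt
    np.fill_diagonal(alpha, 0.0)
    alpha[P.N, P.N] = 0.0  # absorbing self-transition is not a rate
    return TransitionFrequencies(
        alpha=alpha,
        N=P.N,
        dt=dt,
        distribution=P.distribution,
        arg_convention=P.arg_convention,
        hmf_channel=P.hmf_channel,
    )


def mass_weight(
    alpha: TransitionFrequencies, ladder: MassClassLadder
) -> TransitionMatrix:
    """Re-proportion each column by destination molar mass (mass units).

    The state vector tracks mass fractions, so within column ``i`` the
    off-diagonal weights are ``M_j * alpha[j, i]`` normalized among
    themselves and rescaled to the column's breaking probability ``p_i``;
    the diagonal stays ``1 - p_i``.  This keeps the survival probability of
    the unweighted matrix while distributing the broken mass in the
    mass-weighted proportions.
    """
    N = alpha.N
    if ladder.N != N:
        raise DomainError(
            f"ladder has N = {ladder.N} but frequencies have N = {N}"
        )
    M = np.asarray(ladder.masses, dtype=float)
    Pm = np.zeros((N + 1, N + 1))
    Pm[N, N] = 1.0
    for i in range(N):
        a = alpha.alpha[i + 1 :, i]
        p_i = float(a.sum() * alpha.dt)
        w = M[i + 1 :] * a
        ws = w.sum()
        if ws == 0.0:
            if p_i > 0.0:
                raise NormalizationError(
                    f"column {i}: zero mass-weighted flux but p_i = {p_i}"
                )
            Pm[i, i] = 1.0
            continue
        Pm[i + 1 :, i] = p_i * w / ws
        Pm[i, i] = 1.0 - p_i
    return TransitionMatrix(
        P=Pm,
        N=N,
        distribution=alpha.distribution,
        normalization_mode=NormalizationMode.CONSERVATIVE,
        arg_convention=alpha.arg_convention,
        dt=alpha.dt,
        mass_weighted=True,
        hmf_channel=alpha.hmf_channel,
    )


def modulation(conditions: ProcessConditions) -> ModulationFactors:
    """Acid factor ``g`` and temperature factors ``h_bulk`` / ``h_G``.

    ``g = (c_a/c_a,ref)^n``; ``h = exp[(E/R)(1/T - 1/T_ref)]`` with the sign
    governed by ``conditions.arrhenius_sign``.
    """
    g = (conditions.c_a / conditions.c_a_ref) ** conditions.acid_order
    dinv = 1.0 / conditions.T - 1.0 / conditions.T_ref
    sign = 1.0 if conditions.arrhenius_sign is ArrheniusSign.AS_PRINTED else -1.0
    h_bulk = float(np.exp(sign * conditions.E_Am / R_GAS * dinv))
    h_G = float(np.exp(sign * conditions.E_AG / R_GAS * dinv))
    return ModulationFactors(g=float(g), h_bulk=h_bulk, h_G=h_G)


def _renormalize(
    P: np.ndarray,
    N: int,
    distribution: Distribution,
    normalization_mode: NormalizationMode,
) -> float:
    """Recompute diagonals from off-diagonal column sums in place.

    Returns the column-0 defect (nonzero only in strict_paper mode).
    """
    for i in range(N):
        off = P[i + 1 :, i].sum()
        if off > 1.0 + _COLSUM_TOL:
            raise NormalizationError(
                f"modulated column {i} off-diagonal sum {off:.6f} > 1; "
                "use a smaller time step dt"
            )
        P[i, i] = 1.0 - off
    P[N, N] = 1.0
    defect = 0.0
    if normalization_mode is NormalizationMode.STRICT_PAPER:
        P[0, 0] = corner_constant(distribution, N)
        defect = 1.0 - P[:, 0].sum()
    return defect


def apply_modulation(
    P: TransitionMatrix,
    factors: ModulationFactors,
    normalization_mode: NormalizationMode | str | None = None,
) -> TransitionMatrix:
    """Scale off-diagonal breaking probabilities by ``g * h``.

    The glucose→HMF entry ``(N, N-1)`` uses ``h_G``; every other
    off-diagonal uses ``h_bulk``.  Diagonals are recomputed so the matrix
    stays normalized in its (possibly overridden) normalization mode.
    """
    mode = (
        P.normalization_mode
        if normalization_mode is None
        else NormalizationMode(normalization_mode)
    )
    N = P.N
    newP = P.P.copy()
    off_mask = np.tril(np.ones((N + 1, N + 1), dtype=bool), k=-1)
    newP[off_mask] *= factors.g * factors.h_bulk
    if N >= 1:
        # the glucose -> HMF channel carries its own activation energy
        newP[N, N - 1] *= factors.h_G / factors.h_bulk
    defect = _renormalize(newP, N, P.distribution, mode)
    return replace(
        P, P=newP, normalization_mode=mode, column0_defect=defect
    )


def scale_breaking(P: TransitionMatrix, s: float) -> TransitionMatrix:
    """Uniformly scale every off-diagonal breaking probability by ``s > 0``."""
    if s <= 0:
        raise DomainError(f"scale must be > 0, got {s}")
    return apply_modulation(P, ModulationFactors(g=s, h_bulk=1.0, h_G=1.0))


def matrix_to_csv(P: TransitionMatrix, handle: IO[str]) -> None:
    """Write the matrix row-major with a metadata header line."""
    handle.write(
        f"# N={P.N},distribution={P.distribution.value},"
        f"mode={P.normalization_mode.value},arg={P.arg_convention.value},"
        f"dt={P.dt:.17g},mass_weighted={int(P.mass_weighted)},"
        f"hmf_channel={int(P.hmf_channel)}\n"
    )
    writer = csv.writer(handle)
    for row in P.P:
        writer.writerow([f"{v:.17g}" for v in row])


def matrix_from_csv(handle: IO[str]) -> TransitionMatrix:
    header = handle.readline()
    if not header.startswith("# "):
        raise DomainError("missing matrix metadata header")
    meta = dict(kv.split("=", 1) for kv in header[2:].strip().split(","))
    rows = [[float(v) for v in row] for row in csv.reader(handle) if row]
    return TransitionMatrix(
        P=np.array(rows),
        N=int(meta["N"]),
        distribution=Distribution(meta["distribution"]),
        normalization_mode=NormalizationMode(meta["mode"]),
        arg_convention=ArgConvention(meta["arg"]),
        dt=float(meta["dt"]),
        mass_weighted=bool(int(meta.get("mass_weighted", "0"))),
        hmf_channel=bool(int(meta.get("hmf_channel", "0"))),
    )


def load_printed_n10_matrix() -> np.ndarray:
    """The published 11x11 worked-example matrix, transcribed verbatim.

    Shipped for structural regression only: the printed entries are not
    reproducible from the stated construction rules (see the fixture file
    header), so it serves consistency checks, never as an oracle for
    :func:`build_matrix`.
    """
    from importlib.resources import files

    text = files("cellhydro.fixtures").joinpath("eq24_gauss_N10.csv").read_text()
    rows = [
        [float(v) for v in line.split(",")]
        for line in text.splitlines()
        if line and not line.startswith("#")
    ]
    return np.array(rows)
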