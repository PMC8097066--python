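"""Agreement metrics between stochastic and deterministic trajectories.

The stochastic chain resolves every molecular-mass class, the deterministic
scheme only cellulose, glucose and HMF; they are compared on the species
both resolve.  By default the glucose class (``N - 1`` in the
glucose-then-HMF layout) is paired with deterministic ``c_G`` and the
terminal class ``N`` with ``c_HMF``.

Agreement is quantified per species by the root-mean-square error (RMSE,
g/L) and a coefficient of variation CV = RMSE / mean of the reference
(deterministic) series; the exact CV normalization is recorded in the
report so alternatives can be swapped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO, Mapping

import numpy as np

from .dynamics import StateTrajectory
from .errors import DomainError
from .kinetics import CGHTrajectory

#: Relative tolerance used when intersecting time grids.
_GRID_RTOL = 1e-9


def rmse(a, b) -> float:
    """Root-mean-square difference of two equally sampled series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DomainError(f"series lengths differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise DomainError("need at least 2 samples")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def coefficient_of_variation(a, b) -> float:
    """RMSE of ``a`` against reference ``b``, normalized by ``mean(b)``."""
    b = np.asarray(b, dtype=float)
    m = float(np.mean(b))
    if m == 0.0:
        raise DomainError("reference series has zero mean; CV undefined")
    return rmse(a, b) / m


@dataclass(frozen=True)
class AgreementReport:
    """Per-species RMSE / CV plus their maxima over the mapped species."""

    rmse: dict[str, float]
    cv: dict[str, float]
    mapping: dict[int, str]
    n_points: int
    cv_definition: str = "rmse_over_reference_mean"

    @property
    def max_rmse(self) -> float:
        return max(self.rmse.values())

    @property
    def max_cv(self) -> float:
        return max(self.cv.values())

    def to_json(self, handle: IO[str] | None = None) -> str:
        payload = {
            "species": sorted(self.rmse),
            "rmse_g_per_L": self.rmse,
            "cv": self.cv,
            "max_rmse_g_per_L": self.max_rmse,
            "max_cv": self.max_cv,
            "mapping": {str(k): v for k, v in self.mapping.items()},
            "n_points": self.n_points,
            "cv_definition": self.cv_definition,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if handle is not None:
            handle.write(text)
        return text


def _align(
    t_a: np.ndarray, t_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Common evaluation times plus index maps (restriction to coarser grid)."""
    da = np.median(np.diff(t_a)) if t_a.size > 1 else np.inf
    db = np.median(np.diff(t_b)) if t_b.size > 1 else np.inf
    coarse = t_a if da >= db else t_b
    tol = _GRID_RTOL * max(abs(coarse[-1]), 1.0)
    ia, ib, keep = [], [], []
    for t in coarse:
        ja = np.argmin(np.abs(t_a - t))
        jb = np.argmin(np.abs(t_b - t))
        if abs(t_a[ja] - t) <= tol and abs(t_b[jb] - t) <= tol:
            ia.append(ja)
            ib.append(jb)
            keep.append(t)
    if len(keep) < 2:
        raise DomainError("trajectories share fewer than 2 time points")
    return np.array(keep), np.array(ia), np.array(ib)


def compare_models(
    stochastic: StateTrajectory,
    deterministic: CGHTrajectory,
    mapping: Mapping[int, str] | None = None,
    interpolate: bool = False,
) -> AgreementReport:
    """Compare stochastic class concentrations with deterministic species.

    ``mapping`` pairs stochastic class indices with species names
    ("C", "G", "HMF"); the default pairs class ``N - 1`` with glucose and
    class ``N`` with HMF.  Series are compared on the intersection of the
    two time grids (restricted to the coarser one, no interpolation).
    """
    if stochastic.concentrations is None:
        raise DomainError(
            "stochastic trajectory carries no concentrations; simulate with c_C0"
        )
    if mapping is None:
        mapping = {stochastic.N - 1: "G", stochastic.N: "HMF"}
    mapping = dict(mapping)
    if interpolate:
        # evaluate the deterministic closed forms on the stochastic grid
        times = stochastic.times
        ia = np.arange(times.size)
        ib = None
    else:
        times, ia, ib = _align(stochastic.times, deterministic.times)
    rmse_by: dict[str, float] = {}
    cv_by: dict[str, float] = {}
    for cls, name in mapping.items():
        a = stochastic.concentrations[ia, cls]
        det = deterministic.species(name)
        b = np.interp(times, deterministic.times, det) if ib is None else det[ib]
        rmse_by[name] = rmse(a, b)
        cv_by[name] = coefficient_of_variation(a, b)
    return AgreementReport(
        rmse=rmse_by, cv=cv_by, mapping=mapping, n_points=len(times)
    )
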