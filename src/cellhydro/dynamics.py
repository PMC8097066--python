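"""Time evolution of the class mass-fraction vector.

The state is the vector of mass fractions ``omega_i`` (dimensionless, on an
anhydro-mass basis, so it sums to 1 like a probability vector).  Two
evolution paths are provided and must agree to first order in the step:

* a discrete-time Markov update ``omega(t + dt) = P @ omega(t)``;
* the continuous-time mass balance
  ``d omega_i/dt = sum_h alpha_ih omega_h - omega_i sum_j alpha_ji``
  with rates ``alpha = P_offdiag / dt``, integrated with fixed-step
  classical Runge-Kutta (RK4).

Concentrations are recovered as ``c_i = omega_i * c_C0`` (g/L) for an
initial suspension concentration ``c_C0``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import IO

import numpy as np

from .errors import DomainError
from .transition import TransitionMatrix

__all__ = [
    "StateVector",
    "StateTrajectory",
    "initial_state",
    "step",
    "simulate",
    "ode_rhs",
    "simulate_ode",
    "trajectory_to_csv",
    "trajectory_from_csv",
]


@dataclass(frozen=True)
class StateVector:
    """Mass fractions over the N+1 classes at one time point."""

    omega: np.ndarray
    tau: float = 0.0
    step_index: int = 0

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "omega", omega)
        if np.any(omega < -1e-12):
            raise DomainError("mass fractions must be non-negative")


@dataclass(frozen=True)
class StateTrajectory:
    """Sampled states on a uniform time grid.

    ``states[n, i]`` is the mass fraction of class ``i`` at ``times[n]``;
    ``concentrations`` (g/L) is ``states * c_C0`` when an initial
    suspension concentration was supplied.
    """

    times: np.ndarray
    states: np.ndarray
    concentrations: np.ndarray | None = None

    @property
    def N(self) -> int:
        return self.states.shape[1] - 1

    def class_series(self, i: int, concentration: bool = False) -> np.ndarray:
        data = self.concentrations if concentration else self.states
        if data is None:
            raise DomainError("trajectory has no concentrations (c_C0 not given)")
        return data[:, i]


def initial_state(N: int) -> StateVector:
    """All mass in the intact-chain class 0: ``omega = [1, 0, ..., 0]``."""
    if N < 1:
        raise DomainError(f"N must be >= 1, got {N}")
    omega = np.zeros(N + 1)
    omega[0] = 1.0
    return StateVector(omega=omega, tau=0.0, step_index=0)


def step(state: StateVector, P: TransitionMatrix) -> StateVector:
    """One discrete Markov update ``omega <- P @ omega``."""
    if state.omega.shape[0] != P.N + 1:
        raise DomainError(
            f"state has {state.omega.shape[0]} classes, matrix expects {P.N + 1}"
        )
    return StateVector(
        omega=P.P @ state.omega,
        tau=state.tau + P.dt,
        step_index=state.step_index + 1,
    )


def simulate(
    P: TransitionMatrix, n_steps: int, c_C0: float | None = None
) -> StateTrajectory:
    """Run ``n_steps`` discrete updates from the intact-chain initial state."""
    if n_steps < 0:
        raise DomainError(f"n_steps must be >= 0, got {n_steps}")
    states = np.empty((n_steps + 1, P.N + 1))
    s = initial_state(P.N)
    states[0] = s.omega
    for n in range(1, n_steps + 1):
        s = step(s, P)
        states[n] = s.omega
    times = np.arange(n_steps + 1) * P.dt
    conc = states * c_C0 if c_C0 is not None else None
    return StateTrajectory(times=times, states=states, concentrations=conc)


def ode_rhs(omega, Pm: TransitionMatrix, dt: float | None = None) -> np.ndarray:
    """Right-hand side of the continuous species mass balance (1/s).

    Per-step probabilities are converted to rates by division with ``dt``
    (the matrix's own step by default); the diagonal carries no rate.
    """
    dt = Pm.dt if dt is None else dt
    if dt <= 0:
        raise DomainError(f"dt must be > 0, got {dt}")
    w = omega.omega if isinstance(omega, StateVector) else np.asarray(omega, float)
    A = Pm.P / dt
    np.fill_diagonal(A, 0.0)
    return A @ w - w * A.sum(axis=0)


def simulate_ode(
    Pm: TransitionMatrix,
    t_end: float,
    solver_step: float,
    c_C0: float | None = None,
) -> StateTrajectory:
    """Fixed-step RK4 integration of :func:`ode_rhs`, sampled on the dt grid.

    ``solver_step`` must not exceed the matrix step ``dt``; internally it is
    rounded so that an integer number of RK4 steps fits in each ``dt``.
    """
    if t_end <= 0:
        raise DomainError(f"t_end must be > 0, got {t_end}")
    if solver_step > Pm.dt:
        raise DomainError(
            f"solver_step {solver_step} exceeds the sampling step dt = {Pm.dt}"
        )
    if solver_step <= 0:
        raise DomainError("solver_step must be > 0")
    substeps = max(1, round(Pm.dt / solver_step))
    h = Pm.dt / substeps
    n_samples = round(t_end / Pm.dt)

    A = Pm.P / Pm.dt
    np.fill_diagonal(A, 0.0)
    loss = A.sum(axis=0)

    def rhs(w: np.ndarray) -> np.ndarray:
        return A @ w - w * loss

    states = np.empty((n_samples + 1, Pm.N + 1))
    w = initial_state(Pm.N).omega
    states[0] = w
    for n in range(1, n_samples + 1):
        for _ in range(substeps):
            k1 = rhs(w)
            k2 = rhs(w + 0.5 * h * k1)
            k3 = rhs(w + 0.5 * h * k2)
            k4 = rhs(w + h * k3)
            w = w + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        states[n] = w
    times = np.arange(n_samples + 1) * Pm.dt
    conc = states * c_C0 if c_C0 is not None else None
    return StateTrajectory(times=times, states=states, concentrations=conc)


def trajectory_to_csv(traj: StateTrajectory, handle: IO[str]) -> None:
    """Long-format trajectory: one row per (time, class)."""
    writer = csv.writer(handle)
    writer.writerow(
        ["time_s", "class_index", "mass_fraction", "concentration_g_per_L"]
    )
    has_conc = traj.concentrations is not None
    for n, t in enumerate(traj.times):
        for i in range(traj.states.shape[1]):
            row = [f"{t:.17g}", i, f"{traj.states[n, i]:.17g}"]
            row.append(f"{traj.concentrations[n, i]:.17g}" if has_conc else "")
            writer.writerow(row)


def trajectory_from_csv(handle: IO[str]) -> StateTrajectory:
    reader = csv.DictReader(handle)
    times: list[float] = []
    rows: dict[float, dict[int, tuple[float, float | None]]] = {}
    for rec in reader:
        t = float(rec["time_s"])
        i = int(rec["class_index"])
        conc = rec.get("concentration_g_per_L") or None
        rows.setdefault(t, {})[i] = (
            float(rec["mass_fraction"]),
            float(conc) if conc is not None else None,
        )
    times = sorted(rows)
    n_classes = max(max(d) for d in rows.values()) + 1
    # classes absent from the file hold no mass
    states = np.array(
        [[rows[t].get(i, (0.0, 0.0))[0] for i in range(n_classes)] for t in times]
    )
    has_conc = all(v[1] is not None for d in rows.values() for v in d.values())
    conc = (
        np.array(
            [[rows[t].get(i, (0.0, 0.0))[1] for i in range(n_classes)] for t in times]
        )
        if has_conc
        else None
    )
    return StateTrajectory(times=np.array(times), states=states, concentrations=conc)
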