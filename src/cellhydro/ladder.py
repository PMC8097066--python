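"""Molecular-mass class ladder for a cellulose chain of cellobiose units.

A cellulose fragment of ``u`` cellobiose (CB) units is a condensation
polymer: its molar mass is ``u * 342 - (u - 1) * 18`` g/mol, because each
glycosidic bond releases one water molecule.  The hydrolysate population is
discretized into molecular-mass classes indexed ``i = 0 .. N``: class 0 is
the intact chain, successive classes are chains shorter by one CB unit
(uniform spacing of 324 g/mol), and the terminal class is absorbing.

Two terminal layouts are supported:

* ``glucose_terminal`` — the ladder runs down to cellobiose (342 g/mol) and
  the absorbing class ``N = n_units`` is glucose (180 g/mol).  This is the
  layout used for the 10-CB worked example.
* ``glucose_then_hmf`` — the last chain class is the 2-CB fragment, class
  ``N - 1`` is glucose, and the absorbing class ``N`` is
  hydroxymethylfurfural (HMF), glucose's acid degradation product.  This is
  the layout used for the 100-CB simulations, where the glucose class feeds
  a terminal HMF class.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable

from .errors import DomainError

#: Molar mass of cellobiose (CB), g/mol.
CELLOBIOSE_MASS = 342
#: Molar mass of glucose, g/mol.
GLUCOSE_MASS = 180
#: Molar mass of water, g/mol.
WATER_MASS = 18
#: Default molar mass assigned to the HMF class, g/mol.
HMF_MASS_DEFAULT = 126


class TerminalScheme(str, Enum):
    """Layout of the terminal (monomer / degradation-product) classes."""

    GLUCOSE_TERMINAL = "glucose_terminal"
    GLUCOSE_THEN_HMF = "glucose_then_hmf"


def chain_mass(units: int) -> int:
    """Molar mass (g/mol) of a chain of ``units`` cellobiose units.

    ``chain_mass(10) == 3258``, ``chain_mass(1) == 342``.
    """
    if units < 1:
        raise DomainError(f"a chain needs at least one cellobiose unit, got {units}")
    return units * CELLOBIOSE_MASS - (units - 1) * WATER_MASS


@dataclass(frozen=True)
class MassClassLadder:
    """Ordered molar masses of the hydrolysate molecular-mass classes.

    ``masses[i]`` is the molar mass of class ``i``; masses are strictly
    decreasing and ``N = len(masses) - 1`` indexes the absorbing terminal
    class.
    """

    n_units: int
    masses: tuple[int, ...]
    labels: tuple[str, ...]
    terminal_scheme: TerminalScheme
    unit_mass: int = CELLOBIOSE_MASS
    water_mass: int = WATER_MASS

    @property
    def N(self) -> int:
        return len(self.masses) - 1

    @property
    def glucose_class(self) -> int:
        """Index of the glucose class (``N`` or ``N - 1`` depending on layout)."""
        if self.terminal_scheme is TerminalScheme.GLUCOSE_TERMINAL:
            return self.N
        return self.N - 1

    @property
    def last_chain_class(self) -> int:
        """Index of the last polymeric (cleavable) class."""
        return self.glucose_class - 1

    def chain_units(self, i: int) -> int:
        """Number of CB units of chain class ``i``."""
        if not 0 <= i <= self.last_chain_class:
            raise DomainError(f"class {i} is not a chain class")
        return self.n_units - i

    def to_csv(self, handle: IO[str]) -> None:
        writer = csv.writer(handle)
        writer.writerow(["class_index", "molar_mass_g_per_mol", "label"])
        for i, (m, lab) in enumerate(zip(self.masses, self.labels)):
            writer.writerow([i, m, lab])


def _chain_labels(units: Iterable[int]) -> list[str]:
    return [f"CB×{u}" if u > 1 else "CB" for u in units]


def build_ladder(
    n_units: int,
    terminal_scheme: TerminalScheme | str = TerminalScheme.GLUCOSE_TERMINAL,
    hmf_mass: int = HMF_MASS_DEFAULT,
) -> MassClassLadder:
    """Build the mass-class ladder for a chain of ``n_units`` CB units.

    For ``glucose_terminal`` the classes are the chains of
    ``n_units, n_units - 1, ..., 1`` CB units followed by glucose
    (``N = n_units``).  For ``glucose_then_hmf`` the chain classes stop at
    2 CB units and are followed by glucose at ``N - 1`` and HMF at ``N``
    (again ``N = n_units``); the HMF mass only affects labeling and mass
    bookkeeping, never transition probabilities.
    """
    scheme = TerminalScheme(terminal_scheme)
    if n_units < 1:
        raise DomainError(f"n_units must be >= 1, got {n_units}")
    if scheme is TerminalScheme.GLUCOSE_TERMINAL:
        units = range(n_units, 0, -1)
        masses = [chain_mass(u) for u in units] + [GLUCOSE_MASS]
        labels = _chain_labels(units) + ["glucose"]
    else:
        if n_units < 2:
            raise DomainError("glucose_then_hmf needs a chain of at least 2 CB units")
        units = range(n_units, 1, -1)
        masses = [chain_mass(u) for u in units] + [GLUCOSE_MASS, int(hmf_mass)]
        labels = _chain_labels(units) + ["glucose", "HMF"]
    return MassClassLadder(
        n_units=n_units,
        masses=tuple(masses),
        labels=tuple(labels),
        terminal_scheme=scheme,
    )


def cleavage_masses(
    ladder: MassClassLadder, parent_class: int, child_class: int
) -> tuple[int, int]:
    """Masses of the two descendants of a binary hydrolytic cleavage.

    A parent in ``parent_class`` splits into a descendant in
    ``child_class`` plus a complementary fragment; hydrolysis adds one
    water molecule per broken bond, so the two descendant masses sum to
    the parent mass + 18 g/mol.
    """
    if not 0 <= parent_class <= ladder.last_chain_class:
        raise DomainError(
            f"parent class {parent_class} is not a cleavable chain class"
        )
    if not parent_class < child_class <= ladder.glucose_class:
        raise DomainError(
            f"child class must be in ({parent_class}, {ladder.glucose_class}], "
            f"got {child_class}"
        )
    m_parent = ladder.masses[parent_class]
    m_child = ladder.masses[child_class]
    m_complement = m_parent + ladder.water_mass - m_child
    return m_child, m_complement
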