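"""Boltzmann conformer populations and Eyring transition-state-theory rates.

A conformer/spin-state ensemble at one reaction-coordinate stage is weighted
by exp(−G_i/kT); the minimum free energy is subtracted before exponentiation
so the weights never overflow. Rates come from the Eyring equation
k = κ·(k_B T/h)·exp(−ΔG‡/RT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import CODATA, Constants
from .energetics import SpeciesLabel, Stage, StationaryPoint

__all__ = [
    "Ensemble",
    "PopulationRow",
    "PopulationTable",
    "boltzmann_populations",
    "eyring_rate_constant",
    "rate_ratio",
]


@dataclass(frozen=True)
class Ensemble:
    """All conformers/spin states present at one reaction-coordinate stage."""

    stage: Stage
    members: tuple[StationaryPoint, ...]
    temperature: float = CODATA.default_temperature

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ValueError("an ensemble needs at least one member")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        for m in self.members:
            if m.stage is not self.stage:
                raise ValueError(
                    f"member {m.label.describe()} has stage {m.stage.value}, "
                    f"ensemble is stage {self.stage.value}"
                )

    @property
    def free_energies(self) -> np.ndarray:
        return np.array([m.g for m in self.members], dtype=float)


@dataclass(frozen=True)
class PopulationRow:
    label: SpeciesLabel
    g: float
    mole_fraction: float
    percent: float


@dataclass(frozen=True)
class PopulationTable:
    """Boltzmann mole fractions over an ensemble, in input order."""

    rows: tuple[PopulationRow, ...]
    temperature: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        total = sum(r.mole_fraction for r in self.rows)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions must sum to 1, got {total}")

    @property
    def mole_fractions(self) -> np.ndarray:
        return np.array([r.mole_fraction for r in self.rows])

    def percent_of(self, label: SpeciesLabel) -> float:
        for row in self.rows:
            if row.label == label:
                return row.percent
        raise KeyError(f"label {label} not in population table")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": [r.label.site.value for r in self.rows],
                "stereopath": [r.label.stereopath.value for r in self.rows],
                "multiplicity": [r.label.multiplicity for r in self.rows],
                "g_hartree": [r.g for r in self.rows],
                "mole_fraction": [r.mole_fraction for r in self.rows],
                "percent": [r.percent for r in self.rows],
            }
        )


def boltzmann_populations(
    ensemble: Ensemble, constants: Constants = CODATA
) -> PopulationTable:
    """Equilibrium mole fractions p_i ∝ exp(−(G_i − G_min)/kT).

    Subtracting the ensemble minimum before exponentiation keeps every weight
    in (0, 1]; populations are therefore invariant under any uniform shift of
    the free energies.
    """
    g = ensemble.free_energies
    if not np.all(np.isfinite(g)):
        raise ValueError("all ensemble free energies must be finite")
    kt = constants.boltzmann_hartree * ensemble.temperature
    weights = np.exp(-(g - g.min()) / kt)
    fractions = weights / weights.sum()
    rows = [
        PopulationRow(
            label=m.label, g=m.g, mole_fraction=float(p), percent=float(100 * p)
        )
        for m, p in zip(ensemble.members, fractions)
    ]
    return PopulationTable(rows=tuple(rows), temperature=ensemble.temperature)


def eyring_rate_constant(
    dg_activation: float,
    temperature: float = CODATA.default_temperature,
    transmission: float = 1.0,
    constants: Constants = CODATA,
) -> float:
    """Eyring rate constant k = κ·(k_B T/h)·exp(−ΔG‡/RT) in s⁻¹.

    ``dg_activation`` is the free-energy barrier in kcal/mol; ``transmission``
    is the transmission coefficient κ ∈ (0, 1] (default 1: no tunneling or
    recrossing correction).
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if not 0 < transmission <= 1:
        raise ValueError(f"transmission must lie in (0, 1], got {transmission}")
    prefactor = constants.boltzmann_si * temperature / constants.planck
    exponent = -dg_activation / (constants.gas_constant_kcal * temperature)
    return transmission * prefactor * math.exp(exponent)


def rate_ratio(
    dg1: float,
    dg2: float,
    temperature: float = CODATA.default_temperature,
    constants: Constants = CODATA,
) -> float:
    """k₁/k₂ for two barriers (kcal/mol): exp((ΔG‡₂ − ΔG‡₁)/RT).

    The Eyring prefactor cancels, so the ratio depends only on the barrier
    difference. Satisfies ratio(a, b)·ratio(b, a) = 1.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return math.exp((dg2 - dg1) / (constants.gas_constant_kcal * temperature))
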