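"""Synthetic conformer ensembles and mode spectra with known ground truth.

The generator emulates the structure of the study's conformer ensembles: a
handful of conformers/spin states separated by free-energy gaps of a few
kcal/mol at 298.15 K, and harmonic mode spectra with at most one imaginary
mode (a transition state). Gaps are statistical stand-ins — no geometries or
plausible electronic energies are generated.

``generate_ensemble`` also returns the analytically expected Boltzmann
populations, computed here by the direct closed-form expression on the gaps
in kcal/mol (no max-subtraction trick, different unit route) so it serves as
an independent oracle for the statmech implementation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import CODATA
from .energetics import Molecule, Site, SpeciesLabel, Stage, StationaryPoint
from .statmech import Ensemble, PopulationRow, PopulationTable

__all__ = [
    "EnsembleSpec",
    "SpectrumSpec",
    "generate_ensemble",
    "generate_spectrum",
    "analytic_populations",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for one synthetic ensemble.

    ``gap_model`` is 'uniform' (gaps ~ U(0, scale)), 'exponential'
    (gaps ~ Exp(mean=scale)) or 'explicit' (``gaps`` given directly); all
    gaps in kcal/mol above the base conformer. ``seed`` fully determines the
    output.
    """

    n_members: int
    gap_model: str = "uniform"
    scale: float = 3.0
    gaps: tuple[float, ...] | None = None
    temperature: float = CODATA.default_temperature
    base_g: float = -1976.0
    stage: Stage = Stage.RADICAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be ≥ 1")
        if self.gap_model not in {"uniform", "exponential", "explicit"}:
            raise ValueError(f"unknown gap model {self.gap_model!r}")
        if self.gap_model == "explicit":
            if self.gaps is None or len(self.gaps) != self.n_members:
                raise ValueError("explicit gap model needs one gap per member")
            object.__setattr__(self, "gaps", tuple(self.gaps))
            if any(g < 0 for g in self.gaps):
                raise ValueError("gaps must be ≥ 0")
        elif self.scale <= 0:
            raise ValueError("gap scale must be positive")


@dataclass(frozen=True)
class SpectrumSpec:
    """Recipe for a synthetic harmonic spectrum (wavenumbers in cm⁻¹)."""

    n_modes: int
    range: tuple[float, float] = (20.0, 3500.0)
    n_imaginary: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.range
        if not 0 < lo <= hi:
            raise ValueError("frequency range must satisfy 0 < min ≤ max")
        if self.n_imaginary not in (0, 1):
            raise ValueError("n_imaginary must be 0 or 1")
        if self.n_modes < self.n_imaginary:
            raise ValueError("need at least one mode to make it imaginary")


def _sample_gaps(spec: EnsembleSpec) -> np.ndarray:
    if spec.gap_model == "explicit":
        return np.asarray(spec.gaps, dtype=float)
    rng = np.random.default_rng(spec.seed)
    if spec.gap_model == "uniform":
        gaps = rng.uniform(0.0, spec.scale, size=spec.n_members)
    else:
        gaps = rng.exponential(spec.scale, size=spec.n_members)
    gaps[0] = 0.0  # anchor the base conformer
    return gaps


def _synthetic_labels(n: int) -> list[SpeciesLabel]:
    combos = itertools.cycle(
        itertools.product(tuple(Site), (2, 4, 6))
    )
    return [
        SpeciesLabel(molecule=Molecule.BETA_PINENE, site=site, multiplicity=mult)
        for site, mult in itertools.islice(combos, n)
    ]


def analytic_populations(gaps_kcal: Sequence[float], temperature: float) -> np.ndarray:
    """Closed-form Boltzmann fractions from gaps in kcal/mol.

    Deliberately the naive expression — direct exponentials on the kcal/mol
    scale, normalized afterwards, no max-subtraction — sharing no code with
    the statmech route. kT is expressed on the kcal scale through the same
    constant pair the rest of the package uses, so the two routes agree to
    numerical precision.
    """
    rt = CODATA.boltzmann_hartree * CODATA.hartree_to_kcal * temperature
    weights = [math.exp(-g / rt) for g in gaps_kcal]
    total = sum(weights)
    return np.array([w / total for w in weights])


def generate_ensemble(spec: EnsembleSpec) -> tuple[Ensemble, PopulationTable]:
    """Synthesize an ensemble and its analytically expected populations."""
    gaps = _sample_gaps(spec)
    labels = _synthetic_labels(spec.n_members)
    hartree_gaps = gaps / CODATA.hartree_to_kcal
    members = tuple(
        StationaryPoint(
            label=label,
            stage=spec.stage,
            g=spec.base_g + gap,
            note="synthetic",
        )
        for label, gap in zip(labels, hartree_gaps)
    )
    ensemble = Ensemble(
        stage=spec.stage, members=members, temperature=spec.temperature
    )
    fractions = analytic_populations(gaps, spec.temperature)
    table = PopulationTable(
        rows=tuple(
            PopulationRow(
                label=m.label,
                g=m.g,
                mole_fraction=float(p),
                percent=float(100 * p),
            )
            for m, p in zip(members, fractions)
        ),
        temperature=spec.temperature,
    )
    return ensemble, table


def generate_spectrum(spec: SpectrumSpec) -> np.ndarray:
    """Sorted positive wavenumbers, preceded by one imaginary mode if requested."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.range
    n_real = spec.n_modes - spec.n_imaginary
    reals = np.sort(rng.uniform(lo, hi, size=n_real))
    if spec.n_imaginary:
        imag = -rng.uniform(lo, hi)
        return np.concatenate([[imag], reals])
    return reals
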