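"""Domain types and relative-energy arithmetic for pinene/CYP stationary points.

The objects here describe optimized stationary points of the hydrogen
abstraction / oxygen rebound reaction of α- and β-pinene at a cytochrome
P450 (CYP) compound-I model: which carbon the hydrogen leaves from, which of
the two diastereotopic allylic hydrogens is taken (cis/trans), the spin
multiplicity of the Fe–oxo surface, and the corrected Gibbs free energy of
the structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .constants import CODATA, Constants

__all__ = [
    "Molecule",
    "Site",
    "Stereopath",
    "Enantiomer",
    "Stage",
    "SpeciesLabel",
    "CorrectionSet",
    "StationaryPoint",
    "convert_energy",
    "total_free_energy",
    "relative_energies",
    "AUTO_MINIMUM",
]


class Molecule(str, Enum):
    ALPHA_PINENE = "alpha-pinene"
    BETA_PINENE = "beta-pinene"


class Site(str, Enum):
    """Abstraction sites, named with Greek letters around the pinene scaffold."""

    ALPHA = "alpha"
    GAMMA = "gamma"
    DELTA = "delta"
    EPSILON = "epsilon"
    ZETA = "zeta"
    THETA = "theta"
    IOTA = "iota"
    KAPPA = "kappa"


class Stereopath(str, Enum):
    """Which of two diastereotopic allylic hydrogens is abstracted."""

    CIS = "cis"
    TRANS = "trans"
    NONE = "none"


class Enantiomer(str, Enum):
    R = "R"
    S = "S"
    NONE = "none"


class Stage(str, Enum):
    """Reaction-coordinate stages of the abstraction/rebound mechanism."""

    REACTANT_COMPLEX = "I"
    ABSTRACTION_TS = "II"
    RADICAL = "III"
    HYDROXYLATED = "IV"
    BARE_RADICAL = "bare-radical"
    BARE_HYDROXYLATED = "bare-hydroxylated"


VALID_MULTIPLICITIES = frozenset({2, 4, 6})

# Sites bearing two distinguishable allylic hydrogens; only these may carry a
# cis/trans stereopath. β-pinene's epsilon carbon is included because its
# hydroxylated products resolve into cis and trans isomers.
STEREO_SITES = frozenset(
    {
        (Molecule.BETA_PINENE, Site.DELTA),
        (Molecule.ALPHA_PINENE, Site.EPSILON),
        (Molecule.BETA_PINENE, Site.EPSILON),
    }
)


@dataclass(frozen=True, order=True)
class SpeciesLabel:
    """Identity of one species: molecule, site, stereochemistry, spin."""

    molecule: Molecule
    site: Site
    stereopath: Stereopath = Stereopath.NONE
    enantiomer: Enantiomer = Enantiomer.NONE
    multiplicity: int = 2

    def __post_init__(self) -> None:
        if self.multiplicity not in VALID_MULTIPLICITIES:
            raise ValueError(
                f"multiplicity must be one of {sorted(VALID_MULTIPLICITIES)} "
                f"(doublet/quartet/sextet), got {self.multiplicity}"
            )
        if (
            self.stereopath is not Stereopath.NONE
            and (self.molecule, self.site) not in STEREO_SITES
        ):
            raise ValueError(
                f"site {self.site.value} of {self.molecule.value} has no "
                "distinguishable cis/trans allylic hydrogens"
            )

    @property
    def spin(self) -> float:
        """Total spin S = (multiplicity − 1)/2."""
        return (self.multiplicity - 1) / 2

    def describe(self) -> str:
        parts = [self.site.value]
        if self.stereopath is not Stereopath.NONE:
            parts.append(self.stereopath.value)
        parts.append({2: "doublet", 4: "quartet", 6: "sextet"}[self.multiplicity])
        return "-".join(parts)


@dataclass(frozen=True)
class CorrectionSet:
    """Additive post-SCF corrections in hartree.

    ``dispersion`` (D4), ``bsse`` (geometric counterpoise) and
    ``quasi_harmonic`` (low-mode free-rotor entropy correction) are the three
    terms folded into corrected free energies; ``solvent`` is an optional
    continuum-solvation term.
    """

    dispersion: float
    bsse: float
    quasi_harmonic: float
    solvent: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dispersion", "bsse", "quasi_harmonic", "solvent"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"correction term {name} must be finite")

    @property
    def total(self) -> float:
        return self.dispersion + self.bsse + self.quasi_harmonic + self.solvent


#: Tolerance for the g = g_uncorrected + corrections consistency check (Eh).
_G_CONSISTENCY_TOL = 1e-9


@dataclass(frozen=True)
class StationaryPoint:
    """One optimized species: label, stage, energies, optional mode list.

    ``g`` is the corrected Gibbs free energy G_cor in hartree (required —
    every analysis in the package keys off it). ``g_uncorrected`` is the
    plain E+thermal free energy before the additive corrections;
    ``e_elec``/``h`` are the electronic energy and enthalpy. These three are
    optional because the study tables print only G_cor for most species.
    Imaginary vibrational modes are encoded as negative wavenumbers; an
    abstraction transition state must have exactly one.
    """

    label: SpeciesLabel
    stage: Stage
    g: float
    e_elec: float | None = None
    h: float | None = None
    g_uncorrected: float | None = None
    corrections: CorrectionSet | None = None
    frequencies: tuple[float, ...] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.g):
            raise ValueError(f"free energy g must be finite, got {self.g}")
        if self.frequencies is not None:
            object.__setattr__(self, "frequencies", tuple(self.frequencies))
            n_imag = sum(1 for f in self.frequencies if f < 0)
            if self.stage is Stage.ABSTRACTION_TS and n_imag != 1:
                raise ValueError(
                    "an abstraction transition state must carry exactly one "
                    f"imaginary mode, found {n_imag}"
                )
        if self.corrections is not None and self.g_uncorrected is not None:
            expected = self.g_uncorrected + self.corrections.total
            if abs(self.g - expected) > _G_CONSISTENCY_TOL:
                raise ValueError(
                    f"g = {self.g} inconsistent with g_uncorrected + "
                    f"corrections = {expected} (|Δ| > {_G_CONSISTENCY_TOL} Eh)"
                )


_UNIT_FACTORS = {"hartree": 1.0, "kcal/mol": None}  # kcal factor comes from Constants


def convert_energy(
    value: float,
    from_unit: str,
    to_unit: str,
    constants: Constants = CODATA,
) -> float:
    """Convert an energy between hartree and kcal/mol.

    Raises ``ValueError`` for an unknown unit string.
    """
    for unit in (from_unit, to_unit):
        if unit not in _UNIT_FACTORS:
            raise ValueError(
                f"unknown energy unit {unit!r}; supported units are "
                f"{sorted(_UNIT_FACTORS)}"
            )
    if from_unit == to_unit:
        return value
    if from_unit == "hartree":
        return value * constants.hartree_to_kcal
    return value / constants.hartree_to_kcal


def total_free_energy(e_plus_thermal: float, corrections: CorrectionSet) -> float:
    """Corrected Gibbs free energy: E+thermal plus all additive corrections (Eh)."""
    if not math.isfinite(e_plus_thermal):
        raise ValueError("e_plus_thermal must be finite")
    return e_plus_thermal + corrections.total


#: Sentinel selecting the most stable member as the zero reference.
AUTO_MINIMUM = "auto-minimum"


def relative_energies(
    points: Sequence[StationaryPoint],
    reference: str | SpeciesLabel = AUTO_MINIMUM,
    constants: Constants = CODATA,
) -> list[tuple[SpeciesLabel, float]]:
    """Free energies relative to a reference, in kcal/mol.

    With ``reference=AUTO_MINIMUM`` the most stable point (first occurrence on
    ties) maps to exactly 0 and every other value is ≥ 0. An explicit
    ``SpeciesLabel`` reference must be present in ``points``; other members
    may then come out negative.
    """
    if not points:
        raise ValueError("relative_energies requires a nonempty point list")
    if reference == AUTO_MINIMUM:
        g_ref = min(p.g for p in points)
    else:
        matches = [p for p in points if p.label == reference]
        if not matches:
            raise ValueError(f"reference label {reference} not found in point list")
        g_ref = matches[0].g
    return [
        (p.label, convert_energy(p.g - g_ref, "hartree", "kcal/mol", constants))
        for p in points
    ]
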