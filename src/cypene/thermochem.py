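"""Ideal-gas thermochemistry from vibrational frequencies: RRHO and quasi-RRHO.

The rigid-rotor harmonic-oscillator (RRHO) partition function gives thermal
enthalpy and entropy corrections from a molecule's harmonic modes, mass and
moments of inertia. Low-frequency torsions are notoriously poorly described
by the harmonic oscillator: their entropy diverges as the frequency goes to
zero. The quasi-RRHO treatment damps each mode's harmonic-oscillator entropy
toward a free-rotor entropy with a switching function

    w(ν) = 1 / (1 + (ν₀/ν)^α),        S_mode = w·S_HO + (1 − w)·S_FR

so that stiff modes stay harmonic while soft modes behave like hindered
internal rotations. Defaults ν₀ = 100 cm⁻¹, α = 4, average molecular moment
B_av = 1e-44 kg·m² follow the canonical damped free-rotor scheme.

Imaginary modes (negative wavenumbers) never contribute to thermochemistry;
they are dropped with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .constants import CODATA, Constants

__all__ = [
    "QuasiRRHOParams",
    "MoleculeThermoInput",
    "ThermoResult",
    "rrho_mode_entropy",
    "free_rotor_mode_entropy",
    "mode_damping",
    "quasi_rrho_vibrational_entropy",
    "rrho_vibrational_entropy",
    "thermochemistry",
    "total_gibbs",
]

Method = Literal["RRHO", "quasi-RRHO"]


@dataclass(frozen=True)
class QuasiRRHOParams:
    """Damping parameters of the quasi-RRHO interpolation.

    ``nu0`` (cm⁻¹) is the crossover frequency at which a mode is treated
    half-harmonic, half-free-rotor; ``alpha`` sets the sharpness of the
    switch; ``b_av`` (kg·m²) is the average molecular moment of inertia used
    to cap the effective free-rotor moment of very soft modes.
    """

    nu0: float = 100.0
    alpha: float = 4.0
    b_av: float = 1e-44

    def __post_init__(self) -> None:
        if self.nu0 <= 0 or self.alpha <= 0 or self.b_av <= 0:
            raise ValueError("quasi-RRHO parameters must all be positive")


@dataclass(frozen=True)
class MoleculeThermoInput:
    """Everything conventional statistical mechanics needs for one molecule.

    ``principal_moments`` holds three moments of inertia in kg·m² (or a
    single moment with ``linear=True``); ``frequencies`` in cm⁻¹ with
    negatives marking imaginary modes, which are excluded.
    """

    frequencies: tuple[float, ...]
    molar_mass: float
    principal_moments: tuple[float, ...]
    rotational_symmetry_number: int = 1
    electronic_degeneracy: int = 1
    linear: bool = False
    atomic: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", tuple(self.frequencies))
        object.__setattr__(self, "principal_moments", tuple(self.principal_moments))
        if self.molar_mass <= 0:
            raise ValueError("molar mass must be positive")
        if self.rotational_symmetry_number < 1 or self.electronic_degeneracy < 1:
            raise ValueError("symmetry number and degeneracy must be ≥ 1")
        if not self.atomic:
            n_expected = 1 if self.linear else 3
            if len(self.principal_moments) != n_expected:
                raise ValueError(
                    f"expected {n_expected} principal moment(s), "
                    f"got {len(self.principal_moments)}"
                )
            if any(m <= 0 for m in self.principal_moments):
                raise ValueError("principal moments must be positive")
            if not any(f > 0 for f in self.frequencies):
                raise ValueError("a non-atomic species needs ≥ 1 real frequency")

    @property
    def real_frequencies(self) -> np.ndarray:
        freqs = np.asarray(self.frequencies, dtype=float)
        n_imag = int(np.sum(freqs < 0))
        if n_imag:
            warnings.warn(
                f"dropping {n_imag} imaginary mode(s) from thermochemistry",
                stacklevel=3,
            )
        return freqs[freqs > 0]


@dataclass(frozen=True)
class ThermoResult:
    """Thermal corrections (hartree / hartree·K⁻¹, per molecule).

    ``g_corr = h_corr − T·(s_trans + s_rot + s_vib + s_elec)``; with
    degeneracy 1 (every species in this study) ``s_elec`` is exactly 0.
    """

    zpe: float
    h_corr: float
    s_trans: float
    s_rot: float
    s_vib: float
    s_elec: float
    g_corr: float
    method: Method
    temperature: float
    pressure: float


def _theta(frequency: float, constants: Constants) -> float:
    """hcν/k in K for a wavenumber in cm⁻¹."""
    return (
        constants.planck
        * constants.speed_of_light
        * frequency
        / constants.boltzmann_si
    )


def rrho_mode_entropy(
    frequency: float, temperature: float, constants: Constants = CODATA
) -> float:
    """Harmonic-oscillator entropy of one mode, in hartree·K⁻¹ per molecule.

    S = k[(x)/(e^x − 1) − ln(1 − e^{−x})] with x = hcν/kT; strictly
    decreasing in ν and increasing in T.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    x = _theta(frequency, constants) / temperature
    s_si = constants.boltzmann_si * (x / math.expm1(x) - math.log1p(-math.exp(-x)))
    return s_si / constants.hartree_joule


def free_rotor_mode_entropy(
    frequency: float,
    temperature: float,
    b_av: float = 1e-44,
    constants: Constants = CODATA,
) -> float:
    """Free-rotor entropy assigned to a low-frequency mode (hartree·K⁻¹).

    The mode is mapped onto a one-dimensional rotor with effective moment
    μ = h/(8π²cν), reduced against the average molecular moment,
    μ' = μ·B_av/(μ + B_av), then S = k[1/2 + ln(√(8π³μ'kT)/h)].
    """
    if frequency <= 0 or temperature <= 0 or b_av <= 0:
        raise ValueError("frequency, temperature and b_av must all be positive")
    h = constants.planck
    mu = h / (8 * math.pi**2 * constants.speed_of_light * frequency)
    mu_red = mu * b_av / (mu + b_av)
    arg = math.sqrt(8 * math.pi**3 * mu_red * constants.boltzmann_si * temperature) / h
    s_si = constants.boltzmann_si * (0.5 + math.log(arg))
    return s_si / constants.hartree_joule


def mode_damping(frequency: float, nu0: float, alpha: float) -> float:
    """Switching weight w(ν) = 1/(1 + (ν₀/ν)^α) ∈ (0, 1)."""
    return 1.0 / (1.0 + (nu0 / frequency) ** alpha)


def rrho_vibrational_entropy(
    frequencies: Iterable[float], temperature: float, constants: Constants = CODATA
) -> float:
    freqs = [f for f in frequencies if f > 0]
    if not freqs:
        raise ValueError("no positive frequencies supplied")
    return sum(rrho_mode_entropy(f, temperature, constants) for f in freqs)


def quasi_rrho_vibrational_entropy(
    frequencies: Iterable[float],
    temperature: float,
    params: QuasiRRHOParams = QuasiRRHOParams(),
    constants: Constants = CODATA,
) -> float:
    """Total damped vibrational entropy over all real modes (hartree·K⁻¹).

    Each mode's entropy is bracketed by its harmonic and free-rotor values;
    imaginary (negative) inputs are discarded before summation.
    """
    freqs = [f for f in frequencies if f > 0]
    if not freqs:
        raise ValueError("no positive frequencies supplied")
    total = 0.0
    for f in freqs:
        w = mode_damping(f, params.nu0, params.alpha)
        s_ho = rrho_mode_entropy(f, temperature, constants)
        s_fr = free_rotor_mode_entropy(f, temperature, params.b_av, constants)
        total += w * s_ho + (1 - w) * s_fr
    return total


def _translational_entropy(
    molar_mass: float, temperature: float, pressure: float, constants: Constants
) -> float:
    """Sackur–Tetrode entropy of an ideal gas at P atm (hartree·K⁻¹)."""
    k = constants.boltzmann_si
    m = molar_mass * 1e-3 / constants.avogadro
    p_pa = pressure * constants.atm_pascal
    lam_term = (2 * math.pi * m * k * temperature / constants.planck**2) ** 1.5
    q_trans = lam_term * k * temperature / p_pa
    s_si = k * (math.log(q_trans) + 2.5)
    return s_si / constants.hartree_joule


def _rotational_entropy(inp: MoleculeThermoInput, temperature: float, constants: Constants) -> float:
    if inp.atomic:
        return 0.0
    k = constants.boltzmann_si
    h = constants.planck
    sigma = inp.rotational_symmetry_number
    if inp.linear:
        (moment,) = inp.principal_moments
        q_rot = 8 * math.pi**2 * moment * k * temperature / (sigma * h**2)
        s_si = k * (math.log(q_rot) + 1.0)
    else:
        ia, ib, ic = inp.principal_moments
        q_rot = (
            math.sqrt(math.pi)
            / sigma
            * (8 * math.pi**2 * k * temperature / h**2) ** 1.5
            * math.sqrt(ia * ib * ic)
        )
        s_si = k * (math.log(q_rot) + 1.5)
    return s_si / constants.hartree_joule


def thermochemistry(
    inp: MoleculeThermoInput,
    temperature: float = CODATA.default_temperature,
    pressure: float = CODATA.default_pressure,
    method: Method = "quasi-RRHO",
    params: QuasiRRHOParams = QuasiRRHOParams(),
    constants: Constants = CODATA,
) -> ThermoResult:
    """Full ideal-gas thermal correction at (T, P).

    Enthalpy: ZPE + vibrational thermal energy + 3/2 RT translation +
    rotational thermal energy + RT (PV). Entropy: Sackur–Tetrode
    translation, rigid-rotor rotation with symmetry number, vibrational
    (RRHO or quasi-RRHO), electronic k·ln(degeneracy). Frequencies are used
    unscaled.
    """
    if temperature <= 0 or pressure <= 0:
        raise ValueError("temperature and pressure must be positive")
    k_h = constants.boltzmann_hartree  # k in Eh/K: per-molecule "RT" in hartree
    freqs = inp.real_frequencies

    zpe = 0.0
    e_vib = 0.0
    for f in freqs:
        theta = _theta(f, constants)
        zpe += 0.5 * k_h * theta
        e_vib += k_h * theta / math.expm1(theta / temperature)

    e_trans = 1.5 * k_h * temperature
    if inp.atomic:
        e_rot = 0.0
    elif inp.linear:
        e_rot = k_h * temperature
    else:
        e_rot = 1.5 * k_h * temperature
    h_corr = zpe + e_vib + e_trans + e_rot + k_h * temperature

    s_trans = _translational_entropy(inp.molar_mass, temperature, pressure, constants)
    s_rot = _rotational_entropy(inp, temperature, constants)
    if inp.atomic or len(freqs) == 0:
        s_vib = 0.0
    elif method == "RRHO":
        s_vib = rrho_vibrational_entropy(freqs, temperature, constants)
    elif method == "quasi-RRHO":
        s_vib = quasi_rrho_vibrational_entropy(freqs, temperature, params, constants)
    else:
        raise ValueError(f"unknown thermochemistry method {method!r}")
    s_elec = (
        constants.boltzmann_si
        * math.log(inp.electronic_degeneracy)
        / constants.hartree_joule
    )

    g_corr = h_corr - temperature * (s_trans + s_rot + s_vib + s_elec)
    return ThermoResult(
        zpe=zpe,
        h_corr=h_corr,
        s_trans=s_trans,
        s_rot=s_rot,
        s_vib=s_vib,
        s_elec=s_elec,
        g_corr=g_corr,
        method=method,
        temperature=temperature,
        pressure=pressure,
    )


def total_gibbs(e_elec: float, thermo: ThermoResult) -> float:
    """Absolute Gibbs free energy: electronic energy plus thermal correction (Eh)."""
    return e_elec + thermo.g_corr
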