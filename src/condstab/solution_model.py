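"""Solution conditions, ionic strength, Debye length and screening energies.

Electrostatic pair interactions between sticker residues are attenuated by
the ionic atmosphere of the solution.  Within extended Debye-Hückel theory
the attenuation of a unit-charge pair is an energy per mole of pairs,

    s_r = F^2 / (N_A * 8 * pi * eps_r * eps0) * 1 / (r_d + r0),

the electrostatic energy of one mole of charge pairs held at separation
2*(r_d + r0), where r_d is the Debye length and r0 a fitted distance that
rescales the size of the ionic atmosphere per interaction type.  The Debye
length uses the standard two-ion-cloud form

    r_d = sqrt(eps_r * eps0 * R * T / (2 * 1000 * F^2 * I)),

with the ionic strength I in mol dm^-3.  Screening magnitudes are computed
here with |z_a z_b| = 1; the stability model applies them with the
appropriate sign (attractions reduced, repulsions softened).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from scipy import constants as _const

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "IonSpecies",
    "SolutionCondition",
    "ScreeningResult",
    "BUFFER_IONIC_STRENGTH_MM",
    "ionic_strength",
    "debye_length",
    "screening_constant",
    "tight_loose_screening",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants used throughout (SI units)."""

    F: float = _const.physical_constants["Faraday constant"][0]  # C mol^-1
    N_A: float = _const.Avogadro  # mol^-1
    R: float = 8.314  # J mol^-1 K^-1
    eps0: float = _const.epsilon_0  # F m^-1


CONSTANTS = PhysicalConstants()

#: Ionic-strength offset (mM) approximating the study's 20 mM Tris/PIPES
#: buffer background; opt-in via SolutionCondition.extra_ionic_strength.
BUFFER_IONIC_STRENGTH_MM = 20.0


@dataclass(frozen=True)
class IonSpecies:
    """A fully dissociated ion at a given added concentration."""

    name: str
    z: int
    conc: float  # mM

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError(f"ion {self.name!r} must carry a nonzero charge")
        if self.conc < 0:
            raise ValueError(f"ion {self.name!r} concentration must be >= 0")


def salt_ions(name: str, z_cation: int, conc_mm: float) -> list[IonSpecies]:
    """Ions contributed by ``conc_mm`` of a chloride salt of a z+ cation."""
    return [
        IonSpecies(name=name, z=z_cation, conc=conc_mm),
        IonSpecies(name="Cl", z=-1, conc=conc_mm * z_cation),
    ]


@dataclass(frozen=True)
class SolutionCondition:
    """pH, temperature and explicit ion composition of one sample."""

    pH: float
    T: float = 295.15  # K; room-temperature in vitro default
    ions: tuple[IonSpecies, ...] = ()
    extra_ionic_strength: float = 0.0  # mM, e.g. buffer contribution

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.extra_ionic_strength < 0:
            raise ValueError("extra ionic strength must be >= 0")
        object.__setattr__(self, "ions", tuple(self.ions))

    def cation_concentrations(self) -> dict[str, float]:
        """Added concentration (mM) per cation name, summed over entries."""
        out: dict[str, float] = {}
        for ion in self.ions:
            if ion.z >= 1:
                out[ion.name] = out.get(ion.name, 0.0) + ion.conc
        return out


@dataclass(frozen=True)
class ScreeningResult:
    """Ionic strength, Debye length and screening energies for a condition."""

    I: float  # mol dm^-3
    r_d: float  # m
    s_r: float  # kJ mol^-1 (unit-charge pair)
    s_s: float | None = None  # kJ mol^-1, tight/loose variant


def ionic_strength(cond: SolutionCondition) -> float:
    """Ionic strength in mM: I = 1/2 sum_i c_i z_i^2 plus any fixed offset."""
    return 0.5 * sum(i.conc * i.z**2 for i in cond.ions) + cond.extra_ionic_strength


def debye_length(
    I_mM: float, eps_r: float, T: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Debye length (m) at ionic strength ``I_mM`` (mM).

    Returns ``inf`` at I = 0 (no ionic atmosphere, screening vanishes).
    """
    if eps_r <= 0:
        raise ValueError("relative dielectric must be positive")
    if I_mM < 0:
        raise ValueError("ionic strength must be >= 0")
    if I_mM == 0:
        return math.inf
    I_molar = I_mM / 1000.0
    c = constants
    return math.sqrt(
        eps_r * c.eps0 * c.R * T / (2.0 * 1000.0 * c.F**2 * I_molar)
    )


def _prefactor(eps_r: float, constants: PhysicalConstants) -> float:
    """F^2/(N_A 8 pi eps_r eps0) in J m mol^-1."""
    c = constants
    return c.F**2 / (c.N_A * 8.0 * math.pi * eps_r * c.eps0)


def screening_constant(
    z_a: int,
    z_b: int,
    eps_r: float,
    I_mM: float,
    r0: float,
    T: float,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Debye-Hückel screening energy magnitude in kJ mol^-1.

    ``r0`` (m) offsets the Debye length; larger ``r0`` weakens screening.
    The magnitude uses |z_a z_b|; sign conventions are applied by the
    caller when combining with zero-salt pair energies.
    """
    if r0 < 0:
        raise ValueError("screening distance r0 must be >= 0")
    if I_mM == 0:
        return 0.0
    r_d = debye_length(I_mM, eps_r, T, constants)
    energy_j = abs(z_a * z_b) * _prefactor(eps_r, constants) / (r_d + r0)
    return energy_j / 1000.0


def tight_loose_screening(
    z_a: int,
    z_b: int,
    eps_r: float,
    I_mM: float,
    r0: float,
    n: float,
    T: float,
    approximate: bool = False,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Screening free energy between 'tight' and 'loose' ion-pair complexes.

    The tight complex has characteristic distance ``n * r0`` (n >= 1), the
    loose one ``r0``; the exact difference form is

        s_s = |z_a z_b| * F^2/(N_A 8 pi eps eps0)
              * dr0 / ((r_d + r0) * (r_d + n*r0)),   dr0 = (n - 1) * r0.

    With ``approximate=True`` the linear-in-I small-difference limit
    ``s_s ~ pref * dr0 / r_d^2`` is returned instead.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if r0 < 0:
        raise ValueError("screening distance r0 must be >= 0")
    dr0 = (n - 1.0) * r0
    if dr0 == 0.0 or I_mM == 0:
        return 0.0
    r_d = debye_length(I_mM, eps_r, T, constants)
    pref = abs(z_a * z_b) * _prefactor(eps_r, constants)
    if approximate:
        return pref * dr0 / r_d**2 / 1000.0
    return pref * dr0 / ((r_d + r0) * (r_d + n * r0)) / 1000.0


def screening_summary(
    cond: SolutionCondition,
    eps_r: float,
    r0: float,
    constants: PhysicalConstants = CONSTANTS,
) -> ScreeningResult:
    """Convenience bundle of I, r_d and the unit-charge screening energy."""
    I_mM = ionic_strength(cond)
    return ScreeningResult(
        I=I_mM / 1000.0,
        r_d=debye_length(I_mM, eps_r, cond.T, constants),
        s_r=screening_constant(1, 1, eps_r, I_mM, r0, cond.T, constants),
    )
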