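"""Nanoparticle suspension geometry and the solution medium.

All quantities are strict SI internally: metres, seconds, mol m^-3
(1 mol m^-3 == 1 mM), kg m^-3.  The I/O layer converts to the lab-facing
units (nm, hours, mM, ug/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CUO_DENSITY",
    "CUO_MOLAR_MASS",
    "DEFAULT_K_SITE",
    "ParticleSystem",
    "MediumSpec",
    "Inventory",
    "copper_inventories",
]

#: density of tenorite CuO, kg m^-3 (handbook value)
CUO_DENSITY = 6310.0
#: molar mass of CuO, kg mol^-1
CUO_MOLAR_MASS = 0.07955
#: default atomic surface density k_#,s, mol m^-2 (~1e19 sites m^-2),
#: used when k_#,s is not a fit parameter
DEFAULT_K_SITE = 1.66e-5


class InvalidParticleError(ValueError):
    """Raised when a ParticleSystem violates its physical invariants."""


@dataclass(frozen=True)
class ParticleSystem:
    """Monodisperse spherical oxide nanoparticles in suspension.

    Parameters
    ----------
    d0 : float
        Initial particle diameter, m.
    f_fe0 : float
        Initial atomic iron fraction Fe/(Fe+Cu), dimensionless, in [0, 1).
    mass_conc : float
        Oxide mass concentration of the suspension, kg m^-3.
    density : float
        Solid density of the oxide, kg m^-3.
    molar_mass : float
        Mean molar mass of the oxide, kg mol^-1.
    """

    d0: float
    f_fe0: float = 0.0
    mass_conc: float = 0.0125  # 12.5 ug/mL
    density: float = CUO_DENSITY
    molar_mass: float = CUO_MOLAR_MASS

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise InvalidParticleError(f"d0 must be positive, got {self.d0}")
        if not (self.density > 0):
            raise InvalidParticleError(f"density must be positive, got {self.density}")
        if not (self.molar_mass > 0):
            raise InvalidParticleError("molar_mass must be positive")
        if not (0.0 <= self.f_fe0 < 1.0):
            raise InvalidParticleError(
                f"f_fe0 must lie in [0, 1), got {self.f_fe0}"
            )
        if self.mass_conc < 0:
            raise InvalidParticleError("mass_conc must be non-negative")

    @property
    def radius(self) -> float:
        """Initial particle radius R = d0/2, m."""
        return self.d0 / 2.0

    @property
    def particle_mass(self) -> float:
        """Mass of one particle, kg."""
        return self.density * np.pi * self.d0**3 / 6.0

    @property
    def number_density(self) -> float:
        """Particles per unit suspension volume, m^-3."""
        return self.mass_conc / self.particle_mass

    @property
    def area_per_volume(self) -> float:
        """Total particle surface area per suspension volume, m^2 m^-3 = m^-1."""
        return self.number_density * np.pi * self.d0**2

    @property
    def total_metal_molarity(self) -> float:
        """Total metal (Cu+Fe) content of the suspension, mol m^-3."""
        return self.mass_conc / self.molar_mass

    @property
    def total_cu_molarity(self) -> float:
        """Total copper content of the suspension, mol m^-3."""
        return (1.0 - self.f_fe0) * self.total_metal_molarity


@dataclass(frozen=True)
class MediumSpec:
    """Amino-acid dissolution medium.

    Cu2+ and amino acid complex with stoichiometry ``nu`` amino acids
    per copper ion (2 at physiological pH), so dissolved copper depletes
    the free amino-acid pool as c_AA(t) = c_AA0 - nu * c_Cu(t).
    """

    amino_acid: str = "valine"
    c_aa0: float = 5.0  # mol m^-3 == 5 mM
    nu: float = 2.0
    #: if True, the amino acid is treated as an infinite reservoir
    excess: bool = False

    def __post_init__(self) -> None:
        if self.c_aa0 < 0:
            raise ValueError("c_aa0 must be non-negative")
        if not (self.nu > 0):
            raise ValueError("nu must be positive")


@dataclass(frozen=True)
class Inventory:
    """Derived molar/geometric inventories of one suspension condition."""

    number_density: float  # m^-3
    area_per_volume: float  # m^-1
    total_metal_molarity: float  # mol m^-3
    total_cu_molarity: float  # mol m^-3
    surface_site_molarity: float  # mol m^-3, k_site * area

    fields: tuple = field(
        default=(
            "number_density",
            "area_per_volume",
            "total_metal_molarity",
            "total_cu_molarity",
            "surface_site_molarity",
        ),
        repr=False,
        compare=False,
    )


def copper_inventories(particle: ParticleSystem, k_site: float = DEFAULT_K_SITE) -> Inventory:
    """Compute the molar inventories of a suspension condition.

    The surface-site molarity is k_site * A0 where A0 is the total
    particle surface area per suspension volume; all quantities scale
    linearly with the mass concentration.
    """
    if not (k_site > 0):
        raise ValueError("k_site must be positive")
    return Inventory(
        number_density=particle.number_density,
        area_per_volume=particle.area_per_volume,
        total_metal_molarity=particle.total_metal_molarity,
        total_cu_molarity=particle.total_cu_molarity,
        surface_site_molarity=k_site * particle.area_per_volume,
    )
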