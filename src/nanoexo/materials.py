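"""Surface free-energy components and acid-base combining rules.

A material phase (nanoparticle coating, cell/vesicle surface, or the aqueous
medium) is characterised in the van Oss-Chaudhury-Good convention by three
surface free-energy components, all in mJ/m^2:

* ``gamma_lw`` -- the apolar Lifshitz-van der Waals component,
* ``gamma_plus`` -- the electron-acceptor (Lewis acid) parameter,
* ``gamma_minus`` -- the electron-donor (Lewis base) parameter,

plus an optional surface potential ``psi0`` in mV for the electrostatic
double-layer term.  The polar (acid-base) component is derived,
``gamma_ab = 2*sqrt(gamma_plus * gamma_minus)``.

The two ``contact_*`` functions give the interfacial free energy *per unit
area* of two half-spaces of materials 1 and 2 brought to contact distance
across medium 3.  They are the boundary values that the distance-resolved
XDLVO engine (:mod:`nanoexo.xdlvo`) scales into per-particle energy profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SurfaceChemistry",
    "MediumSpec",
    "WATER",
    "gamma_ab",
    "contact_lw",
    "contact_ab",
]


def _check_nonnegative(value: float, name: str) -> None:
    if value < 0:
        raise ValueError(f"surface-energy component {name!r} must be >= 0, got {value}")


@dataclass(frozen=True)
class SurfaceChemistry:
    """Surface free-energy components of one material phase.

    Parameters
    ----------
    name : str
        Label (coating identity, "cell", "water", ...).
    gamma_lw : float
        Lifshitz-van der Waals component, mJ/m^2.
    gamma_plus : float
        Electron-acceptor component, mJ/m^2.
    gamma_minus : float
        Electron-donor component, mJ/m^2.
    psi0 : float, optional
        Surface potential, mV.  Defaults to 0 (neutral surface).
    """

    name: str
    gamma_lw: float
    gamma_plus: float
    gamma_minus: float
    psi0: float = 0.0

    def __post_init__(self) -> None:
        _check_nonnegative(self.gamma_lw, "gamma_lw")
        _check_nonnegative(self.gamma_plus, "gamma_plus")
        _check_nonnegative(self.gamma_minus, "gamma_minus")

    @property
    def gamma_ab(self) -> float:
        """Derived acid-base (polar) component, mJ/m^2."""
        return gamma_ab(self.gamma_plus, self.gamma_minus)

    def with_psi0(self, psi0: float) -> "SurfaceChemistry":
        return replace(self, psi0=psi0)


#: Water in the van Oss convention (20-25 degC reference values), the default
#: suspending medium.  gamma_ab = 2*sqrt(25.5*25.5) = 51 mJ/m^2.
WATER = SurfaceChemistry("water", gamma_lw=21.8, gamma_plus=25.5, gamma_minus=25.5)


@dataclass(frozen=True)
class MediumSpec:
    """Aqueous medium for the electrostatic and thermal terms.

    ``debye_length`` defaults to 0.78 nm, the screening length of a 1:1
    electrolyte at physiological ionic strength (0.154 M) and 310 K;
    ``relative_permittivity`` defaults to 74 (water at 310 K).
    """

    chemistry: SurfaceChemistry = field(default=WATER)
    relative_permittivity: float = 74.0
    debye_length: float = 0.78  # nm
    temperature: float = 310.0  # K

    def __post_init__(self) -> None:
        if self.debye_length <= 0:
            raise ValueError(f"debye_length must be > 0, got {self.debye_length}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if self.relative_permittivity <= 0:
            raise ValueError(
                f"relative_permittivity must be > 0, got {self.relative_permittivity}"
            )


def gamma_ab(gamma_plus: float, gamma_minus: float) -> float:
    """Acid-base surface free-energy component, mJ/m^2.

    ``gamma_ab = 2 * sqrt(gamma_plus * gamma_minus)`` (van Oss combining
    rule).  Symmetric in its arguments; zero for monopolar or apolar
    materials.
    """
    _check_nonnegative(gamma_plus, "gamma_plus")
    _check_nonnegative(gamma_minus, "gamma_minus")
    return 2.0 * math.sqrt(gamma_plus * gamma_minus)


def contact_lw(
    material1: SurfaceChemistry,
    material2: SurfaceChemistry,
    medium: SurfaceChemistry,
) -> float:
    """Lifshitz-van der Waals free energy per unit area at contact, mJ/m^2.

    ``dG_LW(d0) = 2 (sqrt(g3) - sqrt(g1)) (sqrt(g2) - sqrt(g3))`` with
    ``g_i = gamma_lw`` of material 1, material 2 and medium 3.  Symmetric
    under swap of the two materials; for identical materials it reduces to
    ``-2 (sqrt(g1) - sqrt(g3))^2 <= 0`` (self-attraction across a medium).
    """
    s1 = math.sqrt(material1.gamma_lw)
    s2 = math.sqrt(material2.gamma_lw)
    s3 = math.sqrt(medium.gamma_lw)
    return 2.0 * (s3 - s1) * (s2 - s3)


def contact_ab(
    material1: SurfaceChemistry,
    material2: SurfaceChemistry,
    medium: SurfaceChemistry,
) -> float:
    """Lewis acid-base free energy per unit area at contact, mJ/m^2.

    Dual-parameter van Oss combining rule::

        dG_AB(d0) = 2 [ sqrt(g3+) (sqrt(g1-) + sqrt(g2-) - sqrt(g3-))
                      + sqrt(g3-) (sqrt(g1+) + sqrt(g2+) - sqrt(g3+))
                      - sqrt(g1+ g2-) - sqrt(g1- g2+) ]

    Positive values denote hydrophilic repulsion across the medium, negative
    values hydrophobic attraction.
    """
    p1, m1 = math.sqrt(material1.gamma_plus), math.sqrt(material1.gamma_minus)
    p2, m2 = math.sqrt(material2.gamma_plus), math.sqrt(material2.gamma_minus)
    p3, m3 = math.sqrt(medium.gamma_plus), math.sqrt(medium.gamma_minus)
    return 2.0 * (
        p3 * (m1 + m2 - m3)
        + m3 * (p1 + p2 - p3)
        - p1 * m2
        - m1 * p2
    )
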