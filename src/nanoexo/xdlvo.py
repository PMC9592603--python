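"""Distance-resolved XDLVO interaction-energy profiles.

Extended-DLVO theory sums three contributions to the interaction energy of
two colloidal bodies across an aqueous medium: Lifshitz-van der Waals (LW),
electrostatic double layer (EL) and Lewis acid-base (AB).  Here the bodies
are a coated nanoparticle and its transport vesicle (sphere-sphere) or a
vesicle and the cell membrane (sphere-plate).  Distance laws (Derjaguin
scaling in the effective radius ``R_eff``):

* LW:  ``U(d) = 2 pi R_eff d0^2 dG_LW(d0) / d``  (unretarded 1/d tail),
* AB:  ``U(d) = 2 pi R_eff lambda dG_AB(d0) exp((d0 - d)/lambda)``,
* EL:  constant-potential Hogg-Healey-Fuerstenau form,
  ``U(d) = pi eps0 epsr R_eff [ 2 psi1 psi2 ln((1+e^-kd)/(1-e^-kd))
  + (psi1^2 + psi2^2) ln(1 - e^-2kd) ]``.

``d0 = 0.157 nm`` is the minimum contact distance, ``lambda = 0.6 nm`` the
AB decay length in water, and ``1/k`` the Debye screening length.  Contact
free energies per unit area come from :mod:`nanoexo.materials`; per-particle
energies (J) are multiplied by Avogadro's number and reported in kJ/mol.

The exocytosis energy change is ``dG(d) = dG‡_v/m - dG_np/v``: the barrier a
vesicle must cross to fuse with the membrane, minus the (repulsive) NP-vesicle
interaction energy released when the particle desorbs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .materials import MediumSpec, SurfaceChemistry, contact_ab, contact_lw

__all__ = [
    "PairKind",
    "GeometryPair",
    "XdlvoParameters",
    "InteractionProfile",
    "Barrier",
    "InteractionSummary",
    "VesicleRule",
    "energy_profile",
    "np_vesicle_energy",
    "barrier_height",
    "interaction_summary",
]

_EPS0 = 8.8541878128e-12  # F/m
_AVOGADRO = 6.02214076e23  # /mol
_NM = 1e-9


class PairKind(str, enum.Enum):
    SPHERE_SPHERE = "sphere_sphere"
    SPHERE_PLATE = "sphere_plate"


@dataclass(frozen=True)
class GeometryPair:
    """Geometry of one interacting pair; radii in nm.

    For ``sphere_plate`` the sphere is ``radius1`` and ``radius2`` is ignored.
    """

    kind: PairKind
    radius1: float
    radius2: float = 0.0

    def __post_init__(self) -> None:
        if self.radius1 <= 0:
            raise ValueError(f"radius1 must be > 0, got {self.radius1}")
        if self.kind is PairKind.SPHERE_SPHERE and self.radius2 <= 0:
            raise ValueError(f"radius2 must be > 0 for sphere_sphere, got {self.radius2}")

    @property
    def r_eff(self) -> float:
        """Derjaguin effective radius, nm."""
        if self.kind is PairKind.SPHERE_PLATE:
            return self.radius1
        return self.radius1 * self.radius2 / (self.radius1 + self.radius2)


@dataclass(frozen=True)
class XdlvoParameters:
    """Numerical parameters of the profile grid (all lengths in nm)."""

    d0: float = 0.157
    lambda_ab: float = 0.6
    d_max: float = 20.0
    n_grid: int = 2000

    def __post_init__(self) -> None:
        if not (0 < self.d0 < self.d_max):
            raise ValueError(f"require 0 < d0 < d_max, got d0={self.d0}, d_max={self.d_max}")
        if self.lambda_ab <= 0:
            raise ValueError(f"lambda_ab must be > 0, got {self.lambda_ab}")
        if self.n_grid < 100:
            raise ValueError(f"n_grid must be >= 100, got {self.n_grid}")


@dataclass(frozen=True)
class InteractionProfile:
    """Per-component interaction energies on a distance grid.

    ``distances`` in nm; ``lw``, ``el``, ``ab`` and ``total`` in kJ/mol,
    with ``total = lw + el + ab`` at every grid point by construction.
    """

    distances: np.ndarray
    lw: np.ndarray
    el: np.ndarray
    ab: np.ndarray
    total: np.ndarray


@dataclass(frozen=True)
class Barrier:
    """Maximum of a vesicle-membrane profile (kJ/mol) and its position (nm)."""

    height: float
    distance: float
    exists: bool


@dataclass(frozen=True)
class InteractionSummary:
    """Energetics of one NP-cell pair (the Table-1-style row), kJ/mol."""

    dg_np_v: float
    dg_barrier_v_m: float
    dg_change: float
    barrier_distance: float = math.nan
    barrier_exists: bool = True


@dataclass(frozen=True)
class VesicleRule:
    """How the transport-vesicle radius follows the NP radius.

    Default: the vesicle tightly wraps a single NP, so its radius equals the
    NP radius; ``membrane_offset`` (nm) adds a fixed shell on top.
    """

    membrane_offset: float = 0.0

    def vesicle_radius(self, np_radius: float) -> float:
        return np_radius + self.membrane_offset


def _per_mole(energy_j: np.ndarray) -> np.ndarray:
    return energy_j * _AVOGADRO / 1e3  # J/particle -> kJ/mol


def energy_profile(
    pair: GeometryPair,
    material1: SurfaceChemistry,
    material2: SurfaceChemistry,
    medium: MediumSpec,
    params: XdlvoParameters = XdlvoParameters(),
) -> InteractionProfile:
    """Compute LW/EL/AB energy profiles for one geometry pair.

    Energies are per mole of particles (kJ/mol) on the grid
    ``[d0, d_max]`` with ``n_grid`` points.  The EL term uses the surface
    potentials ``psi0`` (mV) of the two materials under constant-potential
    boundary conditions; it is identically zero when both are uncharged.
    """
    d = np.linspace(params.d0, params.d_max, params.n_grid)  # nm
    r_eff_m = pair.r_eff * _NM
    d_m = d * _NM
    d0_m = params.d0 * _NM
    lam_m = params.lambda_ab * _NM

    dg_lw = contact_lw(material1, material2, medium.chemistry) * 1e-3  # J/m^2
    dg_ab = contact_ab(material1, material2, medium.chemistry) * 1e-3

    lw = _per_mole(2.0 * math.pi * r_eff_m * d0_m**2 * dg_lw / d_m)
    ab = _per_mole(
        2.0 * math.pi * r_eff_m * lam_m * dg_ab * np.exp((d0_m - d_m) / lam_m)
    )

    psi1 = material1.psi0 * 1e-3  # mV -> V
    psi2 = material2.psi0 * 1e-3
    if psi1 == 0.0 and psi2 == 0.0:
        el = np.zeros_like(d)
    else:
        kappa_d = d / medium.debye_length  # dimensionless, nm grid
        e_kd = np.exp(-kappa_d)
        el_j = (
            math.pi
            * _EPS0
            * medium.relative_permittivity
            * r_eff_m
            * (
                2.0 * psi1 * psi2 * np.log((1.0 + e_kd) / (1.0 - e_kd))
                + (psi1**2 + psi2**2) * np.log(1.0 - e_kd**2)
            )
        )
        el = _per_mole(el_j)

    return InteractionProfile(distances=d, lw=lw, el=el, ab=ab, total=lw + el + ab)


def np_vesicle_energy(profile: InteractionProfile) -> float:
    """NP-vesicle interaction energy: the maximum of the total profile, kJ/mol.

    For a monotonically decaying repulsive profile this is the contact
    (``d0``) value.  Ties resolve to the smallest distance via argmax.
    """
    if profile.total.size == 0:
        raise ValueError("empty interaction profile")
    return float(profile.total.max())


def barrier_height(profile: InteractionProfile) -> Barrier:
    """Vesicle-membrane energy barrier: profile maximum floored at zero.

    A purely attractive profile (max <= 0) has no barrier to fusion; the
    height is reported as 0 with ``exists=False`` so the activation term of
    the exocytosis energy change stays non-negative.
    """
    if profile.total.size == 0:
        raise ValueError("empty interaction profile")
    i = int(np.argmax(profile.total))  # first index wins at ties
    height = float(profile.total[i])
    if height <= 0.0:
        return Barrier(height=0.0, distance=float(profile.distances[i]), exists=False)
    return Barrier(height=height, distance=float(profile.distances[i]), exists=True)


def interaction_summary(
    np_chemistry: SurfaceChemistry,
    np_radius: float,
    cell: SurfaceChemistry,
    medium: MediumSpec,
    params: XdlvoParameters = XdlvoParameters(),
    vesicle_rule: VesicleRule = VesicleRule(),
) -> InteractionSummary:
    """Full energetics of one NP against one (generic) cell.

    The transport vesicle shares the cell-membrane chemistry (vesicles fuse
    with the membrane during exocytosis) and its radius follows
    ``vesicle_rule``.  Two profiles are computed -- NP-vesicle
    (sphere-sphere) and vesicle-membrane (sphere-plate) -- and reduced to
    ``dg_np_v`` (profile maximum), ``dg_barrier_v_m`` (barrier height) and
    ``dg_change = dg_barrier_v_m - dg_np_v``.
    """
    r_v = vesicle_rule.vesicle_radius(np_radius)

    npv = energy_profile(
        GeometryPair(PairKind.SPHERE_SPHERE, np_radius, r_v),
        np_chemistry,
        cell,
        medium,
        params,
    )
    vm = energy_profile(
        GeometryPair(PairKind.SPHERE_PLATE, r_v),
        cell,
        cell,
        medium,
        params,
    )

    dg_np_v = np_vesicle_energy(npv)
    barrier = barrier_height(vm)
    return InteractionSummary(
        dg_np_v=dg_np_v,
        dg_barrier_v_m=barrier.height,
        dg_change=barrier.height - dg_np_v,
        barrier_distance=barrier.distance,
        barrier_exists=barrier.exists,
    )
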