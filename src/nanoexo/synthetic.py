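"""Seeded synthetic panels, rate datasets and exocytosis curves.

Everything downstream of the surface-energy inputs is testable without
external data: a synthetic NP panel spans the property ranges of the
materials actually studied (organically coated gold NPs and quantum dots,
8-100 nm, gamma_lw 20-45, gamma_plus 0-6, gamma_minus 10-75 mJ/m^2), a
synthetic cell dataset places ln(k_exo) on a known Arrhenius line with
Gaussian noise, and synthetic exocytosis curves follow the plateau-decay
model with additive Gaussian noise on the normalized amounts.  All
generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Dataset, NanoparticleSpec, SizeType
from .kinetics import ExocytosisTimeSeries
from .materials import SurfaceChemistry

__all__ = [
    "SyntheticSpec",
    "generate_np_panel",
    "generate_cell_dataset",
    "generate_exocytosis_series",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth configuration of the synthetic world.

    Defaults mirror the studied system: property ranges of the coated-NP
    panel, and the fitted Hela Arrhenius line (beta = -0.0017 mol/kJ,
    lnA = -7.3) as the true rate law.  ``ln_noise_sd`` is the Gaussian
    scatter of ln(k_exo) around that line; ``curve_noise_sd`` the additive
    noise on normalized amounts.
    """

    seed: int = 0
    n_nps: int = 10
    gamma_lw_range: tuple[float, float] = (20.0, 45.0)
    gamma_plus_range: tuple[float, float] = (0.0, 6.0)
    gamma_minus_range: tuple[float, float] = (10.0, 75.0)
    size_range: tuple[float, float] = (8.0, 100.0)
    true_beta: float = -0.0017
    true_ln_a: float = -7.3
    ln_noise_sd: float = 0.3
    curve_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.n_nps < 3:
            raise ValueError(f"n_nps must be >= 3, got {self.n_nps}")
        for nm in ("gamma_lw_range", "gamma_plus_range", "gamma_minus_range", "size_range"):
            lo, hi = getattr(self, nm)
            if not (0 <= lo < hi):
                raise ValueError(f"{nm} must be a non-empty non-negative interval, got ({lo}, {hi})")


def generate_np_panel(spec: SyntheticSpec, cell_line: str = "synthetic_cell") -> Dataset:
    """Draw a reproducible NP panel spanning the requested property ranges."""
    rng = np.random.default_rng(spec.seed)
    nps = []
    for i in range(spec.n_nps):
        chem = SurfaceChemistry(
            name=f"syn-coat-{i:02d}",
            gamma_lw=float(rng.uniform(*spec.gamma_lw_range)),
            gamma_plus=float(rng.uniform(*spec.gamma_plus_range)),
            gamma_minus=float(rng.uniform(*spec.gamma_minus_range)),
            psi0=0.0,  # neutral NPs, as in the training data
        )
        nps.append(
            NanoparticleSpec(
                np_id=f"SYN{i:02d}",
                coating=chem.name,
                diameter_nm=float(rng.uniform(*spec.size_range)),
                size_type=SizeType.HYDRODYNAMIC,
                chemistry=chem,
                cell_line=cell_line,
            )
        )
    return Dataset(nanoparticles=nps, provenance=f"synthetic(seed={spec.seed})")


def generate_cell_dataset(
    spec: SyntheticSpec, dg_values: "np.ndarray | list[float]"
) -> list[tuple[float, float]]:
    """Place (dG, k_exo) points on the true Arrhenius line with ln-scale noise.

    ``k_exo = exp(true_beta * dG + true_ln_a + eps)`` with
    ``eps ~ N(0, ln_noise_sd)``.  Refuses a degenerate (constant) design.
    """
    dg = np.asarray(dg_values, dtype=float)
    if dg.size < 2 or np.ptp(dg) == 0:
        raise ValueError("dg_values must be non-degenerate (at least two distinct values)")
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.ln_noise_sd, size=dg.size) if spec.ln_noise_sd > 0 else np.zeros(dg.size)
    k = np.exp(spec.true_beta * dg + spec.true_ln_a + eps)
    return list(zip(dg.tolist(), k.tolist()))


def generate_exocytosis_series(
    k: float,
    np_eq: float,
    times_h: "np.ndarray | list[float]",
    noise_sd: float = 0.0,
    seed: int = 0,
    cell_line: str = "synthetic_cell",
    np_id: str = "SYN",
) -> ExocytosisTimeSeries:
    """Simulate a plateau-decay exocytosis curve.

    ``amounts = (1 - np_eq) exp(-k t) + np_eq`` plus seeded Gaussian noise
    (never applied at t=0, so the series stays normalized), floored at 0.
    ``k`` in /s, times in hours.
    """
    if k < 0:
        raise ValueError(f"rate constant must be >= 0, got {k}")
    if np_eq < 0:
        raise ValueError(f"np_eq must be >= 0, got {np_eq}")
    t = np.asarray(times_h, dtype=float)
    amounts = (1.0 - np_eq) * np.exp(-k * t * 3600.0) + np_eq
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=t.size)
        noise[0] = 0.0
        amounts = np.clip(amounts + noise, 0.0, None)
    return ExocytosisTimeSeries(times=t, amounts=amounts, cell_line=cell_line, np_id=np_id)
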