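"""Per-cell-line Arrhenius regression of exocytosis rate constants.

The central relation is ``ln(k_exo) = beta * dG(d) + ln A``: across a panel
of nanoparticles seen by one cell line, the log exocytosis rate constant is
linear in the exocytosis energy change ``dG(d) = dG‡_v/m - dG_np/v``
(kJ/mol).  ``beta`` (mol/kJ) is fitted per cell line rather than pinned to
``-1/RT``: the Boltzmann factor of the raw NP-vesicle energies (hundreds to
thousands of kJ/mol at RT = 2.577 kJ/mol) would be astronomically small, so
the effective slope absorbs ligand-receptor binding, membrane deformation
and cell-specific traits the surface-energy description leaves out.  The
intercept ``A = exp(ln_a)`` (/s) is the generic frequency factor, decomposed
as ``A = A_vesicle * f`` where ``f = exp(-dG_np/v / RT)`` is the Boltzmann
fraction of vesicle-encapsulated particles.

Confidence intervals for predictions are the standard OLS mean-response
intervals on the ln scale (t quantiles, n-2 df), exponentiated; a
prediction-interval variant is available via ``interval="prediction"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GAS_CONSTANT_KJ",
    "CellLineModel",
    "Prediction",
    "VesiclePartition",
    "fit_cell_model",
    "predict_k_exo",
    "vesicle_fraction",
    "decompose_frequency",
    "gamma_kow_regression",
    "GammaKowRegression",
]

GAS_CONSTANT_KJ = 8.31446261815324e-3  # kJ/(mol K)


def rt_kj(temperature: float = 310.0) -> float:
    """Thermal energy RT in kJ/mol (2.577 at 310 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    return GAS_CONSTANT_KJ * temperature


@dataclass(frozen=True)
class CellLineModel:
    """Fitted ``ln(k_exo) = beta * dG + ln_a`` for one cell line.

    Carries everything needed to rebuild OLS intervals: the training-mean
    energy ``mean_dg``, the centered sum of squares ``ss_dg``, the residual
    variance (n-2 df) and the training range for extrapolation flagging.
    """

    cell_line: str
    beta: float  # mol/kJ
    ln_a: float  # ln(/s)
    beta_se: float
    ln_a_se: float
    r2: float
    p_value: float
    n: int
    residual_variance: float
    mean_dg: float
    ss_dg: float
    dg_min: float
    dg_max: float

    @property
    def frequency_factor(self) -> float:
        """A = exp(ln_a), /s."""
        return math.exp(self.ln_a)


@dataclass(frozen=True)
class Prediction:
    """Point prediction of k_exo (/s) with its interval on the rate scale."""

    k_exo: float
    lower: float
    upper: float
    extrapolated: bool


def fit_cell_model(
    points: Sequence[tuple[float, float]],
    cell_line: str = "",
) -> CellLineModel:
    """OLS of ln(k_exo) on dG(d) for one cell line.

    ``points`` are ``(dg_change kJ/mol, k_exo /s)`` pairs, all rates
    strictly positive, n >= 3.  Returns slope/intercept with standard
    errors, R^2 and the two-sided slope p-value (t distribution, n-2 df).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (dg_change, k_exo) pairs")
    n = pts.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 points to fit a cell-line model, got {n}")
    dg, k = pts[:, 0], pts[:, 1]
    if np.any(k <= 0):
        raise ValueError("all k_exo must be > 0 (rates enter on the ln scale)")
    if np.ptp(dg) == 0:
        raise ValueError("degenerate design: dg_change has zero variance")

    y = np.log(k)
    if np.ptp(y) == 0:  # flat response: slope 0 by convention, R^2 = 0
        return CellLineModel(
            cell_line=cell_line,
            beta=0.0,
            ln_a=float(y[0]),
            beta_se=0.0,
            ln_a_se=0.0,
            r2=0.0,
            p_value=1.0,
            n=n,
            residual_variance=0.0,
            mean_dg=float(dg.mean()),
            ss_dg=float(np.sum((dg - dg.mean()) ** 2)),
            dg_min=float(dg.min()),
            dg_max=float(dg.max()),
        )
    res = stats.linregress(dg, y)
    resid = y - (res.slope * dg + res.intercept)
    s2 = float(np.sum(resid**2) / (n - 2))
    return CellLineModel(
        cell_line=cell_line,
        beta=float(res.slope),
        ln_a=float(res.intercept),
        beta_se=float(res.stderr),
        ln_a_se=float(res.intercept_stderr),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=n,
        residual_variance=s2,
        mean_dg=float(dg.mean()),
        ss_dg=float(np.sum((dg - dg.mean()) ** 2)),
        dg_min=float(dg.min()),
        dg_max=float(dg.max()),
    )


def predict_k_exo(
    model: CellLineModel,
    dg_change: float,
    level: float = 0.95,
    interval: Literal["confidence", "prediction"] = "confidence",
) -> Prediction:
    """Predict k_exo (/s) at an energy change with a 95% (default) interval.

    The interval is computed on the ln scale -- mean-response by default,
    prediction interval with ``interval="prediction"`` -- and exponentiated;
    its width grows with ``|dg_change - mean_dg|``.  Predictions outside the
    training dG range carry ``extrapolated=True``.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    yhat = model.beta * dg_change + model.ln_a
    extra = 1.0 if interval == "prediction" else 0.0
    if model.n > 2 and model.ss_dg > 0:
        se = math.sqrt(
            model.residual_variance
            * (extra + 1.0 / model.n + (dg_change - model.mean_dg) ** 2 / model.ss_dg)
        )
        tq = stats.t.ppf(0.5 + level / 2.0, model.n - 2)
        half = tq * se
    else:
        half = 0.0
    return Prediction(
        k_exo=math.exp(yhat),
        lower=math.exp(yhat - half),
        upper=math.exp(yhat + half),
        extrapolated=not (model.dg_min <= dg_change <= model.dg_max),
    )


def vesicle_fraction(dg_np_v: float, temperature: float = 310.0) -> float:
    """Boltzmann fraction of NPs encapsulated by vesicles.

    ``f = exp(-dG_np/v / RT)``; lies in (0, 1] for repulsive (non-negative)
    NP-vesicle energies.  A negative energy is allowed but flagged, since the
    framework assumes purely repulsive NP-vesicle interactions.
    """
    if dg_np_v < 0:
        warnings.warn(
            f"dg_np_v = {dg_np_v} kJ/mol is attractive; vesicle fraction exceeds 1 "
            "(repulsive-interaction assumption violated)",
            stacklevel=2,
        )
    return math.exp(-dg_np_v / rt_kj(temperature))


@dataclass(frozen=True)
class VesiclePartition:
    """Decomposition A = A_vesicle * fraction of the frequency factor.

    ``fraction`` may underflow to 0 for the huge repulsive energies typical
    of this system; the log-scale fields stay finite and exact.
    """

    fraction: float
    a_vesicle: float  # /s (inf on overflow; use ln_a_vesicle)
    rt: float  # kJ/mol
    ln_fraction: float
    ln_a_vesicle: float

    def combined_rate(self, dg_barrier_v_m: float, dg_np_v: float) -> float:
        """Rate from the mechanistic chain: fraction * A_vesicle *
        exp(-(dG‡ - dG_np/v)/RT).  Evaluated in log space."""
        ln_k = (
            self.ln_fraction
            + self.ln_a_vesicle
            - (dg_barrier_v_m - dg_np_v) / self.rt
        )
        return math.exp(ln_k)


def decompose_frequency(
    model: CellLineModel,
    dg_np_v: float,
    temperature: float = 310.0,
) -> VesiclePartition:
    """Split the fitted frequency factor into vesicle fraction and A_vesicle.

    ``A_vesicle = exp(ln_a) / fraction``; computed in log space so the
    round-trip identity ``A_vesicle * fraction = exp(ln_a)`` holds even when
    the Boltzmann fraction underflows.
    """
    rt = rt_kj(temperature)
    ln_fraction = -dg_np_v / rt
    ln_a_vesicle = model.ln_a - ln_fraction
    try:
        a_vesicle = math.exp(ln_a_vesicle)
    except OverflowError:
        a_vesicle = math.inf
    return VesiclePartition(
        fraction=math.exp(ln_fraction) if ln_fraction < 700 else math.inf,
        a_vesicle=a_vesicle,
        rt=rt,
        ln_fraction=ln_fraction,
        ln_a_vesicle=ln_a_vesicle,
    )


@dataclass(frozen=True)
class GammaKowRegression:
    """OLS summary of log K_ow against one surface-energy component."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def gamma_kow_regression(
    records: Sequence[tuple[float, float]],
) -> GammaKowRegression:
    """Correlate a coating's surface-energy component with its log K_ow.

    ``records`` are ``(gamma_component mJ/m^2, log_kow)`` pairs, n >= 3.
    Surface-energy components and the octanol-water partition coefficient
    both express hydrophobicity; a strong correlation justifies gamma
    components as transport descriptors.
    """
    arr = np.asarray(records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (gamma, log_kow) pairs")
    res = stats.linregress(arr[:, 0], arr[:, 1])
    return GammaKowRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=arr.shape[0],
    )
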