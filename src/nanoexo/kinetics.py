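"""Exocytosis rate constants from intracellular-amount time series.

Exocytosis experiments start with loaded cells in NP-free medium and follow
the normalized intracellular amount ``[NP]_t/[NP]_0`` over time.  Two curve
models extract the first-order exocytosis rate constant ``k_exo`` (/s):

* plateau decay, ``y(t) = (y0 - y_eq) exp(-k t) + y_eq`` -- a fraction
  ``y_eq`` of the load is retained at equilibrium;
* pure first order, ``y(t) = y0 exp(-k t)`` (``y_eq = 0``).

When only initial and final amounts are available, the two-point estimate
``k = ln(initial/final)/duration`` applies.  Input times are in hours;
all returned rates are converted to /s.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "ExocytosisTimeSeries",
    "RateModel",
    "RateFit",
    "UnidentifiableRateError",
    "fit_plateau_decay",
    "fit_first_order",
    "two_point_rate",
]

SECONDS_PER_HOUR = 3600.0
_FLAT_RELATIVE_RANGE = 1e-6


class UnidentifiableRateError(ValueError):
    """The series carries no decay signal; k_exo cannot be identified."""


class RateModel(str, enum.Enum):
    PLATEAU = "plateau"
    FIRST_ORDER = "first_order"
    TWO_POINT = "two_point"


@dataclass(frozen=True)
class ExocytosisTimeSeries:
    """Normalized intracellular amounts over time for one NP/cell pair.

    ``times`` are hours, strictly increasing from 0; ``amounts`` are
    ``[NP]_t/[NP]_0`` (first value 1 within tolerance, all non-negative).
    """

    times: np.ndarray
    amounts: np.ndarray
    cell_line: str = ""
    np_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        amounts = np.asarray(self.amounts, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "amounts", amounts)
        if times.shape != amounts.shape or times.ndim != 1:
            raise ValueError("times and amounts must be 1-d arrays of equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(amounts < 0):
            raise ValueError("amounts must be non-negative")
        if amounts.size and not np.isclose(amounts[0], 1.0, atol=0.05):
            warnings.warn(
                f"first amount is {amounts[0]:.3f}, expected ~1 (normalized series)",
                stacklevel=3,
            )


@dataclass(frozen=True)
class RateFit:
    """Fitted exocytosis rate constant and diagnostics."""

    k_exo: float  # /s
    np_eq: float  # plateau fraction; 0 for first_order / two_point
    model: RateModel
    residual_norm: float
    stderr_k: float


def _is_flat(amounts: np.ndarray) -> bool:
    scale = np.max(np.abs(amounts))
    if scale == 0:
        return True
    return (np.max(amounts) - np.min(amounts)) / scale < _FLAT_RELATIVE_RANGE


def fit_plateau_decay(series: ExocytosisTimeSeries) -> RateFit:
    """Nonlinear least squares for the plateau model.

    Fits ``y(t) = (y0 - y_eq) exp(-k t) + y_eq`` with ``y0`` pinned to the
    first observation, ``k in (0, 1] /s`` and ``y_eq in [0, 1]``.  Initial
    guesses come from a log-linear fit of ``y - min(y)``.
    """
    t_s = series.times * SECONDS_PER_HOUR
    y = series.amounts
    if y.size < 4:
        raise ValueError(f"plateau fit needs >= 4 points, got {y.size}")
    if _is_flat(y):
        raise UnidentifiableRateError("series shows no decay; rate unidentifiable")

    y0 = y[0]

    def model(t, k, y_eq):
        return (y0 - y_eq) * np.exp(-k * t) + y_eq

    # log-linear starting point on the baseline-subtracted amounts
    eq0 = float(np.min(y))
    shifted = y - eq0
    pos = shifted > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t_s[pos], np.log(shifted[pos]), 1)[0]
        k0 = float(np.clip(-slope, 1e-10, 1.0))
    else:
        k0 = 1e-5
    try:
        popt, pcov = optimize.curve_fit(
            model,
            t_s,
            y,
            p0=[k0, min(eq0, 1.0)],
            bounds=([1e-12, 0.0], [1.0, 1.0]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise RuntimeError(f"plateau fit did not converge: {exc}") from exc
    k, y_eq = float(popt[0]), float(popt[1])
    resid = y - model(t_s, k, y_eq)
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    return RateFit(
        k_exo=k,
        np_eq=y_eq,
        model=RateModel.PLATEAU,
        residual_norm=float(np.linalg.norm(resid)),
        stderr_k=stderr,
    )


def fit_first_order(series: ExocytosisTimeSeries) -> RateFit:
    """First-order fit with the plateau fixed at zero.

    For strictly positive amounts this is the log-linear regression of
    ``ln(y/y0)`` on time through the origin; otherwise it falls back to a
    nonlinear fit of ``y0 exp(-k t)`` with a warning.
    """
    t_s = series.times * SECONDS_PER_HOUR
    y = series.amounts
    if y.size < 2:
        raise ValueError(f"first-order fit needs >= 2 points, got {y.size}")
    if _is_flat(y):
        raise UnidentifiableRateError("series shows no decay; rate unidentifiable")
    y0 = y[0]

    if np.all(y > 0):
        z = np.log(y / y0)
        denom = float(np.sum(t_s**2))
        if denom == 0:
            raise UnidentifiableRateError("all observations at t=0")
        k = float(-np.sum(t_s * z) / denom)
        resid = z + k * t_s
        dof = max(y.size - 1, 1)
        stderr = float(np.sqrt(np.sum(resid**2) / dof / denom))
    else:
        warnings.warn(
            "non-positive amounts present; falling back to nonlinear first-order fit",
            stacklevel=2,
        )
        popt, pcov = optimize.curve_fit(
            lambda t, k: y0 * np.exp(-k * t),
            t_s,
            y,
            p0=[1e-5],
            bounds=(1e-12, 1.0),
            maxfev=10000,
        )
        k = float(popt[0])
        resid = y - y0 * np.exp(-k * t_s)
        stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    k = max(k, 0.0)
    return RateFit(
        k_exo=k,
        np_eq=0.0,
        model=RateModel.FIRST_ORDER,
        residual_norm=float(np.linalg.norm(resid)),
        stderr_k=stderr,
    )


def two_point_rate(initial: float, final: float, duration_h: float) -> float:
    """Rate constant from initial and final amounts only.

    ``k = ln(initial/final) / duration`` in /s; requires ``final <= initial``
    (exocytosis only removes particles) and a strictly positive final amount.
    """
    if initial <= 0 or duration_h <= 0:
        raise ValueError("initial amount and duration must be > 0")
    if final == 0:
        raise ValueError("final amount is 0: rate is infinite")
    if final < 0:
        raise ValueError("final amount must be >= 0")
    if final > initial:
        raise ValueError(
            f"final amount {final} exceeds initial {initial}: negative rate "
            "(exocytosis assumption violated)"
        )
    return float(np.log(initial / final) / (duration_h * SECONDS_PER_HOUR))
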