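"""Standard-curve fitting and amplification-efficiency estimation.

A qPCR standard curve regresses Ct on log10(template dilution). For a
perfectly efficient reaction the template doubles each cycle, giving the
canonical slope of −1/log10(2) ≈ −3.32 cycles per ten-fold dilution.
The per-cycle amplification factor and percent efficiency follow from
the fitted slope:

    amplification = 10^(−1/slope)        (fold per cycle)
    efficiency%   = (amplification − 1) × 100
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["StandardCurve", "fit_standard_curve", "efficiency_from_slope"]


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct against log10 dilution with derived efficiency.

    ``efficiency_pct`` and ``amplification`` are NaN when the slope is
    non-negative (flagged via ``positive_slope``), where the efficiency
    relation has no physical meaning.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float
    amplification: float
    n_points: int
    positive_slope: bool = False


def efficiency_from_slope(slope: float) -> tuple[float, float]:
    """Convert a standard-curve slope to (amplification, efficiency %).

    Raises for ``slope >= 0``: a non-negative slope means Ct does not
    decrease with template amount and no efficiency is defined.
    """
    if not np.isfinite(slope) or slope >= 0:
        raise ValueError(f"slope must be negative, got {slope}")
    amplification = 10.0 ** (-1.0 / slope)
    return amplification, (amplification - 1.0) * 100.0


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of Ct on log10(dilution).

    ``points`` are (log10_dilution, ct) pairs; technical replicates at the
    same dilution enter as separate observations. Requires ≥ 3 distinct
    dilution levels. A fitted non-negative slope yields a curve with a
    warning and NaN efficiency rather than an error.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (log10_dilution, ct) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct dilution levels")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in dilutions")

    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    if fit.slope >= 0:
        warnings.warn(
            f"standard curve has non-negative slope {fit.slope:.4g}; "
            "efficiency undefined",
            stacklevel=2,
        )
        return StandardCurve(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=r2,
            efficiency_pct=float("nan"),
            amplification=float("nan"),
            n_points=len(x),
            positive_slope=True,
        )
    amp, eff = efficiency_from_slope(float(fit.slope))
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        efficiency_pct=eff,
        amplification=amp,
        n_points=len(x),
    )
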