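"""Chronic daily-exposure equations.

Non-carcinogenic exposure averages the dose over the exposure duration::

    EXPO = C · dissolution · DI · EF · ED / (BW · AT),   AT = ED · 365 day/yr

so ED cancels algebraically; it is kept in the expression for traceability
to the standard USEPA formulation.  Carcinogenic exposure averages over the
lifespan LT instead of ED, i.e. EXPO_cancer = EXPO · ED / LT.

With C in mg/kg (= µg/g) and DI in g/day the product C·DI is already in
µg/day, so EXPO comes out in µg/(kg·day) without an explicit factor.  The
single µg→mg conversion needed by the cancer slope factor is owned by
:func:`ug_to_mg`.
"""

from __future__ import annotations

import numpy as np

from .data_model import ExposureFactors
from .errors import DomainError

__all__ = [
    "daily_exposure",
    "cancer_exposure",
    "expo_noncancer",
    "expo_cancer",
    "ug_to_mg",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 365.0  # exact; no leap-year handling
_UG_PER_MG = 1000.0


def ug_to_mg(x):
    """Convert µg-scale quantities to mg; the only mg↔µg conversion point."""
    return np.asarray(x, dtype=float) / _UG_PER_MG if np.ndim(x) else float(x) / _UG_PER_MG


def _check_concentration(c) -> np.ndarray | float:
    arr = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise DomainError("concentration must be finite and ≥ 0")
    return arr if arr.ndim else float(arr)


def expo_noncancer(c, di, ef, ed, bw, dissolution=1.0):
    """Vectorized non-carcinogenic exposure kernel (broadcasts over arrays)."""
    at_days = np.multiply(ed, DAYS_PER_YEAR)
    return c * dissolution * di * ef * ed / (bw * at_days)


def expo_cancer(c, di, ef, ed, bw, lt, dissolution=1.0):
    """Vectorized lifetime-averaged (carcinogenic) exposure kernel."""
    return c * dissolution * di * ef * ed / (bw * lt * DAYS_PER_YEAR)


def daily_exposure(c, factors: ExposureFactors):
    """Non-carcinogenic chronic daily exposure, µg/(kg·day).

    Accepts a scalar or array concentration ``c`` in mg/kg and broadcasts.
    """
    c = _check_concentration(c)
    return expo_noncancer(
        c, factors.di, factors.ef, factors.ed, factors.bw, factors.dissolution
    )


def cancer_exposure(c, factors: ExposureFactors):
    """Lifetime-averaged carcinogenic daily exposure, µg/(kg·day).

    Equals ``daily_exposure(c) · ED / LT``.
    """
    c = _check_concentration(c)
    if factors.lt <= 0:
        raise DomainError("lifespan LT must be > 0")
    return expo_cancer(
        c, factors.di, factors.ef, factors.ed, factors.bw, factors.lt,
        factors.dissolution,
    )
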