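"""Hazard quotient / hazard index and carcinogenic-risk characterization.

HQ = EXPO / ADI for each chemical (both in µg/(kg·day)); HI sums HQs over
co-occurring chemicals assuming additive, non-interacting toxicity and is
partitioned by chemical class (HI_P pesticides, HI_M metals).  Lifetime
excess cancer probability R = SF × EXPO_cancer with the exposure converted
to mg/(kg·day) to match the slope factor's units.  Conventional thresholds:
HQ/HI of 1; R of 1e-6 (negligible) and 1e-4 (maximum acceptable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data_model import ChemicalSpec, ExposureFactors, METAL, PESTICIDE
from .errors import DomainError, EmptyDataError
from .exposure_engine import cancer_exposure, daily_exposure, ug_to_mg

__all__ = [
    "RiskResult",
    "hazard_quotient",
    "hazard_index",
    "carcinogenic_risk",
    "rank_risks",
    "classify",
    "compute_deterministic_risk",
    "HQ_THRESHOLD",
    "R_NEGLIGIBLE",
    "R_MAX_ACCEPTABLE",
]

HQ_THRESHOLD = 1.0
R_NEGLIGIBLE = 1e-6
R_MAX_ACCEPTABLE = 1e-4


@dataclass
class RiskResult:
    """Partitioned non-carcinogenic risk plus per-carcinogen R values."""

    hq: dict[str, float]
    hi_p: float
    hi_m: float
    hi_total: float
    share_p: float  # percent of hi_total
    share_m: float
    rankings: dict[str, list[str]] = field(default_factory=dict)
    r: dict[str, float] = field(default_factory=dict)


def hazard_quotient(expo: float, adi: float) -> float:
    """HQ = EXPO/ADI, both in µg/(kg·day)."""
    if not np.all(np.isfinite(adi)) or np.any(np.asarray(adi) <= 0):
        raise DomainError("ADI must be finite and > 0")
    return expo / adi


def carcinogenic_risk(expo_cancer: float, sf: float) -> float:
    """R = SF × EXPO_cancer, with exposure converted from µg to mg/(kg·day)."""
    if not np.all(np.isfinite(sf)) or np.any(np.asarray(sf) <= 0):
        raise DomainError("slope factor must be finite and > 0")
    return sf * ug_to_mg(expo_cancer)


def hazard_index(
    hqs: Mapping[str, float], registry: Mapping[str, ChemicalSpec]
) -> RiskResult:
    """Partition a per-chemical HQ map into HI_P, HI_M and HI_total.

    Shares are percent of HI_total and sum to exactly 100 (both zero when
    HI_total is zero).
    """
    if not hqs:
        raise EmptyDataError("empty HQ map")
    unknown = set(hqs) - set(registry)
    if unknown:
        raise KeyError(f"chemicals without registry entry: {sorted(unknown)}")
    hi_p = sum(q for c, q in hqs.items() if registry[c].chem_class == PESTICIDE)
    hi_m = sum(q for c, q in hqs.items() if registry[c].chem_class == METAL)
    hi_total = hi_p + hi_m
    if hi_total > 0:
        share_p = 100.0 * hi_p / hi_total
        share_m = 100.0 - share_p
    else:
        share_p = share_m = 0.0
    rankings = {}
    for cls in (PESTICIDE, METAL):
        members = {c: q for c, q in hqs.items() if registry[c].chem_class == cls}
        if members:
            rankings[cls] = rank_risks(members)
    return RiskResult(
        hq=dict(hqs),
        hi_p=hi_p,
        hi_m=hi_m,
        hi_total=hi_total,
        share_p=share_p,
        share_m=share_m,
        rankings=rankings,
    )


def rank_risks(hqs: Mapping[str, float]) -> list[str]:
    """Chemical ids in descending HQ order; ties broken lexicographically."""
    return [c for c, _ in sorted(hqs.items(), key=lambda kv: (-kv[1], kv[0]))]


def classify(value: float, kind: str = "hi") -> str:
    """Grade a risk metric against regulatory thresholds.

    ``kind='hq'``/``'hi'``: ``acceptable`` below 1, else ``concern``.
    ``kind='cancer'``: three levels — ``negligible`` below 1e-6,
    ``intermediate`` up to 1e-4, ``concern`` at or above 1e-4.
    """
    if value < 0 or not np.isfinite(value):
        raise DomainError("risk metrics must be finite and ≥ 0")
    if kind in ("hq", "hi"):
        return "acceptable" if value < HQ_THRESHOLD else "concern"
    if kind == "cancer":
        if value < R_NEGLIGIBLE:
            return "negligible"
        if value < R_MAX_ACCEPTABLE:
            return "intermediate"
        return "concern"
    raise ValueError(f"unknown kind {kind!r}")


def compute_deterministic_risk(
    mean_concentrations: Mapping[str, float],
    factors: ExposureFactors,
    registry: Mapping[str, ChemicalSpec],
) -> RiskResult:
    """Full deterministic chain: mean concentrations (mg/kg) → HQ/HI/R."""
    hqs = {}
    r = {}
    for chem_id, c in mean_concentrations.items():
        spec = registry[chem_id]
        expo = daily_exposure(c, factors)
        hqs[chem_id] = hazard_quotient(expo, spec.adi)
        if spec.carcinogenic:
            r[chem_id] = carcinogenic_risk(cancer_exposure(c, factors), spec.slope_factor)
    result = hazard_index(hqs, registry)
    result.r = r
    return result
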