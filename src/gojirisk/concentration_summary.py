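"""Per-chemical summary statistics of a concentration dataset.

Mirrors the conventions of printed residue-survey tables: mean ± SD over
all n samples (censored values substituted per the active ND policy),
min–max range (min reported as ``ND`` when any censored record exists),
detection rate in percent, and a screen of the mean against the maximum
residue limit (MRL).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import ChemicalSpec, ConcentrationDataset, nd_substitute
from .errors import EmptyDataError

__all__ = ["ConcentrationSummary", "summarize", "screen_mrl", "summarize_all"]


@dataclass(frozen=True)
class ConcentrationSummary:
    chem_id: str
    source: str
    n: int
    mean: float  # mg/kg, ND substituted per policy
    sd: float  # sample (n−1) standard deviation, mg/kg
    min: float  # mg/kg on the substituted scale; display layer prints ND
    max: float
    detection_rate: float  # percent of samples with value ≥ LOD
    exceeds_mrl: bool
    any_censored: bool


def summarize(
    dataset: ConcentrationDataset,
    chem: ChemicalSpec,
    nd_policy: str = "zero",
) -> ConcentrationSummary:
    """Summarize one chemical in one dataset.

    A record counts as *detected* iff it is not censored and its value is at
    or above the LOD — a nominally detected record below the LOD does not
    count.  The detection rate is therefore invariant to the ND policy,
    while mean/SD/min/max are computed on the substituted values.
    """
    records = dataset.records_for(chem.chem_id)
    n = len(records)
    if n == 0:
        raise EmptyDataError(f"no records for {chem.chem_id} in {dataset.source}")
    sub = nd_substitute(nd_policy, chem.lod)
    values = np.array([sub if r.censored else r.value for r in records], dtype=float)
    detected = sum(1 for r in records if not r.censored and r.value >= chem.lod)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return ConcentrationSummary(
        chem_id=chem.chem_id,
        source=dataset.source,
        n=n,
        mean=mean,
        sd=sd,
        min=float(values.min()),
        max=float(values.max()),
        detection_rate=100.0 * detected / n,
        exceeds_mrl=mean > chem.mrl,
        any_censored=any(r.censored for r in records),
    )


def screen_mrl(summary: ConcentrationSummary, chem: ChemicalSpec) -> bool:
    """True iff the summarized mean strictly exceeds the MRL."""
    if summary.chem_id != chem.chem_id:
        raise ValueError(
            f"summary is for {summary.chem_id}, spec for {chem.chem_id}"
        )
    return summary.mean > chem.mrl


def summarize_all(
    dataset: ConcentrationDataset,
    registry: Mapping[str, ChemicalSpec],
    nd_policy: str = "zero",
) -> pd.DataFrame:
    """One summary row per chemical present in the dataset."""
    rows = []
    for chem_id in dataset.chemicals():
        s = summarize(dataset, registry[chem_id], nd_policy)
        rows.append(
            {
                "chemical": s.chem_id,
                "source": s.source,
                "n": s.n,
                "mean_mg_per_kg": s.mean,
                "sd_mg_per_kg": s.sd,
                "min_mg_per_kg": s.min,
                "max_mg_per_kg": s.max,
                "detection_rate_pct": s.detection_rate,
                "exceeds_mrl": s.exceeds_mrl,
                "any_censored": s.any_censored,
            }
        )
    return pd.DataFrame(rows)
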