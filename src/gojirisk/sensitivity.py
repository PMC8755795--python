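"""Contribution-to-variance sensitivity analysis.

Attributes output variance to model inputs by normalized squared Spearman
rank correlation: share_i = 100·ρ_i² / Σ_j ρ_j², the convention used by
spreadsheet Monte Carlo tools for their "contribution to variance" charts.
Being rank-based, shares are invariant under strictly monotone transforms
of any input; shares are non-negative and sum to exactly 100.  The signed
rank correlation is reported alongside for tornado-style output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SensitivityError

__all__ = ["SensitivityResult", "contribution_to_variance"]


@dataclass
class SensitivityResult:
    output_name: str
    shares: dict[str, float]  # percent, sums to 100
    correlations: dict[str, float]  # signed Spearman rho
    ordering: list[str]  # inputs sorted by descending share

    def top(self, k: int) -> list[str]:
        return self.ordering[:k]


def contribution_to_variance(
    inputs: pd.DataFrame, output, output_name: str = "output"
) -> SensitivityResult:
    """Normalized squared-rank-correlation shares of one output.

    Constant input columns get share 0; if every input is constant (or the
    output carries no rank variation at all) the decomposition is
    undefined and a :class:`SensitivityError` is raised.
    """
    output = np.asarray(output, dtype=float)
    if len(inputs) != output.size:
        raise ValueError("input matrix rows must align with the output vector")
    rhos: dict[str, float] = {}
    any_varying = False
    for col in inputs.columns:
        x = inputs[col].to_numpy()
        if np.unique(x).size < 2:
            rhos[col] = 0.0
            continue
        any_varying = True
        rho = stats.spearmanr(x, output).statistic
        rhos[col] = 0.0 if not np.isfinite(rho) else float(rho)
    if not any_varying:
        raise SensitivityError("all inputs are constant; sensitivity is undefined")
    total = sum(r * r for r in rhos.values())
    if total == 0:
        raise SensitivityError(
            "no input shows rank correlation with the output; shares undefined"
        )
    shares = {c: 100.0 * r * r / total for c, r in rhos.items()}
    ordering = [c for c, _ in sorted(shares.items(), key=lambda kv: (-kv[1], kv[0]))]
    return SensitivityResult(
        output_name=output_name, shares=shares, correlations=rhos, ordering=ordering
    )
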