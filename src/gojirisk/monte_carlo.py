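"""Monte Carlo propagation of input distributions through the risk equations.

Each model input — one concentration per chemical plus the exposure factors
DI, EF, ED and BW — is represented by a sampler: a fitted parametric
distribution, a censored mixture (a detection-probability spike at the ND
substitute plus a parametric family for detected values), an empirical
resample, or a fixed scalar.  Inputs are sampled independently (no rank
correlation is induced), pushed through the exposure/HQ/HI/R chain per
trial, and summarized as empirical percentiles plus a fitted output
distribution.

Truncation policy: concentration draws are truncated at 0, EF draws are
clipped to [1, 365] day/yr and BW is floored at a small positive value so
the dose denominator stays physical.  Output trials are never truncated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .data_model import (
    ChemicalSpec,
    ConcentrationDataset,
    RiskConfig,
    DEFAULT_LIFESPAN_YEARS,
    PESTICIDE,
    nd_substitute,
)
from .concentration_summary import summarize
from .distribution_fitting import (
    FittedDistribution,
    MIN_FIT_SIZE,
    select_best,
)
from .errors import (
    ConfigurationError,
    EmptyDataError,
    FitError,
    GojiRiskError,
    InsufficientDataError,
    NoFitError,
)
from .exposure_engine import expo_cancer, expo_noncancer, ug_to_mg

__all__ = [
    "FixedInput",
    "EmpiricalInput",
    "CensoredMixtureInput",
    "MCResult",
    "ProbabilisticRun",
    "sample_inputs",
    "run_probabilistic_risk",
    "summarize_percentiles",
    "exceedance_probability",
    "concentration_input_from_data",
    "concentration_inputs_from_dataset",
    "factor_inputs_from_survey",
]


@dataclass(frozen=True)
class FixedInput:
    """A degenerate input held at a constant value."""

    value: float

    def sample(self, rng, size: int) -> np.ndarray:
        return np.full(size, float(self.value))

    def mean(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class EmpiricalInput:
    """Resampling fallback for inputs whose parametric fit is unavailable."""

    values: tuple[float, ...]

    def sample(self, rng, size: int) -> np.ndarray:
        arr = np.asarray(self.values, dtype=float)
        return rng.choice(arr, size=size, replace=True)

    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class CensoredMixtureInput:
    """Detected-value family mixed with a below-LOD spike.

    With probability ``detection_prob`` a trial draws from the fitted
    detected-value distribution, otherwise it takes the ND substitute.
    Keeps both the detection rate and the overall mean of censored
    concentration data.
    """

    detection_prob: float
    fitted: FittedDistribution
    nd_value: float = 0.0

    def sample(self, rng, size: int) -> np.ndarray:
        detected = rng.random(size) < self.detection_prob
        draws = self.fitted.sample(rng, size)
        return np.where(detected, draws, self.nd_value)

    def mean(self) -> float:
        p = self.detection_prob
        return p * self.fitted.mean() + (1 - p) * self.nd_value


InputLike = Union[FixedInput, EmpiricalInput, CensoredMixtureInput, FittedDistribution]


def _as_input(spec) -> InputLike:
    if isinstance(spec, (int, float)):
        return FixedInput(float(spec))
    if hasattr(spec, "sample") and hasattr(spec, "mean"):
        return spec
    raise ConfigurationError(f"cannot interpret {spec!r} as a model input")


def _clip_for(name: str, draws: np.ndarray) -> np.ndarray:
    if name.startswith("C:"):
        return np.maximum(draws, 0.0)  # concentrations cannot be negative
    if name == "EF":
        return np.clip(draws, 1.0, 365.0)
    if name == "BW":
        return np.maximum(draws, 1e-6)  # keep the dose denominator physical
    return draws


def sample_inputs(
    inputs: Mapping[str, InputLike], n_iter: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw an (n_iter × n_inputs) trial matrix, columns sorted by name.

    Sampling is independent across inputs and bitwise reproducible for a
    given seed and input set.
    """
    if n_iter < 1000:
        raise ConfigurationError("n_iter must be ≥ 1000")
    if not inputs:
        raise ConfigurationError("no model inputs supplied")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    columns = {}
    for name in sorted(inputs):
        draws = _as_input(inputs[name]).sample(rng, n_iter)
        columns[name] = _clip_for(name, np.asarray(draws, dtype=float))
    return pd.DataFrame(columns)


def summarize_percentiles(trials, percentiles: Sequence[float]) -> dict[float, float]:
    """Empirical quantiles with linear interpolation between order statistics."""
    trials = np.asarray(trials, dtype=float)
    if trials.size == 0:
        raise EmptyDataError("no trials to summarize")
    qs = np.quantile(trials, list(percentiles), method="linear")
    return {float(p): float(q) for p, q in zip(percentiles, qs)}


def exceedance_probability(trials, threshold: float) -> float:
    trials = np.asarray(trials, dtype=float)
    if trials.size == 0:
        raise EmptyDataError("no trials")
    return float(np.mean(trials > threshold))


@dataclass
class MCResult:
    """Monte Carlo summary for one output quantity."""

    name: str
    trials: np.ndarray
    percentiles: dict[float, float]
    seed: int
    n_iter: int
    output_fit: FittedDistribution | None = None
    fit_error: str | None = None
    deterministic_value: float | None = None
    within_band: bool | None = None  # deterministic value inside [p_lo, p_hi]


@dataclass
class ProbabilisticRun:
    """Inputs and per-output results of one probabilistic assessment."""

    source: str
    inputs: pd.DataFrame
    results: dict[str, MCResult]
    seed: int
    n_iter: int


# ---------------------------------------------------------------------------
# Building concentration inputs from data
# ---------------------------------------------------------------------------


def concentration_input_from_data(
    dataset: ConcentrationDataset,
    chem: ChemicalSpec,
    config: RiskConfig,
) -> InputLike:
    """Choose a sampler for one chemical's concentration.

    Detected values (≥ LOD) are fit parametrically and mixed with the ND
    spike at the observed detection rate.  When there are too few detected
    values for a parametric fit the full column is resampled empirically
    (ND substituted per policy); an all-censored chemical is a fixed zero
    (or the policy substitute).
    """
    s = summarize(dataset, chem, config.nd_policy)
    detected = dataset.detected_values(chem.chem_id, chem)
    nd_value = nd_substitute(config.nd_policy, chem.lod)
    if detected.size == 0:
        return FixedInput(nd_value)
    if detected.size < MIN_FIT_SIZE or np.ptp(detected) == 0:
        values = dataset.values_for(chem.chem_id, chem, config.nd_policy)
        return EmpiricalInput(tuple(float(v) for v in values))
    fitted = select_best(detected, config.candidate_families or None)
    return CensoredMixtureInput(
        detection_prob=s.detection_rate / 100.0, fitted=fitted, nd_value=nd_value
    )


def concentration_inputs_from_dataset(
    dataset: ConcentrationDataset,
    registry: Mapping[str, ChemicalSpec],
    config: RiskConfig,
) -> dict[str, InputLike]:
    return {
        chem_id: concentration_input_from_data(dataset, registry[chem_id], config)
        for chem_id in dataset.chemicals()
    }


def factor_inputs_from_survey(records, config: RiskConfig) -> dict[str, InputLike]:
    """Fit exposure-factor distributions to chronic-valid survey records.

    Falls back to empirical resampling for a factor whose parametric fit is
    unavailable.  EF day counts keep the discrete geometric family in the
    candidate set.
    """
    from .survey_tools import filter_chronic  # local import: avoid cycle

    valid = [r for r in filter_chronic(records) if r.valid]
    if not valid:
        raise EmptyDataError("no chronic-valid survey records to fit")
    columns = {
        "DI": np.array([r.di for r in valid]),
        "EF": np.array([r.freq for r in valid]),
        "ED": np.array([r.duration for r in valid]),
        "BW": np.array([r.bw for r in valid]),
    }
    out: dict[str, InputLike] = {}
    for name, values in columns.items():
        try:
            out[name] = select_best(values, config.candidate_families or None)
        except (NoFitError, InsufficientDataError) as _:
            out[name] = EmpiricalInput(tuple(float(v) for v in values))
    return out


# ---------------------------------------------------------------------------
# The probabilistic risk chain
# ---------------------------------------------------------------------------


def _risk_outputs(
    inputs: pd.DataFrame,
    registry: Mapping[str, ChemicalSpec],
    lt: float,
    dissolution: float,
) -> dict[str, np.ndarray]:
    di = inputs["DI"].to_numpy()
    ef = inputs["EF"].to_numpy()
    ed = inputs["ED"].to_numpy()
    bw = inputs["BW"].to_numpy()
    chem_cols = [c for c in inputs.columns if c.startswith("C:")]
    hi_p = np.zeros(len(inputs))
    hi_m = np.zeros(len(inputs))
    outputs: dict[str, np.ndarray] = {}
    for col in chem_cols:
        chem = registry[col[2:]]
        expo = expo_noncancer(inputs[col].to_numpy(), di, ef, ed, bw, dissolution)
        hq = expo / chem.adi
        if chem.chem_class == PESTICIDE:
            hi_p += hq
        else:
            hi_m += hq
        if chem.carcinogenic:
            ec = expo_cancer(inputs[col].to_numpy(), di, ef, ed, bw, lt, dissolution)
            outputs[f"R_{chem.chem_id}"] = chem.slope_factor * ug_to_mg(ec)
    outputs["HI_P"] = hi_p
    outputs["HI_M"] = hi_m
    outputs["HI_total"] = hi_p + hi_m
    return outputs


def run_probabilistic_risk(
    concentration_inputs: Mapping[str, InputLike],
    factor_inputs: Mapping[str, InputLike],
    registry: Mapping[str, ChemicalSpec],
    config: RiskConfig,
    source: str = "scenario",
    lt: float = DEFAULT_LIFESPAN_YEARS,
    dissolution: float = 1.0,
) -> ProbabilisticRun:
    """Propagate input samplers through the exposure/HQ/HI/R chain.

    ``factor_inputs`` must provide DI, EF, ED and BW (samplers or scalars).
    Per output, empirical percentiles from the run config are reported, the
    output distribution is re-fit with the same family-selection machinery
    (unless disabled), and the deterministic value computed from the input
    means is checked to lie between the lowest and highest requested
    percentile.
    """
    missing = {"DI", "EF", "ED", "BW"} - set(factor_inputs)
    if missing:
        raise ConfigurationError(f"missing exposure-factor inputs: {sorted(missing)}")
    inputs: dict[str, InputLike] = {
        f"C:{chem_id}": _as_input(spec) for chem_id, spec in concentration_inputs.items()
    }
    for name in ("DI", "EF", "ED", "BW"):
        inputs[name] = _as_input(factor_inputs[name])

    trial_matrix = sample_inputs(inputs, config.mc_iterations, config.seed)
    outputs = _risk_outputs(trial_matrix, registry, lt, dissolution)

    # deterministic chain from the input means (same clipping rules)
    mean_row = pd.DataFrame(
        {name: [_clip_for(name, np.array([inp.mean()]))[0]] for name, inp in inputs.items()}
    )
    deterministic = {k: float(v[0]) for k, v in _risk_outputs(mean_row, registry, lt, dissolution).items()}

    results: dict[str, MCResult] = {}
    p_lo, p_hi = min(config.percentiles), max(config.percentiles)
    for name, trials in outputs.items():
        pcts = summarize_percentiles(trials, config.percentiles)
        res = MCResult(
            name=name,
            trials=trials,
            percentiles=pcts,
            seed=config.seed,
            n_iter=config.mc_iterations,
            deterministic_value=deterministic[name],
            within_band=bool(pcts[p_lo] <= deterministic[name] <= pcts[p_hi]),
        )
        if config.fit_outputs:
            try:
                res.output_fit = select_best(
                    trials, config.candidate_families or None
                )
            except (NoFitError, FitError, InsufficientDataError, GojiRiskError) as exc:
                res.fit_error = f"{name}: {exc}"
        results[name] = res
    return ProbabilisticRun(
        source=source,
        inputs=trial_matrix,
        results=results,
        seed=config.seed,
        n_iter=config.mc_iterations,
    )
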