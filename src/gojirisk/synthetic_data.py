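"""Synthetic concentration and survey data with the study's structure.

The generator emulates what a residue survey of Goji berries produces:

* per-sample concentrations whose per-chemical summaries (mean, SD, range,
  detection rate) target published summary tables, with below-LOD censoring
  implemented as a structural mixture — each sample is non-detected with
  probability 1 − detection_rate and otherwise draws from a parametric
  family for the detected values.  Detected-value moments are solved from
  the target overall moments so that the ND→0 summary reproduces them;
* questionnaire records whose chronic-valid subset reproduces the survey's
  mean exposure factors under the families reported for them (DI ~ beta,
  EF ~ geometric, ED ~ lognormal, BW ~ beta).

Detected counts and chronic-valid counts are planted exactly
(``round(rate × n)``) rather than drawn, so detection rates and inclusion
counts are reproducible at any n; which samples carry them is randomized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .data_model import ConcentrationDataset, ConcentrationRecord
from .errors import ValidationError
from .survey_tools import SurveyRecord, CONSUMPTION_MODES

__all__ = [
    "ChemicalScenario",
    "ScenarioSpec",
    "SurveySpec",
    "generate_concentrations",
    "generate_survey",
    "DEFAULT_PLANTATION",
    "DEFAULT_SUPERMARKET",
    "DEFAULT_SURVEY",
    "default_scenario",
]


# ---------------------------------------------------------------------------
# Moment helpers
# ---------------------------------------------------------------------------


def _beta_from_moments(mean: float, sd: float, lo: float, hi: float):
    """Method-of-moments beta parameters on the support [lo, hi]."""
    if not lo < mean < hi:
        raise ValidationError(f"beta target mean {mean} outside support [{lo}, {hi}]")
    m = (mean - lo) / (hi - lo)
    v = (sd / (hi - lo)) ** 2
    if v <= 0 or v >= m * (1 - m):
        raise ValidationError(
            f"beta target sd {sd} infeasible on [{lo}, {hi}] for mean {mean}"
        )
    common = m * (1 - m) / v - 1
    return m * common, (1 - m) * common


def _lognormal_from_moments(mean: float, sd: float):
    sdlog2 = np.log1p((sd / mean) ** 2)
    meanlog = np.log(mean) - sdlog2 / 2.0
    return meanlog, np.sqrt(sdlog2)


_EULER_GAMMA = 0.57721566490153286


def _gumbel_from_moments(mean: float, sd: float):
    scale = sd * np.sqrt(6.0) / np.pi
    return mean - _EULER_GAMMA * scale, scale


# ---------------------------------------------------------------------------
# Concentration scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChemicalScenario:
    """Targets for one chemical: overall moments, range and detection rate.

    ``mean``/``sd`` are the ND→0 summary targets over all n samples;
    ``min``/``max`` the printed range (``None`` when the minimum is ND or
    no range was printed); ``detection_rate`` in percent; ``family`` names
    the detected-value distribution.
    """

    chem_id: str
    family: str  # normal | lognormal | beta | gumbel_max
    mean: float
    sd: float
    detection_rate: float
    lod: float
    min: float | None = None
    max: float | None = None

    def __post_init__(self):
        if not 0 <= self.detection_rate <= 100:
            raise ValidationError(f"{self.chem_id}: detection_rate must be in [0, 100]")
        if self.detection_rate > 0 and self.mean <= 0:
            raise ValidationError(f"{self.chem_id}: detected chemical needs mean > 0")
        if self.sd < 0 or (self.sd == 0 and self.max not in (None, self.min)):
            raise ValidationError(f"{self.chem_id}: sd target infeasible for range")

    def detected_moments(self) -> tuple[float, float]:
        """Mean/SD of the detected-value component implied by the mixture.

        For detection probability p, the ND→0 mixture has mean p·µ_d and
        variance p·σ_d² + p(1−p)·µ_d²; invert for (µ_d, σ_d).  When the
        printed SD is too small to be consistent with the censoring mass
        the detected spread is set to µ_d/2.
        """
        p = self.detection_rate / 100.0
        mu_d = self.mean / p
        var_d = (self.sd**2 - p * (1 - p) * mu_d**2) / p
        sd_d = np.sqrt(var_d) if var_d > 0 else mu_d / 2.0
        return mu_d, float(sd_d)

    def detected_sampler(self):
        """Frozen distribution for detected values."""
        mu_d, sd_d = self.detected_moments()
        if self.family == "normal":
            return stats.norm(mu_d, sd_d)
        if self.family == "lognormal":
            meanlog, sdlog = _lognormal_from_moments(mu_d, sd_d)
            return stats.lognorm(sdlog, 0.0, np.exp(meanlog))
        if self.family == "gumbel_max":
            loc, scale = _gumbel_from_moments(mu_d, sd_d)
            return stats.gumbel_r(loc, scale)
        if self.family == "beta":
            lo = self.min if self.min is not None else self.lod
            hi = self.max
            if hi is None:
                raise ValidationError(f"{self.chem_id}: beta family needs a max target")
            a, b = _beta_from_moments(mu_d, sd_d, lo, hi)
            return stats.beta(a, b, lo, hi - lo)
        raise ValidationError(f"{self.chem_id}: unknown family {self.family!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    source: str
    n_samples: int
    chemicals: tuple[ChemicalScenario, ...]

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValidationError("n_samples must be ≥ 1")

    def scenario_for(self, chem_id: str) -> ChemicalScenario:
        for c in self.chemicals:
            if c.chem_id == chem_id:
                return c
        raise KeyError(chem_id)

    def target_means(self) -> dict[str, float]:
        return {c.chem_id: c.mean for c in self.chemicals}


def generate_concentrations(
    spec: ScenarioSpec, seed: int | np.random.Generator, n_samples: int | None = None
) -> ConcentrationDataset:
    """Draw a per-sample concentration dataset for a scenario.

    Exactly ``round(detection_rate × n)`` samples per chemical are detected
    (randomly placed); detected draws are clipped into
    [max(LOD, printed min), printed max] so detection semantics and ranges
    stay physical.  Deterministic under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_samples if n_samples is not None else spec.n_samples
    sample_ids = [f"{spec.source[:2].upper()}{i + 1:04d}" for i in range(n)]
    records: list[ConcentrationRecord] = []
    for scn in spec.chemicals:
        n_det = int(round(scn.detection_rate / 100.0 * n))
        detected_at = set(rng.permutation(n)[:n_det].tolist())
        values = np.zeros(n)
        if n_det > 0:
            draws = np.asarray(
                scn.detected_sampler().rvs(size=n_det, random_state=rng), dtype=float
            )
            lo = max(scn.lod, scn.min if scn.min is not None else scn.lod)
            draws = np.maximum(draws, lo)
            if scn.max is not None:
                draws = np.minimum(draws, scn.max)
            values[sorted(detected_at)] = draws
        for i, sid in enumerate(sample_ids):
            records.append(
                ConcentrationRecord(
                    sample_id=sid,
                    chem_id=scn.chem_id,
                    value=float(values[i]),
                    censored=i not in detected_at,
                )
            )
    return ConcentrationDataset(source=spec.source, records=records)


# ---------------------------------------------------------------------------
# Survey scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurveySpec:
    """Targets for the questionnaire generator (chronic-valid subpopulation).

    DI ~ beta on [di_lo, di_hi] g/day; EF = 52 + geometric day counts
    clipped to 365 with the geometric mean solved so the clipped mean hits
    ``ef_mean``; ED ~ lognormal years floored at 0.25; BW ~ beta on
    [bw_lo, bw_hi] kg.  ``valid_fraction`` of records satisfy the chronic
    rule; the rest are corrupted to fail it.
    """

    di_mean: float = 1.37
    di_sd: float = 0.6
    di_lo: float = 0.05
    di_hi: float = 10.0
    ef_mean: float = 145.7
    ed_mean: float = 5.93
    ed_sd: float = 4.0
    bw_mean: float = 64.81
    bw_sd: float = 10.0
    bw_lo: float = 40.0
    bw_hi: float = 100.0
    valid_fraction: float = 401.0 / 558.0
    mode_probs: tuple[float, float, float] = (0.70, 0.25, 0.05)

    def ef_geometric_mean(self) -> float:
        """Unclipped geometric mean m solved so E[52 + min(G, 313)] = ef_mean."""
        target = self.ef_mean - 52.0
        k = 365.0 - 52.0

        def clipped_mean(m):
            p = 1.0 / m
            return (1.0 - (1.0 - p) ** k) / p - target

        return float(brentq(clipped_mean, target + 1e-9, 50 * target))


def generate_survey(
    n: int, spec: SurveySpec | None = None, seed: int | np.random.Generator = 0
) -> list[SurveyRecord]:
    """Generate questionnaire records; exactly round(n·valid_fraction) are
    chronic-valid.  Deterministic under the seed."""
    if n < 1:
        raise ValidationError("n must be ≥ 1")
    spec = spec or DEFAULT_SURVEY
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_valid = int(round(n * spec.valid_fraction))
    valid_mask = np.zeros(n, dtype=bool)
    valid_mask[rng.permutation(n)[:n_valid]] = True

    a, b = _beta_from_moments(spec.di_mean, spec.di_sd, spec.di_lo, spec.di_hi)
    di = stats.beta(a, b, spec.di_lo, spec.di_hi - spec.di_lo).rvs(
        size=n, random_state=rng
    )
    m_geom = spec.ef_geometric_mean()
    g = stats.geom(1.0 / m_geom).rvs(size=n, random_state=rng)
    freq = 52.0 + np.minimum(g, 365.0 - 52.0)
    meanlog, sdlog = _lognormal_from_moments(spec.ed_mean, spec.ed_sd)
    duration = np.maximum(
        stats.lognorm(sdlog, 0.0, np.exp(meanlog)).rvs(size=n, random_state=rng), 0.25
    )
    a2, b2 = _beta_from_moments(spec.bw_mean, spec.bw_sd, spec.bw_lo, spec.bw_hi)
    bw = stats.beta(a2, b2, spec.bw_lo, spec.bw_hi - spec.bw_lo).rvs(
        size=n, random_state=rng
    )
    age = rng.uniform(18.0, 70.0, size=n)
    modes = rng.choice(CONSUMPTION_MODES, size=n, p=spec.mode_probs)

    records = []
    for i in range(n):
        f, d = float(freq[i]), float(duration[i])
        if not valid_mask[i]:
            u = rng.random()
            if u < 0.4:
                f = float(rng.integers(1, 52))
            elif u < 0.8:
                d = float(rng.uniform(0.02, 0.24))
            else:
                f = float(rng.integers(1, 52))
                d = float(rng.uniform(0.02, 0.24))
        records.append(
            SurveyRecord(
                respondent_id=f"R{i + 1:04d}",
                di=float(di[i]),
                freq=f,
                duration=d,
                bw=float(bw[i]),
                age=float(age[i]),
                mode=str(modes[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Default scenarios: published summary structure of the two berry sources
# ---------------------------------------------------------------------------

DEFAULT_PLANTATION = ScenarioSpec(
    source="plantation",
    n_samples=37,
    chemicals=(
        ChemicalScenario("dichlorvos", "lognormal", 0.02, 0.03, 21.62, 0.0050, None, 0.17),
        ChemicalScenario("omethoate", "lognormal", 0.02, 0.05, 16.22, 0.0100, None, 0.16),
        ChemicalScenario("malathion", "lognormal", 0.01, 0.03, 27.03, 0.0050, None, 0.07),
        ChemicalScenario("cypermethrin", "lognormal", 0.02, 0.03, 29.73, 0.0100, None, 0.52),
        ChemicalScenario("fenvalerate", "lognormal", 0.88, 0.70, 72.97, 0.0200, None, 4.43),
        ChemicalScenario("deltamethrin", "lognormal", 0.0, 0.0, 0.0, 0.0200),
        ChemicalScenario("Pb", "beta", 0.35, 0.27, 89.19, 0.0024, None, 0.96),
        ChemicalScenario("Cd", "beta", 0.10, 0.07, 100.0, 0.0702, 0.03, 0.35),
        ChemicalScenario("Cu", "normal", 8.70, 2.70, 100.0, 0.0093, 2.29, 14.49),
        ChemicalScenario("Ni", "gumbel_max", 0.88, 0.44, 100.0, 0.0034, 0.21, 2.52),
        ChemicalScenario("Zn", "lognormal", 19.56, 6.41, 100.0, 0.0021, 10.98, 35.35),
        ChemicalScenario("As", "beta", 0.20, 0.23, 56.76, 0.0075, None, 0.81),
    ),
)

DEFAULT_SUPERMARKET = ScenarioSpec(
    source="supermarket",
    n_samples=80,
    chemicals=(
        ChemicalScenario("dichlorvos", "lognormal", 0.01, 0.02, 10.00, 0.0050),
        ChemicalScenario("omethoate", "lognormal", 0.0, 0.0, 0.0, 0.0100),
        ChemicalScenario("malathion", "lognormal", 0.0, 0.0, 0.0, 0.0050),
        ChemicalScenario("cypermethrin", "lognormal", 0.0, 0.0, 0.0, 0.0100),
        ChemicalScenario("fenvalerate", "lognormal", 0.0, 0.0, 0.0, 0.0200),
        ChemicalScenario("deltamethrin", "lognormal", 0.0, 0.0, 0.0, 0.0200),
        ChemicalScenario("Pb", "lognormal", 0.08, 0.20, 70.00, 0.0024, None, 0.84),
        # printed Cd mean (0.04) sits below the printed LOD (0.0702); a
        # bounded family on [LOD, max] is infeasible, so detected values are
        # lognormal and the LOD clip biases the mean upward (documented).
        ChemicalScenario("Cd", "lognormal", 0.04, 0.03, 72.50, 0.0702, None, 0.14),
        ChemicalScenario("Cu", "normal", 7.55, 1.37, 100.0, 0.0093, 5.96, 10.03),
        ChemicalScenario("Ni", "gumbel_max", 0.90, 0.57, 96.67, 0.0034, None, 1.51),
        ChemicalScenario("Zn", "lognormal", 14.37, 4.02, 100.0, 0.0021, 8.26, 24.15),
        ChemicalScenario("As", "lognormal", 0.03, 0.09, 86.67, 0.0075, None, 0.35),
    ),
)

DEFAULT_SURVEY = SurveySpec()


def default_scenario(source: str) -> ScenarioSpec:
    if source == "plantation":
        return DEFAULT_PLANTATION
    if source == "supermarket":
        return DEFAULT_SUPERMARKET
    raise KeyError(f"no default scenario for source {source!r}")
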