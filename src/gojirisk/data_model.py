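"""Domain types and CSV/config I/O shared by every pipeline stage.

Unit discipline
---------------
Concentrations are stored in mg/kg (numerically equal to µg/g) everywhere;
chronic daily exposures are µg/(kg·day).  The single mg↔µg conversion is
owned by :mod:`gojirisk.exposure_engine` and never repeated elsewhere.

Censoring
---------
A measurement below the limit of detection (LOD) is a left-censored
observation, written as the token ``ND`` in CSV files.  Censored records
keep their row identity; their numeric contribution to summaries and fits
is governed by the active ND-substitution policy (``zero`` by default,
``half_lod`` and ``lod`` available).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "ChemicalSpec",
    "ConcentrationRecord",
    "ConcentrationDataset",
    "ExposureFactors",
    "RiskConfig",
    "ND_POLICIES",
    "nd_substitute",
    "default_registry",
    "read_chemical_registry",
    "read_concentrations",
    "read_all_concentrations",
    "write_concentrations",
    "load_config",
    "DEFAULT_EXPOSURE_FACTORS",
    "DEFAULT_LIFESPAN_YEARS",
]

PESTICIDE = "pesticide"
METAL = "metal"

ND_POLICIES = ("zero", "half_lod", "lod")

#: Average consumer lifespan (years) used for lifetime-averaged carcinogenic dose.
DEFAULT_LIFESPAN_YEARS = 76.34

CONCENTRATION_COLUMNS = ["sample_id", "source", "chemical", "value_mg_per_kg", "censored"]

_FLOAT_FMT = "%.6g"  # ≥6 significant digits on all written floats


def nd_substitute(policy: str, lod: float) -> float:
    """Numeric stand-in for a below-LOD value under an ND policy."""
    if policy == "zero":
        return 0.0
    if policy == "half_lod":
        return lod / 2.0
    if policy == "lod":
        return lod
    raise ValidationError(f"unknown nd_policy {policy!r}; expected one of {ND_POLICIES}")


@dataclass(frozen=True)
class ChemicalSpec:
    """Registry entry for one hazardous chemical.

    Parameters
    ----------
    lod : limit of detection, mg/kg.
    mrl : maximum residue limit, mg/kg, with its regulatory source.
    adi : allowable daily intake, µg/(kg·day).
    slope_factor : cancer potency, (mg/(kg·day))⁻¹; required iff carcinogenic.
    """

    chem_id: str
    display_name: str
    chem_class: str
    lod: float
    mrl: float
    adi: float
    mrl_source: str = ""
    carcinogenic: bool = False
    slope_factor: float | None = None

    def __post_init__(self):
        if self.chem_class not in (PESTICIDE, METAL):
            raise ValidationError(
                f"{self.chem_id}: chem_class must be '{PESTICIDE}' or '{METAL}'"
            )
        for name in ("lod", "mrl", "adi"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{self.chem_id}: {name} must be finite and > 0")
        if self.carcinogenic:
            if self.slope_factor is None or not np.isfinite(self.slope_factor) or self.slope_factor <= 0:
                raise ValidationError(
                    f"{self.chem_id}: carcinogenic chemical requires slope_factor > 0"
                )
        elif self.slope_factor is not None:
            raise ValidationError(
                f"{self.chem_id}: slope_factor given for a non-carcinogenic chemical"
            )


@dataclass(frozen=True)
class ConcentrationRecord:
    sample_id: str
    chem_id: str
    value: float  # mg/kg; ignored by summaries when censored (policy decides)
    censored: bool = False

    def __post_init__(self):
        if not np.isfinite(self.value) or self.value < 0:
            raise ValidationError(
                f"{self.sample_id}/{self.chem_id}: value must be finite and ≥ 0"
            )


@dataclass
class ConcentrationDataset:
    """Per-sample measurements from one source (plantation, supermarket, ...)."""

    source: str
    records: list[ConcentrationRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for r in self.records:
            key = (r.sample_id, r.chem_id)
            if key in seen:
                raise ValidationError(f"duplicate record for sample {key}")
            seen.add(key)

    def chemicals(self) -> list[str]:
        return sorted({r.chem_id for r in self.records})

    def records_for(self, chem_id: str) -> list[ConcentrationRecord]:
        return [r for r in self.records if r.chem_id == chem_id]

    def n_samples(self, chem_id: str) -> int:
        return len(self.records_for(chem_id))

    def values_for(self, chem_id: str, chem: ChemicalSpec, nd_policy: str = "zero") -> np.ndarray:
        """All n values for a chemical with ND rows substituted per policy."""
        sub = nd_substitute(nd_policy, chem.lod)
        return np.array(
            [sub if r.censored else r.value for r in self.records_for(chem_id)],
            dtype=float,
        )

    def detected_values(self, chem_id: str, chem: ChemicalSpec) -> np.ndarray:
        """Values of non-censored records at or above the LOD."""
        return np.array(
            [r.value for r in self.records_for(chem_id) if not r.censored and r.value >= chem.lod],
            dtype=float,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "source": self.source,
                "chemical": [r.chem_id for r in self.records],
                "value_mg_per_kg": [r.value for r in self.records],
                "censored": [r.censored for r in self.records],
            }
        )


@dataclass(frozen=True)
class ExposureFactors:
    """Survey-derived inputs to the chronic daily-exposure equations.

    di : daily intake of berries, g/day.
    ef : exposure frequency, day/year.
    ed : exposure duration, year.
    bw : body weight, kg.
    lt : average lifespan, year (carcinogenic averaging time).
    dissolution : fraction of the residue extracted when berries are brewed
        rather than eaten; applied multiplicatively to the concentration.
        1.0 means direct consumption (the factor is off).
    """

    di: float
    ef: float
    ed: float
    bw: float
    lt: float = DEFAULT_LIFESPAN_YEARS
    dissolution: float = 1.0

    def __post_init__(self):
        checks = [
            (self.di > 0, "di must be > 0"),
            (0 < self.ef <= 365, "ef must be in (0, 365]"),
            (self.ed > 0, "ed must be > 0"),
            (self.bw > 0, "bw must be > 0"),
            (self.lt >= self.ed, "lt must be ≥ ed"),
            (0 < self.dissolution <= 1, "dissolution must be in (0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValidationError(msg)
        for name in ("di", "ef", "ed", "bw", "lt", "dissolution"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    def with_(self, **kw) -> "ExposureFactors":
        return replace(self, **kw)


#: Mean exposure factors of the chronic-consumer survey population.
DEFAULT_EXPOSURE_FACTORS = ExposureFactors(di=1.37, ef=145.7, ed=5.93, bw=64.81)


@dataclass(frozen=True)
class RiskConfig:
    """Run configuration shared by the probabilistic stages."""

    nd_policy: str = "zero"
    mc_iterations: int = 10_000
    seed: int = 20210
    candidate_families: tuple[str, ...] = ()  # empty → module default
    percentiles: tuple[float, ...] = (0.10, 0.50, 0.90)
    fit_outputs: bool = True

    def __post_init__(self):
        if self.nd_policy not in ND_POLICIES:
            raise ConfigurationError(f"nd_policy must be one of {ND_POLICIES}")
        if self.mc_iterations < 1000:
            raise ConfigurationError("mc_iterations must be ≥ 1000")
        ps = self.percentiles
        if not ps or any(not (0 < p < 1) for p in ps) or any(
            b <= a for a, b in zip(ps, ps[1:])
        ):
            raise ConfigurationError("percentiles must be strictly increasing in (0, 1)")


# ---------------------------------------------------------------------------
# Registry I/O
# ---------------------------------------------------------------------------

_REGISTRY_COLUMNS = [
    "chem_id",
    "display_name",
    "chem_class",
    "lod_mg_per_kg",
    "mrl_mg_per_kg",
    "mrl_source",
    "adi_ug_per_kg_day",
    "carcinogenic",
    "slope_factor_per_mg_kg_day",
]

_TRUE_TOKENS = {"true", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "0", "no", "n", ""}


def _parse_bool(token) -> bool:
    s = str(token).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS or s == "nan":
        return False
    raise SchemaError(f"unparsable boolean token {token!r}")


def read_chemical_registry(path=None) -> dict[str, ChemicalSpec]:
    """Load a chemical registry CSV; ``None`` loads the packaged default."""
    if path is None:
        with resources.files("gojirisk.data").joinpath("registry.csv").open("r") as fh:
            df = pd.read_csv(fh, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    missing = set(_REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"registry is missing columns {sorted(missing)}")
    registry: dict[str, ChemicalSpec] = {}
    for _, row in df.iterrows():
        carcinogenic = _parse_bool(row["carcinogenic"])
        sf_token = row["slope_factor_per_mg_kg_day"]
        sf = None
        if isinstance(sf_token, str) and sf_token.strip():
            sf = float(sf_token)
        if carcinogenic and sf is None:
            raise ValidationError(
                f"{row['chem_id']}: carcinogenic chemical has no slope factor"
            )
        spec = ChemicalSpec(
            chem_id=str(row["chem_id"]),
            display_name=str(row["display_name"]),
            chem_class=str(row["chem_class"]),
            lod=float(row["lod_mg_per_kg"]),
            mrl=float(row["mrl_mg_per_kg"]),
            mrl_source=str(row["mrl_source"]),
            adi=float(row["adi_ug_per_kg_day"]),
            carcinogenic=carcinogenic,
            slope_factor=sf,
        )
        if spec.chem_id in registry:
            raise ValidationError(f"duplicate registry entry {spec.chem_id}")
        registry[spec.chem_id] = spec
    return registry


def default_registry() -> dict[str, ChemicalSpec]:
    return read_chemical_registry(None)


# ---------------------------------------------------------------------------
# Concentration I/O
# ---------------------------------------------------------------------------


def _records_from_frame(df: pd.DataFrame, registry: Mapping[str, ChemicalSpec]):
    records = []
    for _, row in df.iterrows():
        chem = str(row["chemical"])
        if chem not in registry:
            raise SchemaError(f"chemical {chem!r} not present in the registry")
        raw = row["value_mg_per_kg"]
        censored = _parse_bool(row["censored"]) if "censored" in row else False
        if isinstance(raw, str) and raw.strip().upper() == "ND":
            censored, value = True, 0.0
        else:
            value = float(raw)
        if value < 0:
            raise ValidationError(
                f"{row['sample_id']}/{chem}: negative concentration {value}"
            )
        records.append(
            ConcentrationRecord(
                sample_id=str(row["sample_id"]),
                chem_id=chem,
                value=0.0 if censored else value,
                censored=censored,
            )
        )
    return records


def read_concentrations(
    path, registry: Mapping[str, ChemicalSpec], source: str | None = None
) -> ConcentrationDataset:
    """Read a per-sample concentration CSV into a single-source dataset.

    The file must contain one distinct ``source`` unless ``source`` selects
    one.  An explicit ``ND`` token in ``value_mg_per_kg`` marks a censored
    record (equivalent to ``censored=true``).
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "source": str, "chemical": str})
    missing = set(CONCENTRATION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"concentration file missing columns {sorted(missing)}")
    sources = sorted(df["source"].unique())
    if source is not None:
        if source not in sources:
            raise SchemaError(f"source {source!r} not found (available: {sources})")
        df = df[df["source"] == source]
    elif len(sources) > 1:
        raise SchemaError(
            f"file contains multiple sources {sources}; pass source= to select one"
        )
    else:
        source = sources[0]
    return ConcentrationDataset(source=source, records=_records_from_frame(df, registry))


def read_all_concentrations(path, registry) -> dict[str, ConcentrationDataset]:
    """Read a concentration CSV into one dataset per source."""
    df = pd.read_csv(path, dtype={"sample_id": str, "source": str, "chemical": str})
    missing = set(CONCENTRATION_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"concentration file missing columns {sorted(missing)}")
    return {
        src: ConcentrationDataset(
            source=src, records=_records_from_frame(sub, registry)
        )
        for src, sub in df.groupby("source", sort=True)
    }


def write_concentrations(dataset: ConcentrationDataset, path) -> None:
    """Write a dataset back to CSV; censored values render as ``ND``."""
    df = dataset.to_frame()
    df["value_mg_per_kg"] = [
        "ND" if c else _FLOAT_FMT % v
        for v, c in zip(df["value_mg_per_kg"], df["censored"])
    ]
    df["censored"] = df["censored"].map({True: "true", False: "false"})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


def load_config(path) -> RiskConfig:
    """Load a flat YAML mapping into a :class:`RiskConfig`."""
    if hasattr(path, "read"):
        raw = yaml.safe_load(path)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a flat key-value mapping")
    known = {
        "nd_policy",
        "mc_iterations",
        "seed",
        "candidate_families",
        "percentiles",
        "fit_outputs",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
    if "candidate_families" in raw:
        raw["candidate_families"] = tuple(raw["candidate_families"])
    if "percentiles" in raw:
        raw["percentiles"] = tuple(float(p) for p in raw["percentiles"])
    return RiskConfig(**raw)


def config_to_yaml(config: RiskConfig) -> str:
    return yaml.safe_dump(
        {
            "nd_policy": config.nd_policy,
            "mc_iterations": config.mc_iterations,
            "seed": config.seed,
            "candidate_families": list(config.candidate_families),
            "percentiles": list(config.percentiles),
            "fit_outputs": config.fit_outputs,
        },
        sort_keys=True,
    )
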