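"""Publication-shaped tables, run manifests, and the full pipeline driver.

All internal computation stays at full precision; rounding to the display
conventions of residue-survey reports (4 decimals for HQ/HI, 3 significant
figures in scientific notation for carcinogenic risk) happens only in the
``*_display`` columns emitted here.  Numeric columns are written with
enough digits to round-trip between stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .concentration_summary import summarize_all
from .data_model import (
    ChemicalSpec,
    ExposureFactors,
    RiskConfig,
    config_to_yaml,
    read_all_concentrations,
    read_chemical_registry,
)
from .deterministic_risk import classify, compute_deterministic_risk
from .errors import ConfigurationError
from .exposure_engine import cancer_exposure, daily_exposure
from .monte_carlo import (
    ProbabilisticRun,
    concentration_inputs_from_dataset,
    factor_inputs_from_survey,
    run_probabilistic_risk,
)
from .sensitivity import contribution_to_variance
from .survey_tools import filter_chronic, read_survey, summarize_factors

__all__ = [
    "RunManifest",
    "render_summary_table",
    "render_exposure_table",
    "render_risk_table",
    "render_mc_table",
    "render_sensitivity_table",
    "run_full_pipeline",
]

_FLOAT = "%.10g"


def _fmt_hq(x: float) -> str:
    return f"{x:.4f}" if x >= 5e-5 else f"{x:.2e}"


def _fmt_r(x: float) -> str:
    return f"{x:.2e}"


@dataclass
class RunManifest:
    """Provenance snapshot tying every emitted table to one run."""

    manifest_id: str
    tool_version: str
    seed: int
    config: dict
    input_digests: dict[str, str]
    created_utc: str

    @classmethod
    def create(cls, config: RiskConfig, input_paths: Mapping[str, Path | str | None]):
        digests = {}
        for name, p in input_paths.items():
            if p is None:
                continue
            digests[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        core = config_to_yaml(config) + json.dumps(digests, sort_keys=True)
        manifest_id = hashlib.sha256(core.encode()).hexdigest()[:12]
        return cls(
            manifest_id=manifest_id,
            tool_version=__version__,
            seed=config.seed,
            config={"yaml": config_to_yaml(config)},
            input_digests=digests,
            created_utc=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Table renderers
# ---------------------------------------------------------------------------


def render_summary_table(dataset, registry, nd_policy: str = "zero") -> pd.DataFrame:
    """Residue-summary table: level string, detection rate, LOD/MRL screen."""
    df = summarize_all(dataset, registry, nd_policy)
    levels = []
    for _, row in df.iterrows():
        if row["detection_rate_pct"] == 0 and row["any_censored"]:
            levels.append("ND")
            continue
        lo = "ND" if row["any_censored"] else f"{row['min_mg_per_kg']:.2f}"
        levels.append(
            f"{row['mean_mg_per_kg']:.2f} ± {row['sd_mg_per_kg']:.2f}"
            f" ({lo}–{row['max_mg_per_kg']:.2f})"
        )
    df["level_display"] = levels
    df["lod_mg_per_kg"] = [registry[c].lod for c in df["chemical"]]
    df["mrl_mg_per_kg"] = [registry[c].mrl for c in df["chemical"]]
    return df


def render_exposure_table(
    mean_concentrations: Mapping[str, float],
    factors: ExposureFactors,
    registry: Mapping[str, ChemicalSpec],
    source: str,
) -> pd.DataFrame:
    rows = []
    for chem_id in sorted(mean_concentrations):
        c = mean_concentrations[chem_id]
        spec = registry[chem_id]
        expo = daily_exposure(c, factors)
        row = {
            "chemical": chem_id,
            "source": source,
            "chem_class": spec.chem_class,
            "expo_ug_per_kg_day": expo,
        }
        if spec.carcinogenic:
            row["expo_cancer_ug_per_kg_day"] = cancer_exposure(c, factors)
        rows.append(row)
    return pd.DataFrame(rows)


def render_risk_table(result, source: str) -> pd.DataFrame:
    """Deterministic HQ/HI/R table with display rounding and classification."""
    rows = [
        {
            "item": chem_id,
            "source": source,
            "kind": "HQ",
            "value": hq,
            "display": _fmt_hq(hq),
            "classification": classify(hq, "hq"),
        }
        for chem_id, hq in sorted(result.hq.items())
    ]
    for name, value in (
        ("HI_P", result.hi_p),
        ("HI_M", result.hi_m),
        ("HI_total", result.hi_total),
    ):
        rows.append(
            {
                "item": name,
                "source": source,
                "kind": "HI",
                "value": value,
                "display": _fmt_hq(value),
                "classification": classify(value, "hi"),
            }
        )
    rows.append(
        {
            "item": "share_P_pct",
            "source": source,
            "kind": "share",
            "value": result.share_p,
            "display": f"{result.share_p:.2f}",
            "classification": "",
        }
    )
    rows.append(
        {
            "item": "share_M_pct",
            "source": source,
            "kind": "share",
            "value": result.share_m,
            "display": f"{result.share_m:.2f}",
            "classification": "",
        }
    )
    for chem_id, r in sorted(result.r.items()):
        rows.append(
            {
                "item": f"R_{chem_id}",
                "source": source,
                "kind": "R",
                "value": r,
                "display": _fmt_r(r),
                "classification": classify(r, "cancer"),
            }
        )
    return pd.DataFrame(rows)


def render_mc_table(run: ProbabilisticRun) -> pd.DataFrame:
    """Probabilistic-estimate table: output fit family, parameters, percentiles."""
    rows = []
    for name in sorted(run.results):
        res = run.results[name]
        fit = res.output_fit
        row = {
            "output": name,
            "source": run.source,
            "n_iter": res.n_iter,
            "distribution": fit.family if fit else "",
            "parameters": (
                "; ".join(f"{k}={v:.4g}" for k, v in fit.params.items()) if fit else ""
            ),
            "deterministic_value": res.deterministic_value,
            "deterministic_within_band": res.within_band,
        }
        for p, q in res.percentiles.items():
            row[f"p{int(round(p * 100))}"] = q
        rows.append(row)
    return pd.DataFrame(rows)


def render_sensitivity_table(sens) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "output": sens.output_name,
                "input": name,
                "share_pct": sens.shares[name],
                "spearman_sign": (
                    0 if sens.correlations[name] == 0
                    else (1 if sens.correlations[name] > 0 else -1)
                ),
            }
            for name in sens.ordering
        ]
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_full_pipeline(
    concentrations_path,
    outdir,
    registry_path=None,
    survey_path=None,
    factors: ExposureFactors | None = None,
    config: RiskConfig | None = None,
) -> dict:
    """Run every stage on one concentration file and write the report bundle.

    Exposure factors come from the survey file (chronic-filtered means and
    fitted factor distributions) when given, otherwise from ``factors``
    (fixed scalars in the probabilistic stage).
    """
    config = config or RiskConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = read_chemical_registry(registry_path)
    datasets = read_all_concentrations(concentrations_path, registry)

    if survey_path is not None:
        records = filter_chronic(read_survey(survey_path))
        factors = summarize_factors(records)
        factor_inputs = factor_inputs_from_survey(records, config)
    elif factors is not None:
        records = None
        factor_inputs = {
            "DI": factors.di,
            "EF": factors.ef,
            "ED": factors.ed,
            "BW": factors.bw,
        }
    else:
        raise ConfigurationError("either survey_path or factors must be provided")

    manifest = RunManifest.create(
        config,
        {"concentrations": concentrations_path, "survey": survey_path,
         "registry": registry_path},
    )

    bundle: dict = {"manifest": manifest, "sources": {}}
    classification_rows = []
    for idx, (source, dataset) in enumerate(sorted(datasets.items())):
        summary_df = render_summary_table(dataset, registry, config.nd_policy)
        means = dict(
            zip(summary_df["chemical"], summary_df["mean_mg_per_kg"])
        )
        exposure_df = render_exposure_table(means, factors, registry, source)
        det = compute_deterministic_risk(means, factors, registry)
        risk_df = render_risk_table(det, source)

        mc_config = replace(config, seed=config.seed + idx)
        conc_inputs = concentration_inputs_from_dataset(dataset, registry, mc_config)
        run = run_probabilistic_risk(
            conc_inputs, factor_inputs, registry, mc_config,
            source=source, lt=factors.lt, dissolution=factors.dissolution,
        )
        mc_df = render_mc_table(run)

        sens_frames = []
        for output in ["HI_total"] + [n for n in run.results if n.startswith("R_")]:
            sens = contribution_to_variance(
                run.inputs, run.results[output].trials, output_name=output
            )
            sens_frames.append(render_sensitivity_table(sens))
        sens_df = pd.concat(sens_frames, ignore_index=True)
        sens_df.insert(1, "source", source)

        for df, stem in (
            (summary_df, "concentration_summary"),
            (exposure_df, "exposure"),
            (risk_df, "deterministic_risk"),
            (mc_df, "probabilistic_risk"),
            (sens_df, "sensitivity"),
        ):
            df = df.copy()
            df.insert(0, "manifest_id", manifest.manifest_id)
            df.to_csv(outdir / f"{stem}_{source}.csv", index=False, float_format=_FLOAT)

        classification_rows += [
            {
                "source": source,
                "metric": "HI_total",
                "value": det.hi_total,
                "classification": classify(det.hi_total, "hi"),
            }
        ] + [
            {
                "source": source,
                "metric": f"R_{chem}",
                "value": r,
                "classification": classify(r, "cancer"),
            }
            for chem, r in sorted(det.r.items())
        ]
        bundle["sources"][source] = {
            "summary": summary_df,
            "exposure": exposure_df,
            "deterministic": det,
            "risk_table": risk_df,
            "mc": run,
            "mc_table": mc_df,
            "sensitivity": sens_df,
        }

    classification_df = pd.DataFrame(classification_rows)
    classification_df.insert(0, "manifest_id", manifest.manifest_id)
    classification_df.to_csv(
        outdir / "classification.csv", index=False, float_format=_FLOAT
    )
    manifest.write(outdir / "manifest.json")
    bundle["classification"] = classification_df
    bundle["factors"] = factors
    return bundle
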