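"""End-to-end analysis pipeline driven by a validated configuration.

A single schema-validated config (JSON or YAML) describes the whole run:
where the subject table comes from (a file or the synthetic generator),
the fitting options, which diagnostics to produce, optional external
validation, and optional PTA/FTA dosing simulation.  ``run_pipeline``
executes the requested stages into a deterministic artifact directory:

    fit.json           population distribution, moments, -2LL/AIC/BIC
    predictions.csv    id, time, obs, pop_pred, ind_pred
    diagnostics/       gof.json, vpc.csv, npde.csv, bland_altman.json (+ plots)
    validation.json    MPE/RMSPE reports (when external data requested)
    pta.csv, fta.csv   dosing-simulation outputs (when requested)
    log.txt            seed, version and stage log
    config.json        the fully resolved configuration

Config problems are reported all at once (pydantic validation), before any
computation starts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cohorts import CohortDesign, generate_cohort, generate_external_cohort
from .diagnostics import bland_altman, gof_regression, npde, vpc
from .dosing import MICDistribution, PDTarget, fta, pta
from .io import read_subject_table
from .pk import Regimen
from .popfit import ErrorModel, NPAGConfig, ParameterSpace, npag_fit
from .posterior import individual_posterior, predict, predictions_frame
from .reference import DEFAULT_BOUNDS, FINAL_ERROR_MODEL_KWARGS
from .validation import external_validation_report

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class ErrorModelConfig(BaseModel):
    c0: float = FINAL_ERROR_MODEL_KWARGS["c0"]
    c1: float = FINAL_ERROR_MODEL_KWARGS["c1"]
    mode: str = FINAL_ERROR_MODEL_KWARGS["mode"]
    gamma: float = FINAL_ERROR_MODEL_KWARGS["gamma"]
    lam: float = 0.0

    def build(self) -> ErrorModel:
        return ErrorModel(**self.model_dump())


class FitConfig(BaseModel):
    bounds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    max_cycles: int = 60
    seed: int = 0

    def space(self) -> ParameterSpace:
        return ParameterSpace(self.bounds)


class DataConfig(BaseModel):
    subject_table: str | None = None  # CSV path; None -> synthetic
    synthetic_n_subjects: int = 24
    synthetic_seed: int = 0


class RegimenConfig(BaseModel):
    dose_mg: float = 4000.0
    interval_h: float = 6.0
    infusion_h: float = 0.5

    def build(self) -> Regimen:
        return Regimen(self.dose_mg, self.interval_h, self.infusion_h)


class DosingConfig(BaseModel):
    enabled: bool = False
    regimens: list[RegimenConfig] = Field(
        default_factory=lambda: [
            RegimenConfig(interval_h=6.0),
            RegimenConfig(interval_h=8.0),
        ]
    )
    crcl_scenarios: list[float] = Field(default_factory=lambda: [30.0, 60.0, 90.0, 130.0])
    targets: list[float] = Field(default_factory=lambda: [0.5, 1.0])
    n_sim: int = 1000
    seed: int = 0
    mic_table: str | None = None  # mic_mg_per_L,count CSV; required for FTA
    breakpoint: float = 16.0
    fta: bool = False


class ValidationConfig(BaseModel):
    enabled: bool = False
    styles: list[str] = Field(default_factory=lambda: ["rich_q6h", "rich_tds"])
    seed: int = 1
    concentration_cutoff: float | None = 100.0


class DiagnosticsConfig(BaseModel):
    enabled: bool = True
    n_sim: int = 1000
    seed: int = 0
    plots: bool = False


class PipelineConfig(BaseModel):
    data: DataConfig = Field(default_factory=DataConfig)
    error_model: ErrorModelConfig = Field(default_factory=ErrorModelConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    diagnostics: DiagnosticsConfig = Field(default_factory=DiagnosticsConfig)
    validation: ValidationConfig = Field(default_factory=ValidationConfig)
    dosing: DosingConfig = Field(default_factory=DosingConfig)

    @model_validator(mode="after")
    def _preflight(self) -> "PipelineConfig":
        problems = []
        if self.dosing.enabled and self.dosing.fta and self.dosing.mic_table is None:
            problems.append("dosing.fta requested but dosing.mic_table is not set")
        if self.dosing.enabled and self.dosing.mic_table is not None:
            if not Path(self.dosing.mic_table).exists():
                problems.append(f"MIC table not found: {self.dosing.mic_table}")
        if self.data.subject_table is not None and not Path(self.data.subject_table).exists():
            problems.append(f"subject table not found: {self.data.subject_table}")
        if problems:
            raise ValueError("; ".join(problems))
        return self


def load_config(path) -> PipelineConfig:
    """Load and validate a JSON or YAML pipeline config."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return PipelineConfig.model_validate(raw or {})


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"pippk {__version__}"]

    (out / "config.json").write_text(json.dumps(config.model_dump(), indent=2))

    # --- data ---------------------------------------------------------------
    if config.data.subject_table:
        subjects = read_subject_table(config.data.subject_table)
        log_lines.append(f"loaded {len(subjects)} subjects from {config.data.subject_table}")
    else:
        design = CohortDesign(n_subjects=config.data.synthetic_n_subjects)
        subjects, truth = generate_cohort(design, seed=config.data.synthetic_seed)
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
        log_lines.append(
            f"generated synthetic cohort n={len(subjects)} "
            f"(seed {config.data.synthetic_seed})"
        )

    error_model = config.error_model.build()

    # --- fit ----------------------------------------------------------------
    fit = npag_fit(
        subjects,
        space=config.fit.space(),
        error_model=error_model,
        config=NPAGConfig(seed=config.fit.seed, max_cycles=config.fit.max_cycles),
    )
    (out / "fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
    log_lines.append(
        f"fit: -2LL={fit.minus2ll:.2f} AIC={fit.aic:.2f} BIC={fit.bic:.2f} "
        f"support={len(fit.distribution)} cycles={fit.n_cycles} "
        f"converged={fit.converged} (seed {config.fit.seed})"
    )

    # --- posthoc predictions ------------------------------------------------
    records = []
    for s in subjects:
        post = individual_posterior(s, fit.distribution, error_model)
        records.extend(predict(s, fit.distribution, post))
    predictions_frame(records).to_csv(out / "predictions.csv", index=False)

    # --- diagnostics --------------------------------------------------------
    if config.diagnostics.enabled:
        ddir = out / "diagnostics"
        ddir.mkdir(exist_ok=True)
        gof = gof_regression(records, which="population", error_model=error_model)
        ba = bland_altman(
            [(r.observed, r.individual_predicted) for r in records],
            scale="percent_of_mean",
        )
        v = vpc(
            subjects, fit.distribution, error_model,
            n_sim=config.diagnostics.n_sim, seed=config.diagnostics.seed,
        )
        nd = npde(
            subjects, fit.distribution, error_model,
            n_sim=max(config.diagnostics.n_sim, 500), seed=config.diagnostics.seed,
        )
        (ddir / "gof.json").write_text(json.dumps(vars(gof) | {"slope_ci": list(gof.slope_ci)}, indent=2))
        pd.DataFrame(
            {"time": v.bin_times, "q05": v.q05, "q50": v.q50, "q95": v.q95}
        ).to_csv(ddir / "vpc.csv", index=False)
        pd.DataFrame({"npde": nd.values}).to_csv(ddir / "npde.csv", index=False)
        (ddir / "bland_altman.json").write_text(
            json.dumps(
                {"bias": ba.bias, "lower_loa": ba.lower_loa,
                 "upper_loa": ba.upper_loa, "scale": ba.scale},
                indent=2,
            )
        )
        log_lines.append(
            f"diagnostics: gof slope={gof.slope:.3f} r2={gof.r2:.3f} "
            f"vpc coverage={v.coverage:.3f} npde mean={nd.mean:.3f} "
            f"(seed {config.diagnostics.seed})"
        )
        if config.diagnostics.plots:
            from . import plots

            plots.obs_vs_pred(records).savefig(ddir / "obs_vs_pred.png", dpi=120)
            plots.vpc_plot(v).savefig(ddir / "vpc.png", dpi=120)
            plots.bland_altman_plot(ba).savefig(ddir / "bland_altman.png", dpi=120)

    # --- external validation ------------------------------------------------
    if config.validation.enabled:
        reports = []
        for style in config.validation.styles:
            ext_subjects, _ = generate_external_cohort(style, seed=config.validation.seed)
            ext_records = []
            for s in ext_subjects:
                post = individual_posterior(s, fit.distribution, error_model)
                ext_records.extend(predict(s, fit.distribution, post))
            reports.append(external_validation_report(ext_records, label=style).to_dict())
            if config.validation.concentration_cutoff:
                reports.append(
                    external_validation_report(
                        ext_records, label=style,
                        max_obs=config.validation.concentration_cutoff,
                    ).to_dict()
                )
        (out / "validation.json").write_text(json.dumps(reports, indent=2))
        log_lines.append(
            f"validation: {len(reports)} reports (seed {config.validation.seed})"
        )

    # --- dosing simulation --------------------------------------------------
    if config.dosing.enabled:
        mic_dist = None
        if config.dosing.mic_table:
            mic_dist = MICDistribution.from_csv(
                config.dosing.mic_table, breakpoint=config.dosing.breakpoint
            )
        pta_rows, fta_rows = [], []
        for reg_cfg in config.dosing.regimens:
            regimen = reg_cfg.build()
            for crcl in config.dosing.crcl_scenarios:
                for frac in config.dosing.targets:
                    target = PDTarget(fraction=frac)
                    res = pta(
                        fit.distribution, regimen, crcl, target,
                        n_sim=config.dosing.n_sim, seed=config.dosing.seed,
                    )
                    for mic, p in zip(res.mic_grid, res.pta):
                        pta_rows.append(
                            {
                                "dose_mg": regimen.dose,
                                "interval_h": regimen.interval,
                                "crcl": crcl,
                                "target": frac,
                                "mic_mg_per_L": mic,
                                "pta": p,
                            }
                        )
                    if config.dosing.fta and mic_dist is not None:
                        f = fta(res, mic_dist)
                        fta_rows.append(
                            {
                                "dose_mg": regimen.dose,
                                "interval_h": regimen.interval,
                                "crcl": crcl,
                                "target": frac,
                                "fta_percent": f.fta_percent,
                                "optimal": f.optimal,
                            }
                        )
        pd.DataFrame(pta_rows).to_csv(out / "pta.csv", index=False)
        if fta_rows:
            pd.DataFrame(fta_rows).to_csv(out / "fta.csv", index=False)
        log_lines.append(f"dosing: PTA grid written (seed {config.dosing.seed})")

    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
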