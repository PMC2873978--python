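"""End-to-end pipeline driver: harmonize -> classify -> filter -> scan ->
permutation FDR -> multi-cohort validation -> combined fits -> prototype
predictions -> sensitivity modes, with all outputs written to one directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import codebook as cb
from .combine import (PrototypeProfile, SensitivitySpec, fit_combined,
                      predict_prototype, run_sensitivity,
                      sensitivity_to_frame)
from .fdr import (estimate_fdr, estimate_validation_fdr, permutation_null,
                  select_significant, validate_multicohort)
from .plotting import class_summary, manhattan_plot
from .screen import DEFAULT_COVARIATES, results_to_frame, screen_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.detail = message


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (serialized next to the
    outputs together with the seed, so every run is reproducible)."""

    cohort_paths: dict[str, str] = dataclasses.field(default_factory=dict)
    codebook_path: str | None = None
    phenotype_column: str = "fbg"
    case_threshold: float = 126.0
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha: float = 0.02
    B: int = 1000
    seed: int = 0
    lonely_psu: str = "error"
    reference: str = "t"
    lod_substitution: str = "lod_sqrt2"
    sensitivity_modes: tuple[str, ...] = ()
    outdir: str = "ewascan-output"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        d["sensitivity_modes"] = list(self.sensitivity_modes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        for key in ("covariates", "sensitivity_modes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclasses.dataclass
class PipelineResult:
    scan: pd.DataFrame
    fdr_by_cohort: dict[str, float]
    validation: object
    combined: pd.DataFrame
    sensitivity: pd.DataFrame | None
    class_summary: pd.DataFrame


def _write_json(path: str, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)


def run_pipeline(config: PipelineConfig, *,
                 cohorts: Sequence[cb.CohortTable] | None = None,
                 codebook: cb.Codebook | None = None) -> PipelineResult:
    """Execute the full scan and write the output bundle.

    Inputs may be given as in-memory tables/codebook or as paths in the
    config. Any stage failure aborts with the stage name and writes a
    machine-readable error record into the output directory.
    """
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    _write_json(os.path.join(outdir, "config.json"), config.to_dict())
    stage = "load"
    try:
        if cohorts is None:
            cohorts = [cb.read_cohort_csv(p, cid)
                       for cid, p in config.cohort_paths.items()]
        if codebook is None:
            if config.codebook_path is None:
                raise ValueError("no codebook given")
            codebook = cb.Codebook.from_yaml(config.codebook_path)

        stage = "harmonize"
        tables, registry = cb.harmonize_symbols(cohorts, codebook)

        stage = "classify"
        case_def = cb.CaseDefinition(config.phenotype_column,
                                     config.case_threshold)
        tables = [cb.classify_cases(t, case_def) for t in tables]

        stage = "filter"
        retained: dict[str, list[str]] = {}
        exclusions = []
        analysis_tables = []
        for t in tables:
            kept, excl = cb.filter_factors(t, codebook)
            if not kept:
                raise ValueError(f"cohort {t.cohort_id!r}: no factors "
                                 "retained after filtering")
            retained[t.cohort_id] = kept
            exclusions += [{"cohort_id": t.cohort_id, "symbol": e.symbol,
                            "reason": e.reason, "detail": e.detail}
                           for e in excl]
            analysis_tables.append(
                cb.substitute_below_lod(t, codebook,
                                        config.lod_substitution))
        pd.DataFrame(exclusions,
                     columns=["cohort_id", "symbol", "reason", "detail"]
                     ).to_csv(os.path.join(outdir, "exclusions.csv"),
                              index=False)

        stage = "screen"
        results_by_cohort = {}
        for t in analysis_tables:
            results_by_cohort[t.cohort_id] = screen_cohort(
                t, codebook, retained[t.cohort_id], config.covariates,
                lonely_psu=config.lonely_psu, reference=config.reference)
        scan = pd.concat([results_to_frame(r)
                          for r in results_by_cohort.values()],
                         ignore_index=True)
        scan.to_csv(os.path.join(outdir, "scan.csv"), index=False)

        stage = "fdr"
        nulls = {}
        fdr_by_cohort = {}
        for i, t in enumerate(analysis_tables):
            nd = permutation_null(t, codebook, retained[t.cohort_id],
                                  config.B, config.seed + i,
                                  config.covariates,
                                  lonely_psu=config.lonely_psu,
                                  reference=config.reference)
            nulls[t.cohort_id] = nd
            obs_p = [r.p_value for r in results_by_cohort[t.cohort_id]]
            est = estimate_fdr(obs_p, nd.pooled(), config.alpha)
            fdr_by_cohort[t.cohort_id] = est.fdr

        stage = "validate"
        report = validate_multicohort(results_by_cohort, config.alpha,
                                      registry=registry)
        report = estimate_validation_fdr(nulls, report)
        report.table.to_csv(os.path.join(outdir, "validation.csv"),
                            index=False)
        _write_json(os.path.join(outdir, "validation.json"),
                    report.to_json_dict()
                    | {"B": config.B, "seed": config.seed,
                       "stage1_fdr_by_cohort": fdr_by_cohort,
                       "discoveries_by_cohort": {
                           cid: sorted(select_significant(r, config.alpha))
                           for cid, r in results_by_cohort.items()}})

        stage = "combine"
        combined_rows = []
        for sym in report.validated:
            res, fit, frame = fit_combined(analysis_tables, codebook, sym,
                                           config.covariates,
                                           lonely_psu=config.lonely_psu,
                                           reference=config.reference)
            pred = predict_prototype(fit, frame, PrototypeProfile())
            combined_rows.append({
                "symbol": sym, "env_class": res.env_class,
                "cohorts": frame.cohort_id, "or_point": res.or_point,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p_value": res.p_value, "n_case": res.n_case,
                "n_control": res.n_control,
                "exposure_low": pred.exposure_low,
                "exposure_high": pred.exposure_high,
                "prob_low": pred.p_low, "prob_high": pred.p_high})
        combined = pd.DataFrame(combined_rows, columns=[
            "symbol", "env_class", "cohorts", "or_point", "ci_low",
            "ci_high", "p_value", "n_case", "n_control", "exposure_low",
            "exposure_high", "prob_low", "prob_high"])
        combined.to_csv(os.path.join(outdir, "combined.csv"), index=False)

        stage = "sensitivity"
        sens_frame = None
        if config.sensitivity_modes:
            sens = []
            for sym in report.validated:
                for mode in config.sensitivity_modes:
                    sens.append(run_sensitivity(
                        analysis_tables, codebook, sym,
                        SensitivitySpec(mode=mode), config.covariates,
                        lonely_psu=config.lonely_psu,
                        reference=config.reference))
            sens_frame = sensitivity_to_frame(sens)
            sens_frame.to_csv(os.path.join(outdir, "sensitivity.csv"),
                              index=False)

        stage = "report"
        summary = class_summary(scan, config.alpha)
        summary.to_csv(os.path.join(outdir, "class_summary.csv"),
                       index=False)
        manhattan_plot(scan, config.alpha, set(report.validated),
                       path=os.path.join(outdir, "manhattan.png"))
    except Exception as exc:
        _write_json(os.path.join(outdir, "error.json"),
                    {"stage": stage, "error": type(exc).__name__,
                     "message": str(exc)})
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    return PipelineResult(scan=scan, fdr_by_cohort=fdr_by_cohort,
                          validation=report, combined=combined,
                          sensitivity=sens_frame, class_summary=summary)
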