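"""End-to-end pipeline orchestration and cohort description.

Stages: generate (optional, synthetic data) -> qc -> build-delta -> screen
-> report.  Each stage writes its artifacts under the output directory and
a manifest JSON records the configuration, seed, row counts and the QC drop
log, so a run is fully reconstructable from its outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .delta import build_deq
from .mediation import GATE_DEFAULT, fit_base_model, screen_panel
from .qc import run_qc
from .synthetic import (COVARIATES, INDICATORS, GeneratorConfig, generate,
                        inject_assay_artifacts)

__all__ = ["RunConfig", "run_pipeline", "summarize_cohort", "PipelineError"]

log = logging.getLogger("deqscreen")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str = "deqscreen_out"
    seed: int = 0
    gate: float = GATE_DEFAULT
    covariates: tuple = tuple(COVARIATES)
    generator: GeneratorConfig | None = None  # None => load inputs from files
    cohort_path: str | None = None
    panel_path: str | None = None
    panel_meta_path: str | None = None
    inject_artifacts: bool = True
    replicate: str = "mediators"

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Execute generate (optional) -> qc -> build-delta -> screen -> report.

    Returns the manifest dict (also written to ``manifest.json``).  Raises
    :class:`PipelineError` naming the failing stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": config.to_json_dict(),
                      "stages": {}}

    stage = "generate"
    try:
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            cohort, panel, truth = generate(gen)
            if config.inject_artifacts:
                panel = inject_assay_artifacts(panel, gen)
            dio.write_cohort(cohort, out / "cohort.csv")
            dio.write_panel(panel, out / "panel.csv", out / "panel_meta.csv")
            dio.write_json(truth.to_json_dict(), out / "ground_truth.json")
            manifest["stages"][stage] = {"n_subjects": int(gen.n_subjects),
                                         "n_analytes": len(panel.analytes)}
        else:
            if not (config.cohort_path and config.panel_path and config.panel_meta_path):
                raise PipelineError("no generator config and no input paths given")
            cohort = dio.read_cohort(config.cohort_path)
            panel = dio.read_panel(config.panel_path, config.panel_meta_path)
            manifest["stages"][stage] = {"loaded": True,
                                         "n_rows": int(len(cohort)),
                                         "n_analytes": len(panel.analytes)}
        _validate_cohort(cohort)

        stage = "qc"
        clean, qc_report = run_qc(panel)
        dio.write_clean(clean, out / "clean.csv")
        dio.write_json(qc_report.to_json_dict(), out / "qc_report.json")
        manifest["stages"][stage] = {
            "n_analytes_in": len(panel.analytes),
            "n_analytes_out": int(clean.shape[1]),
            "dropped": qc_report.dropped_analytes}
        log.info("qc: %d/%d analytes retained", clean.shape[1], len(panel.analytes))

        stage = "build-delta"
        delta = build_deq(cohort)
        delta.scores.to_csv(out / "scores.csv", index=False)
        dio.write_json(delta.to_json_dict(), out / "delta.json")
        manifest["stages"][stage] = {
            "determinacy": delta.determinacy,
            "validation": delta.validation,
            "converged": bool(delta.fit.converged)}

        stage = "screen"
        base = fit_base_model(cohort, delta.scores)
        report = screen_panel(cohort, delta.scores, clean, gate=config.gate,
                              seed=config.seed, replicate=config.replicate)
        report.to_frame().to_csv(out / "results.csv", index=False)
        dio.write_json(report.to_json_dict(), out / "screen.json")
        manifest["stages"][stage] = {
            "base_apoe_on_deq": base.apoe_on_deq.estimate,
            "base_apoe_on_gprime": base.apoe_on_gprime.estimate,
            "gprime_dropped": base.gprime_dropped,
            "tables": {k: len(v) for k, v in report.tables.items()}}

        stage = "report"
        summary = summarize_cohort(cohort)
        summary.to_csv(out / "summary.csv")
        manifest["stages"][stage] = {"summarized_variables": int(len(summary))}
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - re-raise with the stage name
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    dio.write_json(manifest, out / "manifest.json")
    return manifest


def _validate_cohort(cohort: pd.DataFrame) -> None:
    required = ["subject_id", "wave"] + INDICATORS + list(COVARIATES) + ["APOE"]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise PipelineError(f"cohort is missing required column(s): {missing}")
    dup = cohort.duplicated(["subject_id", "wave"])
    if dup.any():
        raise PipelineError("each subject may appear at most once per wave")


def summarize_cohort(cohort: pd.DataFrame, wave: int | None = None) -> pd.DataFrame:
    """Descriptive statistics: N non-missing, mean and SD per variable.

    Dichotomous variables are summarized as the proportion coded 1 (the mean
    of the 0/1 indicator) with its n-1-denominator sample SD, matching how
    demographic tables report carrier and group fractions.  A final row
    counts complete cases across the model indicators and covariates.
    """
    df = cohort if wave is None else cohort.loc[cohort["wave"] == wave]
    rows = {}
    for col in df.columns:
        if col in ("subject_id", "wave", "diagnosis"):
            continue
        x = pd.to_numeric(df[col], errors="coerce")
        n = int(x.notna().sum())
        rows[col] = {"N": n,
                     "mean": float(x.mean()) if n else np.nan,
                     "sd": float(x.std(ddof=1)) if n > 1 else np.nan}
    present = [c for c in INDICATORS + list(COVARIATES) if c in df.columns]
    rows["complete_cases"] = {
        "N": int(df[present].notna().all(axis=1).sum()),
        "mean": np.nan, "sd": np.nan}
    out = pd.DataFrame(rows).T
    out.index.name = "variable"
    out["N"] = out["N"].astype(int)
    return out
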