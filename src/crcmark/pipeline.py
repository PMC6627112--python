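"""End-to-end orchestration: simulate -> process -> paired -> survival -> recurrence.

Each stage reads and writes plain TSV tables so every step is independently
runnable; a JSON manifest records stage parameters, input checksums and row
counts for reproducibility.  A fixed seed makes the whole run byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import crcmark
from crcmark import io as cio
from crcmark.config import CohortConfig, MarkerSpec
from crcmark.errors import StageError
from crcmark.paired import summarize_paired
from crcmark.qpcr import marker_qc_summary, process_table
from crcmark.recurrence import run_recurrence_analysis
from crcmark.survival import (
    DEFAULT_MIN_GROUP_FRACTION,
    DEFAULT_PANEL,
    fit_panel_cutoffs,
    km_estimate,
    km_table,
)
from crcmark.synthetic import generate_cohort, generate_ct_table, write_cohort

logger = logging.getLogger("crcmark")

STAGES = ("simulate", "process", "paired", "survival", "recurrence")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    When ``simulate`` is enabled the cohort tables are generated into
    ``outdir``; otherwise ``clinical_path`` / ``qpcr_raw_path`` /
    ``samples_path`` must point at existing inputs.
    """

    outdir: str = "crcmark_run"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortConfig field overrides
    clinical_path: str | None = None
    samples_path: str | None = None
    qpcr_raw_path: str | None = None
    qpcr_tolerance: float = 0.5
    qpcr_ct_max: float = 35.0
    reference_run: str | None = None
    survival_stratum: str | None = "palliative"
    survival_panel: tuple[str, ...] = DEFAULT_PANEL
    min_group_fraction: float = DEFAULT_MIN_GROUP_FRACTION
    recurrence_fold: float = 1.5
    recurrence_consecutive_k: int | None = 2
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise StageError("config", f"unknown configuration key(s): {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "survival_panel" in data:
            data["survival_panel"] = tuple(data["survival_panel"])
        return cls(**data)

    def cohort_config(self) -> CohortConfig:
        overrides = dict(self.cohort)
        if "markers" in overrides:
            overrides["markers"] = tuple(
                MarkerSpec(**m) if isinstance(m, dict) else m for m in overrides["markers"]
            )
        if "followup_samples_range" in overrides:
            overrides["followup_samples_range"] = tuple(overrides["followup_samples_range"])
        overrides.setdefault("seed", self.seed)
        return CohortConfig(**overrides)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write ``manifest.json``.

    Any stage failure aborts the run with a ``StageError`` naming the stage.
    Returns the manifest dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": crcmark.__version__,
        "seed": config.seed,
        "stages": [],
    }
    enabled = [s for s in STAGES if s in config.stages]

    paths: dict[str, Path] = {}
    if config.clinical_path:
        paths["clinical"] = Path(config.clinical_path)
    if config.samples_path:
        paths["samples"] = Path(config.samples_path)
    if config.qpcr_raw_path:
        paths["qpcr_raw"] = Path(config.qpcr_raw_path)

    for stage in enabled:
        logger.info("running stage %s", stage)
        try:
            entry = _STAGE_RUNNERS[stage](config, outdir, paths)
        except StageError:
            raise
        except Exception as exc:  # surface with stage context
            raise StageError(stage, str(exc)) from exc
        entry["name"] = stage
        manifest["stages"].append(entry)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=_json_default))
    logger.info("wrote %s (%d stages)", manifest_path, len(manifest["stages"]))
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage_simulate(config: PipelineConfig, outdir: Path, paths: dict) -> dict:
    cohort_cfg = config.cohort_config()
    clinical, samples = generate_cohort(cohort_cfg)
    qpcr = generate_ct_table(samples, cohort_cfg)
    written = write_cohort(clinical, samples, qpcr, outdir)
    paths.update(written)
    return {
        "parameters": {"seed": cohort_cfg.seed, "n_patients": cohort_cfg.n_patients},
        "outputs": {k: str(v) for k, v in written.items()},
        "row_counts": {"clinical": len(clinical), "samples": len(samples), "qpcr_raw": len(qpcr)},
        "checksums": {k: cio.sha256_of(v) for k, v in written.items()},
    }


def _stage_process(config: PipelineConfig, outdir: Path, paths: dict) -> dict:
    raw_path = paths.get("qpcr_raw")
    if raw_path is None:
        raise StageError("process", "no qPCR raw table available (enable simulate or set qpcr_raw_path)")
    raw = cio.read_qpcr_raw(raw_path)
    levels, log = process_table(
        raw,
        tolerance=config.qpcr_tolerance,
        ct_max=config.qpcr_ct_max,
        reference_run=config.reference_run,
    )
    # serum markers bypass qPCR and join from the sample table
    if "samples" in paths and paths["samples"].exists():
        serum = cio.serum_levels_from_samples(cio.read_samples(paths["samples"]))
        levels = pd.concat([levels, serum], ignore_index=True)
    levels_path = cio.write_tsv(levels, outdir / "levels.tsv")
    qc_path = cio.write_tsv(marker_qc_summary(levels), outdir / "marker_qc.tsv")
    paths["levels"] = levels_path
    return {
        "parameters": {
            "tolerance": config.qpcr_tolerance,
            "ct_max": config.qpcr_ct_max,
            "reference_run": log["reference_run"],
        },
        "inputs": {"qpcr_raw": cio.sha256_of(raw_path)},
        "outputs": {"levels": str(levels_path), "marker_qc": str(qc_path)},
        "row_counts": {"levels": len(levels)},
        "qc_counts": log["qc_counts"],
    }


def _require(paths: dict, key: str, stage: str) -> Path:
    p = paths.get(key)
    if p is None or not Path(p).exists():
        raise StageError(stage, f"required input '{key}' not available")
    return Path(p)


def _stage_paired(config: PipelineConfig, outdir: Path, paths: dict) -> dict:
    levels = cio.read_levels(_require(paths, "levels", "paired"))
    clinical = cio.read_clinical(_require(paths, "clinical", "paired"))
    summary = summarize_paired(levels, clinical, alpha=config.alpha)
    out = cio.write_tsv(cio.format_paired_summary(summary), outdir / "paired_summary.tsv")
    return {
        "parameters": {"alpha": config.alpha},
        "outputs": {"paired_summary": str(out)},
        "row_counts": {"paired_summary": len(summary)},
    }


def _stage_survival(config: PipelineConfig, outdir: Path, paths: dict) -> dict:
    levels = cio.read_levels(_require(paths, "levels", "survival"))
    clinical = cio.read_clinical(_require(paths, "clinical", "survival"))
    fits, matrix, calls, (chi2, p) = fit_panel_cutoffs(
        levels,
        clinical,
        panel=config.survival_panel,
        stratum=config.survival_stratum,
        min_group_fraction=config.min_group_fraction,
    )
    cutoffs_df = pd.DataFrame(
        [
            (f.marker, f.cutoff, f.logrank_chi2, f.p_value, f.n_low, f.n_high, f.candidate_count)
            for f in fits
        ],
        columns=["marker", "cutoff", "chi2", "p", "n_low", "n_high", "candidate_count"],
    )
    cio.write_tsv(cutoffs_df, outdir / "cutoffs.tsv")

    clin = clinical.set_index("patient_id")
    if config.survival_stratum is not None:
        clin = clin[clin["surgery_type"] == config.survival_stratum]
    for f in fits:
        sub = pd.DataFrame(
            {"v": matrix[f.marker], "t": clin["survival_weeks"], "e": clin["death_event"]}
        ).dropna()
        tables = []
        for group, mask in (("low", sub["v"] <= f.cutoff), ("high", sub["v"] > f.cutoff)):
            if mask.sum() == 0:
                continue
            tab = km_table(km_estimate(sub.loc[mask, "t"], sub.loc[mask, "e"]))
            tab.insert(0, "group", group)
            tables.append(tab)
        cio.write_tsv(
            pd.concat(tables, ignore_index=True),
            outdir / f"km_{f.marker.replace('/', '_')}.tsv",
        )

    calls_df = pd.DataFrame(
        [(c.patient_id, c.risk, ";".join(c.triggering_markers)) for c in calls],
        columns=["patient_id", "risk", "triggering_markers"],
    )
    cio.write_tsv(calls_df, outdir / "combined_calls.tsv")
    return {
        "parameters": {
            "stratum": config.survival_stratum,
            "panel": list(config.survival_panel),
            "min_group_fraction": config.min_group_fraction,
        },
        "outputs": {"cutoffs": str(outdir / "cutoffs.tsv"), "combined_calls": str(outdir / "combined_calls.tsv")},
        "row_counts": {"cutoffs": len(cutoffs_df), "combined_calls": len(calls_df)},
        "combined_logrank": {"chi2": chi2, "p": p},
    }


def _stage_recurrence(config: PipelineConfig, outdir: Path, paths: dict) -> dict:
    levels = cio.read_levels(_require(paths, "levels", "recurrence"))
    clinical = cio.read_clinical(_require(paths, "clinical", "recurrence"))
    result = run_recurrence_analysis(
        levels,
        clinical,
        fold=config.recurrence_fold,
        consecutive_k=config.recurrence_consecutive_k,
    )
    cio.write_tsv(result["calls"], outdir / "recurrence_calls.tsv")
    diag_df = cio.diagnostics_frame(result["diagnostics"])
    cio.write_tsv(diag_df, outdir / "diagnostics.tsv")
    cio.write_tsv(result["non_evaluable"], outdir / "non_evaluable.tsv")
    aucs = {}
    for marker, roc in result["roc"].items():
        cio.write_tsv(
            pd.DataFrame(
                {
                    "threshold": np.concatenate([[np.inf], roc.thresholds]),
                    "fpr": roc.fpr,
                    "tpr": roc.tpr,
                }
            ),
            outdir / f"roc_{marker.replace('/', '_')}.tsv",
        )
        aucs[marker] = roc.auc
    (outdir / "recurrence_summary.json").write_text(
        json.dumps(
            {"auc": aucs, "fold": config.recurrence_fold, "consecutive_k": config.recurrence_consecutive_k},
            indent=2,
        )
    )
    return {
        "parameters": {"fold": config.recurrence_fold, "consecutive_k": config.recurrence_consecutive_k},
        "outputs": {"diagnostics": str(outdir / "diagnostics.tsv")},
        "row_counts": {
            "recurrence_calls": len(result["calls"]),
            "diagnostics": len(diag_df),
            "non_evaluable": len(result["non_evaluable"]),
        },
        "auc": aucs,
    }


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "process": _stage_process,
    "paired": _stage_paired,
    "survival": _stage_survival,
    "recurrence": _stage_recurrence,
}
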