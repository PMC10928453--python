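"""End-to-end orchestration: simulate (or load) → preprocess → stratify →
classify → survival, with one YAML config, derived per-stage seeds and a
machine-readable run report.

The root ``seed`` is fanned out deterministically: stage *i* (0 = simulate,
1 = classify) uses ``(seed * 1_000_003 + i) mod 2³¹``, so any stage can be
rerun in isolation with the exact stream it saw inside the full run.
Reports are pure functions of the config; rerunning an identical config
reproduces an identical ``report.json`` apart from the timestamps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .errors import ConfigError, IrsurvError
from .preprocess import (
    FINGERPRINT_HIGH,
    FINGERPRINT_LOW,
    PreprocessConfig,
    SpectralDataset,
    concatenate_datasets,
    preprocess_patient,
)
from .classify import bootstrap_evaluate
from .spectra_io import read_cohort, read_cube, read_mask, write_cohort_table
from .stratify import label_endpoint, stratify_by_outcome
from .survstats import cox_fit, reverse_analysis
from .synthdata import SimulationConfig, simulate_cohort

logger = logging.getLogger("irsurv.pipeline")

__all__ = ["validate_config", "run_pipeline", "stage_seed"]

_STAGES = ("simulate", "preprocess", "stratify", "classify", "survival")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "stratify": {"min_group_size": 3, "censored_policy": "exclude", "cutoff_months": None},
    "classify": {
        "n_components": 7,
        "ridge_penalty": 1e-4,
        "n_replicates": 500,
        "threshold": 0.5,
    },
    "survival": {"min_group_size": 3, "alpha": 0.05},
}


def stage_seed(root_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return (int(root_seed) * 1_000_003 + stage_index) % (2**31)


def _merge_defaults(section: dict[str, Any] | None, defaults: dict[str, Any]) -> dict:
    merged = dict(defaults)
    merged.update(section or {})
    return merged


def validate_config(source: str | Path | dict) -> tuple[dict, list[str], list[str]]:
    """Normalise a run config, filling defaults and checking cross-field
    constraints.  Returns ``(config, errors, warnings)``; errors name the
    offending field paths.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    errors: list[str] = []
    warnings: list[str] = []
    config: dict[str, Any] = {
        "seed": int(raw.get("seed", 0)),
        "run_dir": str(raw.get("run_dir", "runs/run")),
        "data": raw.get("data"),  # None → synthetic mode
    }
    for section in ("stratify", "classify", "survival"):
        config[section] = _merge_defaults(raw.get(section), _DEFAULTS[section])

    try:
        sim = SimulationConfig(**(raw.get("simulate") or {}))
        config["simulate"] = sim.to_dict()
        if not (
            sim.wavenumber_start <= FINGERPRINT_LOW
            and FINGERPRINT_HIGH <= sim.wavenumber_end
        ):
            errors.append(
                "simulate.wavenumber_start/wavenumber_end: fingerprint window "
                f"[{FINGERPRINT_LOW}, {FINGERPRINT_HIGH}] not inside axis range"
            )
    except (ConfigError, TypeError) as exc:
        errors.append(f"simulate: {exc}")
        config["simulate"] = raw.get("simulate") or {}

    try:
        pre = PreprocessConfig(**(raw.get("preprocess") or {}))
        config["preprocess"] = asdict(pre)
    except (IrsurvError, TypeError) as exc:
        errors.append(f"preprocess: {exc}")
        config["preprocess"] = raw.get("preprocess") or {}

    if config["classify"]["n_replicates"] < 10:
        errors.append("classify.n_replicates: need at least 10 replicates")
    if not 0 < config["survival"]["alpha"] < 1:
        errors.append("survival.alpha: must lie in (0, 1)")
    if config["stratify"]["cutoff_months"] is not None:
        warnings.append(
            "stratify.cutoff_months supplied: the outcome-driven cut-off search "
            "is skipped and the supplied value is used"
        )
    if config["data"] is not None:
        for key in ("cohort",):
            if key not in config["data"]:
                errors.append(f"data.{key}: required in user-data mode")
    return config, errors, warnings


def _load_user_data(data_cfg: dict):
    directory = Path(data_cfg.get("directory", "."))
    cohort = read_cohort(data_cfg["cohort"])
    cubes, masks = [], []
    for pid in cohort["patient_id"]:
        cubes.append(read_cube(directory / f"{pid}.cube.json"))
        mask_csv = directory / f"{pid}.mask.csv"
        mask_png = directory / f"{pid}.mask.png"
        masks.append(read_mask(mask_csv if mask_csv.exists() else mask_png, pid))
    return cubes, masks, cohort, None


def run_pipeline(config: str | Path | dict, run_dir: str | Path | None = None) -> dict:
    """Execute every stage and return (and write) the run report.

    Any stage failure re-raises with the stage name after writing a partial
    report to ``<run_dir>/report.partial.json``.
    """
    config, errors, warnings = validate_config(config)
    if errors:
        raise ConfigError("; ".join(errors))
    for w in warnings:
        logger.warning(w)

    run_path = Path(run_dir if run_dir is not None else config["run_dir"])
    results_dir = run_path / "results"
    intermediate_dir = run_path / "intermediate"
    results_dir.mkdir(parents=True, exist_ok=True)
    intermediate_dir.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {
        "schema_version": 1,
        "software_version": __version__,
        "seed": config["seed"],
        "config": config,
        "warnings": warnings,
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
    }
    stage = "simulate"
    try:
        # --- simulate or load -------------------------------------------------
        if config["data"] is None:
            sim_cfg = dict(config["simulate"])
            sim_cfg["mask_shift"] = tuple(sim_cfg["mask_shift"])
            sim_cfg["seed"] = stage_seed(config["seed"], 0)
            synthetic = simulate_cohort(SimulationConfig(**sim_cfg))
            cubes, masks, cohort = synthetic.cubes, synthetic.masks, synthetic.cohort
            refs = synthetic.references
        else:
            from .synthdata import make_reference_spectra

            cubes, masks, cohort, _ = _load_user_data(config["data"])
            refs = make_reference_spectra(cubes[0].axis)
        write_cohort_table(cohort, intermediate_dir / "cohort.tsv")
        report["stages"]["simulate"] = {
            "mode": "synthetic" if config["data"] is None else "user",
            "n_patients": int(len(cohort)),
            "n_events": int(cohort["event"].sum()),
            "outputs": ["intermediate/cohort.tsv"],
        }

        # --- preprocess -------------------------------------------------------
        stage = "preprocess"
        pre_cfg = PreprocessConfig(**config["preprocess"])
        parts, patient_reports = [], []
        for cube, mask in zip(cubes, masks):
            dataset, patient_report = preprocess_patient(cube, mask, refs, pre_cfg)
            patient_reports.append(patient_report)
            if not patient_report["excluded"]:
                parts.append(dataset)
        dataset = concatenate_datasets(parts)
        report["stages"]["preprocess"] = {
            "inputs": ["intermediate/cohort.tsv"],
            "n_datapoints": int(dataset.n_datapoints),
            "n_fingerprint_wavenumbers": int(dataset.axis.size),
            "patients": patient_reports,
        }

        # --- stratify ---------------------------------------------------------
        stage = "stratify"
        if config["stratify"]["cutoff_months"] is not None:
            cutoff = float(config["stratify"]["cutoff_months"])
            strat_record: dict[str, Any] = {"cutoff_months": cutoff, "source": "config"}
        else:
            strat = stratify_by_outcome(
                cohort,
                min_group_size=config["stratify"]["min_group_size"],
                censored_policy=config["stratify"]["censored_policy"],
            )
            cutoff = strat.cutoff_months
            strat.candidate_profile.to_csv(
                intermediate_dir / "stratification_profile.tsv", sep="\t", index=False
            )
            strat_record = {
                "cutoff_months": cutoff,
                "source": "log-rank maximisation",
                "statistic": strat.statistic_at_cutoff,
                "p_value": strat.p_value_at_cutoff,
                "n_high": int((strat.assignments == "high").sum()),
                "n_low": int((strat.assignments == "low").sum()),
                "n_excluded": int((strat.assignments == "excluded").sum()),
            }
        labels = label_endpoint(cohort, cutoff)
        strat_record["inputs"] = ["intermediate/cohort.tsv"]
        strat_record["n_labelled"] = int(len(labels))
        report["stages"]["stratify"] = strat_record

        # --- classify ---------------------------------------------------------
        stage = "classify"
        summary, scores = bootstrap_evaluate(
            dataset,
            labels,
            n_replicates=config["classify"]["n_replicates"],
            seed=stage_seed(config["seed"], 1),
            n_components=config["classify"]["n_components"],
            ridge_penalty=config["classify"]["ridge_penalty"],
            threshold=config["classify"]["threshold"],
        )
        scored = cohort.copy()
        scored["score"] = scored["patient_id"].astype(str).map(scores)
        write_cohort_table(scored, results_dir / "cohort_scored.tsv")
        report["stages"]["classify"] = {
            "inputs": ["intermediate/cohort.tsv"],
            "n_replicates": summary.n_replicates,
            "median_auroc": summary.median_auroc,
            "median_sensitivity": summary.median_sensitivity,
            "median_specificity": summary.median_specificity,
            "dispersion": summary.dispersion,
            "outputs": ["results/cohort_scored.tsv"],
        }

        # --- survival ---------------------------------------------------------
        stage = "survival"
        scored_only = scored.dropna(subset=["score"])
        cox = cox_fit(
            scored_only["score"].to_numpy(),
            scored_only["time_months"].to_numpy(),
            scored_only["event"].to_numpy(),
        )
        reverse = reverse_analysis(
            scores,
            cohort,
            min_group_size=config["survival"]["min_group_size"],
            alpha=config["survival"]["alpha"],
        )
        reverse.km_high.to_frame().to_csv(
            results_dir / "km_high.tsv", sep="\t", index=False
        )
        reverse.km_low.to_frame().to_csv(
            results_dir / "km_low.tsv", sep="\t", index=False
        )
        report["stages"]["survival"] = {
            "inputs": ["results/cohort_scored.tsv"],
            "cox": {
                "hazard_ratio": cox.hazard_ratio,
                "ci_lower": cox.ci_lower,
                "ci_upper": cox.ci_upper,
                "p_value": cox.p_value,
                "n_events": cox.n_events,
                "separated": cox.separated,
            },
            "reverse_analysis": {
                "threshold": reverse.threshold,
                "logrank_statistic": reverse.logrank.statistic,
                "logrank_p": reverse.logrank.p_value,
                "n_high": int((reverse.groups == "high").sum()),
                "n_low": int((reverse.groups == "low").sum()),
            },
            "outputs": ["results/km_high.tsv", "results/km_low.tsv"],
        }
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (run_path / "report.partial.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
        )
        raise IrsurvError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["finished"] = datetime.now(timezone.utc).isoformat()
    (run_path / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"
    )
    return report
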