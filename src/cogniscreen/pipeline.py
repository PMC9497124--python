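"""End-to-end orchestration: preprocess → features → assemble → evaluate.

Stages are pure functions of (inputs, config, seed); the single
configured seed fans out to per-stage seeds by stable hashing of the
stage name, so stages stay reproducible and independent.  Each stage
failure is re-raised as a :class:`StageError` tagged with the stage
name, leaving already-written artifacts on disk.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification, et_features, features_assembly
from .classification import SVMConfig, compare_models, default_grid, grid_search
from .eeg_features import EEGFeatureConfig, extract_subject_eeg_features
from .eeg_processing import (
    EEGRecording,
    denoise_eeg,
    detect_electrode_offset,
    read_eeg_csv,
    segment_signal,
)
from .et_features import ETConfig, extract_subject_et_features, read_et_csv
from .features_assembly import FeatureTable, assemble, clean_ntb
from .synthetic_cohort import NTB_RANGES, SimulatedCohort

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StageError",
    "stage_seed",
    "extract_cohort_tables",
    "tables_from_cohort",
    "run_pipeline",
    "write_report",
]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class EEGParams:
    passband: tuple[float, float] = (0.5, 30.0)
    notch: float = 50.0
    order: int = 2
    window_s: float = 5.0
    overlap_frac: float = 0.6
    flat_run_s: float = 1.0
    rail_frac: float = 0.95
    full_scale_uv: float = 200.0


@dataclass
class PipelineConfig:
    """Structured pipeline configuration (YAML-loadable)."""

    eeg: EEGParams = field(default_factory=EEGParams)
    et: ETConfig = field(default_factory=ETConfig)
    features: EEGFeatureConfig = field(default_factory=EEGFeatureConfig)
    mrmr_k: int = 20
    mrmr_bins: int = 8
    mrmr_criterion: str = "miq"
    svm: SVMConfig = field(default_factory=SVMConfig)
    cv_folds: int = 5
    seed: int = 0
    run_grid_search: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        if "eeg" in d:
            e = dict(d["eeg"])
            if "passband" in e:
                e["passband"] = tuple(e["passband"])
            cfg.eeg = EEGParams(**e)
        if "et" in d:
            e = dict(d["et"])
            if "aoi" in e:
                e["aoi"] = tuple(e["aoi"])
            cfg.et = ETConfig(**e)
        if "features" in d:
            cfg.features = EEGFeatureConfig(**d["features"])
        if "svm" in d:
            cfg.svm = SVMConfig(**d["svm"])
        for key in ("mrmr_k", "mrmr_bins", "mrmr_criterion", "cv_folds", "seed", "run_grid_search"):
            if key in d:
                setattr(cfg, key, d[key])
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed by stable hashing of the stage name."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _eeg_features_for_recording(rec: EEGRecording, cfg: PipelineConfig) -> dict | None:
    rec = detect_electrode_offset(
        rec, cfg.eeg.flat_run_s, cfg.eeg.rail_frac, cfg.eeg.full_scale_uv
    )
    if not rec.valid:
        log.info("excluding %s: %s", rec.subject_id, ", ".join(rec.invalid_reasons))
        return None
    rec = denoise_eeg(rec, cfg.eeg.passband, cfg.eeg.notch, cfg.eeg.order)
    segs = segment_signal(rec, cfg.eeg.window_s, cfg.eeg.overlap_frac)
    return extract_subject_eeg_features(segs, cfg.features)


def tables_from_cohort(cohort: SimulatedCohort, cfg: PipelineConfig | None = None) -> FeatureTable:
    """Assemble the full feature table straight from an in-memory cohort."""
    cfg = cfg or PipelineConfig()
    eeg_rows, et_rows = [], []
    try:
        for rec in cohort.subjects:
            feats = _eeg_features_for_recording(rec.eeg, cfg)
            if feats is not None:
                eeg_rows.append({"subject_id": rec.subject_id, **feats})
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise StageError("eeg_processing", exc) from exc
    try:
        for rec in cohort.subjects:
            feats = extract_subject_et_features(rec.et, cfg.et)
            et_rows.append({"subject_id": rec.subject_id, **feats})
    except Exception as exc:  # noqa: BLE001
        raise StageError("et_features", exc) from exc
    try:
        ntb, _ = clean_ntb(cohort.ntb, NTB_RANGES)
        return assemble(
            cohort.demographics, ntb, pd.DataFrame(eeg_rows), pd.DataFrame(et_rows), view="all"
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("features_assembly", exc) from exc


def extract_cohort_tables(cohort_dir, cfg: PipelineConfig | None = None) -> FeatureTable:
    """Assemble the feature table from an on-disk cohort layout."""
    cfg = cfg or PipelineConfig()
    root = Path(cohort_dir)
    demographics = pd.read_csv(root / "demographics.csv")
    ntb_raw = pd.read_csv(root / "ntb.csv")
    eeg_rows, et_rows = [], []
    for sid in demographics["subject_id"]:
        sdir = root / str(sid)
        try:
            rec = read_eeg_csv(sdir / "eeg.csv", subject_id=str(sid))
            feats = _eeg_features_for_recording(rec, cfg)
            if feats is not None:
                eeg_rows.append({"subject_id": sid, **feats})
        except FileNotFoundError:
            log.info("no EEG file for %s", sid)
        except Exception as exc:  # noqa: BLE001
            raise StageError("eeg_processing", exc) from exc
        try:
            stream = read_et_csv(sdir / "et.csv", subject_id=str(sid))
            et_rows.append(
                {"subject_id": sid, **extract_subject_et_features(stream, cfg.et)}
            )
        except FileNotFoundError:
            log.info("no ET file for %s", sid)
        except Exception as exc:  # noqa: BLE001
            raise StageError("et_features", exc) from exc
    try:
        ntb, _ = clean_ntb(ntb_raw, NTB_RANGES)
        return assemble(
            demographics, ntb, pd.DataFrame(eeg_rows), pd.DataFrame(et_rows), view="all"
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("features_assembly", exc) from exc


def _strip_private(report: dict) -> dict:
    clean = json.loads(json.dumps({k: v for k, v in report.items()}, default=_json_default))
    for view in clean.get("views", {}).values():
        view.pop("_final_artifact", None)
    return clean


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(
    config: PipelineConfig,
    cohort1_dir,
    cohort2_dir=None,
    out_dir=None,
) -> dict:
    """Execute the full pipeline on on-disk cohorts and write artifacts."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    t1 = extract_cohort_tables(cohort1_dir, config)
    t2 = extract_cohort_tables(cohort2_dir, config) if cohort2_dir is not None else None
    if out is not None:
        t1.data.to_csv(out / "features_cohort1.csv", float_format="%.10g")
        if t2 is not None:
            t2.data.to_csv(out / "features_cohort2.csv", float_format="%.10g")

    svm_cfg = config.svm
    try:
        if config.run_grid_search:
            svm_cfg, grid_results = grid_search(
                t1.view("all"),
                folds=config.cv_folds,
                seed=stage_seed(config.seed, "grid_search"),
                select_k=config.mrmr_k,
            )
            if out is not None:
                grid_results.to_csv(out / "grid_search.csv", index=False, float_format="%.10g")
        report = compare_models(
            t1,
            t2,
            config=svm_cfg,
            seed=stage_seed(config.seed, "evaluate"),
            select_k=config.mrmr_k,
            criterion=config.mrmr_criterion,
            n_bins=config.mrmr_bins,
            k=config.cv_folds,
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("classification", exc) from exc

    report = _strip_private(report)
    if out is not None:
        write_report(report, out)
    return report


def write_report(report: dict, out_dir) -> None:
    """Write the evaluation report: JSON, model-comparison CSVs, ROC points."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = _strip_private(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    rows_cv, rows_test = [], []
    for view, entry in report.get("views", {}).items():
        cv = entry["cv"]
        rows_cv.append(
            {
                "model": view,
                "accuracy_mean": cv["accuracy_mean"],
                "accuracy_sd": cv["accuracy_sd"],
                "sensitivity_mean": cv["sensitivity_mean"],
                "sensitivity_sd": cv["sensitivity_sd"],
                "specificity_mean": cv["specificity_mean"],
                "specificity_sd": cv["specificity_sd"],
                "auc": cv["auc"],
                "auc_ci_low": cv["auc_ci"][0],
                "auc_ci_high": cv["auc_ci"][1],
            }
        )
        pd.DataFrame(cv["roc"]).to_csv(
            out / f"roc_{view}_cohort1.csv", index=False, float_format="%.10g"
        )
        if "test" in entry:
            te = entry["test"]
            rows_test.append(
                {
                    "model": view,
                    "accuracy": te["accuracy"],
                    "accuracy_boot_sd": te["accuracy_boot_sd"],
                    "sensitivity": te["sensitivity"],
                    "specificity": te["specificity"],
                    "auc": te["auc"],
                    "auc_ci_low": te["auc_ci"][0],
                    "auc_ci_high": te["auc_ci"][1],
                }
            )
            pd.DataFrame(te["roc"]).to_csv(
                out / f"roc_{view}_cohort2.csv", index=False, float_format="%.10g"
            )
    pd.DataFrame(rows_cv).to_csv(out / "models_cohort1.csv", index=False, float_format="%.10g")
    if rows_test:
        pd.DataFrame(rows_test).to_csv(
            out / "models_cohort2.csv", index=False, float_format="%.10g"
        )
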