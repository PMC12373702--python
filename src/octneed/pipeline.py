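"""End-to-end pipeline: simulate → export → biomarkers → labels → evaluate.

Configuration is a YAML document validated against pydantic models (the
generated JSON schema is versioned under ``octneed/schemas``).  Every
stage writes its artifacts under the output root and records a SHA-256
per artifact in the run manifest, making full-run determinism checkable
by comparing manifests.  Completed stages are skipped on re-runs when
their configuration hash matches (cache hit).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import biomarkers as bm
from . import io as oio
from .cohort import CohortConfig, DeviceProfile, simulate_cohort
from .datasets import EXPERIMENTS, CohortDataset
from .evaluation import run_experiment
from .labels import LabelSet, first_interval_label, final_interval_label, yearly_need_label

log = logging.getLogger("octneed")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class CohortSection(BaseModel):
    n_patients: int = Field(40, gt=0)
    step_weeks: int = 2
    min_interval_weeks: int = 8
    max_interval_weeks: int = 16
    activity_mu: float = 2.5
    activity_sigma: float = 1.1
    decay_rate: float = 0.15
    noise_sd: float = 0.35
    srf_gain: float = 2.5
    horizon_weeks: int = Field(104, ge=52)
    late_start_fraction: float = Field(0.5, ge=0.0, le=1.0)


class DeviceSection(BaseModel):
    axial_um_per_px: float = Field(7.0, gt=0)
    lateral_um_per_px: float = Field(23.3333333333, gt=0)
    bscan_spacing_um: float = Field(120.0, gt=0)
    n_bscans: int = Field(31, ge=28)
    height_px: int = Field(192, gt=0)
    width_px: int = Field(144, gt=0)
    intensity_gamma: float = Field(1.0, gt=0)
    speckle_sd: float = Field(0.22, ge=0)


class BiomarkerSection(BaseModel):
    relative_threshold: float = Field(0.45, gt=0)
    min_size: int = Field(20, ge=0)
    smooth_sigma: float = Field(0.4, ge=0)


class EvaluateSection(BaseModel):
    experiments: List[str] = ["1", "2y1", "2y2", "3"]
    model: str = "logreg"
    repeats: int = Field(5, gt=0)
    l2_strength: float = Field(1.0, gt=0)

    @field_validator("experiments")
    @classmethod
    def _known(cls, v):
        unknown = [e for e in v if e not in EXPERIMENTS]
        if unknown:
            raise ValueError(f"unknown experiment id(s): {unknown}")
        return v


class RunConfig(BaseModel):
    seed: int = 0
    output_root: str = "octneed_run"
    log_level: str = "INFO"
    cohort: CohortSection = CohortSection()
    device: DeviceSection = DeviceSection()
    biomarkers: BiomarkerSection = BiomarkerSection()
    evaluate: EvaluateSection = EvaluateSection()

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(seed=self.seed, **self.cohort.model_dump())

    def device_profile(self) -> DeviceProfile:
        return DeviceProfile(**self.device.model_dump())

    def segmentation_params(self) -> bm.SegmentationParams:
        return bm.SegmentationParams(**self.biomarkers.model_dump())


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.model_dump(), sort_keys=True).encode()).hexdigest()


def _stage_fresh(meta_path: Path, stage: str, chash: str, outputs) -> bool:
    if not meta_path.exists():
        return False
    meta = json.loads(meta_path.read_text())
    ok = meta.get(stage) == chash and all(Path(o).exists() for o in outputs)
    return ok


def _mark_stage(meta_path: Path, stage: str, chash: str) -> None:
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    meta[stage] = chash
    meta_path.write_text(json.dumps(meta, sort_keys=True, indent=1))


def _labels_from_visits(visits: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for pid, g in visits.groupby("patient_id", sort=True):
        g = g.sort_values("week")
        inj_weeks = [int(w) for w, giv in zip(g.week, g.injection_given)
                     if str(giv).lower() in ("true", "1")]
        decisions = [d for d in g.decision if str(d) != ""]
        first = (first_interval_label(decisions[:4]).value if len(decisions) >= 4 else "")
        assigned = [a for a in g.assigned_interval_weeks if str(a) != ""]
        final = final_interval_label(int(float(assigned[-1]))).value if assigned else ""
        last_week = max(inj_weeks) if inj_weeks else -1
        y1 = yearly_need_label(inj_weeks, 1).value if last_week >= 0 else ""
        y2 = yearly_need_label(inj_weeks, 2).value if last_week >= 52 else ""
        rows.append({"patient_id": pid, "first_interval": first, "year1_need": y1,
                     "year2_need": y2, "final_interval": final})
    df = pd.DataFrame(rows, columns=list(oio.LABELS_COLUMNS))
    oio.validate_columns(df, oio.LABELS_COLUMNS, "labels table")
    return df


def compute_biomarkers(data_dir: Path, params: bm.SegmentationParams) -> pd.DataFrame:
    """Stand-in segmentation + quantification of every exported scan."""
    manifest = json.loads((data_dir / "manifest.json").read_text())
    rows = []
    for entry in manifest["patients"]:
        for scan in entry["scans"]:
            vol = oio.read_volume(data_dir / scan["scan"])
            mask_gt = oio.read_mask(data_dir / scan["mask"])
            seg = bm.segment_fluid_standin(vol, mask_gt.layers, params)
            metrics = bm.compute_fluid_metrics(seg)
            rows.append({
                "scan_id": vol.meta.get("scan_id", Path(scan["scan"]).stem),
                "patient_id": entry["patient_id"],
                "week": scan["week"],
                "irf_volume_nl": metrics.irf_volume_nl,
                "srf_volume_nl": metrics.srf_volume_nl,
                "srf_max_height_um": metrics.srf_max_height_um,
                "irf_present": metrics.irf_present,
                "srf_present": metrics.srf_present,
                "srf_ge_50um": metrics.srf_ge_50um,
            })
    df = pd.DataFrame(rows, columns=list(oio.METRICS_COLUMNS))
    oio.validate_columns(df, oio.METRICS_COLUMNS, "metrics table")
    return df


def _dataset_from_tables(metrics: pd.DataFrame, labels: pd.DataFrame,
                         manifest: dict) -> CohortDataset:
    from .labels import Interval, Need

    arms = {e["patient_id"]: e["arm"] for e in manifest["patients"]}
    wide = metrics.pivot(index="patient_id", columns="week",
                         values=["irf_volume_nl", "srf_volume_nl", "srf_max_height_um"])
    feats, ids, arm_list, lsets = [], [], [], []
    lab = labels.set_index("patient_id")
    for pid in wide.index:
        irf8 = wide.loc[pid, ("irf_volume_nl", 8)]
        irf16 = wide.loc[pid, ("irf_volume_nl", 16)]
        srf8 = wide.loc[pid, ("srf_volume_nl", 8)]
        srf16 = wide.loc[pid, ("srf_volume_nl", 16)]
        h8 = wide.loc[pid, ("srf_max_height_um", 8)]
        h16 = wide.loc[pid, ("srf_max_height_um", 16)]
        feats.append([irf8, irf16, srf8, srf16, h8, h16, irf16 - irf8, srf16 - srf8])
        ids.append(pid)
        arm_list.append(arms.get(pid, "early_start"))
        r = lab.loc[pid]
        lsets.append(LabelSet(
            first_interval=Interval(r.first_interval) if r.first_interval else None,
            year1_need=Need(r.year1_need) if r.year1_need else None,
            year2_need=Need(r.year2_need) if r.year2_need else None,
            final_interval=Interval(r.final_interval) if r.final_interval else None,
        ))
    return CohortDataset(patient_ids=np.array(ids), arms=np.array(arm_list),
                         label_sets=lsets, features=np.asarray(feats, dtype=float))


def run_pipeline(config: RunConfig, out_dir: Optional[str] = None) -> Path:
    """Execute all stages; returns the path of the run manifest.

    Artifacts: ``data/`` (scans, masks, visits.csv, manifest.json),
    ``metrics.csv``, ``labels.csv``, ``results.json`` and
    ``run_manifest.json`` with per-artifact SHA-256 hashes.
    """
    out = Path(out_dir or config.output_root)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    chash = _config_hash(config)
    meta_path = out / "stage_meta.json"
    artifacts = {}
    stage = "simulate"
    try:
        cohort = simulate_cohort(config.cohort_config())

        stage = "export"
        data_dir = out / "data"
        if _stage_fresh(meta_path, stage, chash, [data_dir / "manifest.json"]):
            log.info("export: cache hit, skipping")
        else:
            oio.export_cohort(cohort, data_dir, config.device_profile(), seed=config.seed)
            _mark_stage(meta_path, stage, chash)
        artifacts["visits"] = data_dir / "visits.csv"
        artifacts["data_manifest"] = data_dir / "manifest.json"

        stage = "biomarkers"
        metrics_path = out / "metrics.csv"
        if _stage_fresh(meta_path, stage, chash, [metrics_path]):
            log.info("biomarkers: cache hit, skipping recomputation")
        else:
            compute_biomarkers(data_dir, config.segmentation_params()).to_csv(
                metrics_path, index=False, float_format="%.6f")
            _mark_stage(meta_path, stage, chash)
        artifacts["metrics"] = metrics_path

        stage = "labels"
        labels_path = out / "labels.csv"
        visits = oio.import_visits(data_dir / "visits.csv")
        _labels_from_visits(visits).to_csv(labels_path, index=False)
        artifacts["labels"] = labels_path

        stage = "evaluate"
        manifest = json.loads((data_dir / "manifest.json").read_text())
        metrics = pd.read_csv(metrics_path)
        labels = pd.read_csv(labels_path, keep_default_na=False)
        ds = _dataset_from_tables(metrics, labels, manifest)
        results = {}
        for exp in config.evaluate.experiments:
            try:
                res = run_experiment(ds, exp, model_kind=config.evaluate.model,
                                     repeats=config.evaluate.repeats, seed=config.seed,
                                     l2_strength=config.evaluate.l2_strength)
            except ValueError as err:
                log.warning("experiment %s skipped: %s", exp, err)
                results[exp] = {"skipped": str(err)}
                continue
            results[exp] = {
                "auc_mean": round(res.auc_mean, 6),
                "auc_std": round(res.auc_std, 6),
                "accuracy": round(res.accuracy, 6),
                "sensitivity": round(res.sensitivity, 6),
                "specificity": round(res.specificity, 6),
                "n_positive": res.n_positive,
                "n_negative": res.n_negative,
                "n_excluded": res.n_excluded,
            }
        results_path = out / "results.json"
        results_path.write_text(json.dumps(results, sort_keys=True, indent=1))
        artifacts["results"] = results_path

        stage = "manifest"
        run_manifest = {
            "seed": config.seed,
            "config": config.model_dump(),
            "config_sha256": chash,
            "artifacts": {k: {"path": str(p.relative_to(out)), "sha256": oio.file_sha256(p)}
                          for k, p in artifacts.items()},
        }
        manifest_path = out / "run_manifest.json"
        manifest_path.write_text(json.dumps(run_manifest, sort_keys=True, indent=1))
        return manifest_path
    except PipelineError:
        raise
    except Exception as err:
        partial = {"failed_stage": stage, "error": str(err),
                   "artifacts": {k: str(p) for k, p in artifacts.items()}}
        (out / "run_manifest.partial.json").write_text(json.dumps(partial, sort_keys=True))
        raise PipelineError(stage, err) from err
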