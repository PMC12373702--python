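"""Readers, writers and schemas shared by all pipeline stages.

Scan volumes travel as multi-page TIFF (one page per B-scan, with a JSON
sidecar carrying spacings and metadata — TIFF has no standard spacing
fields) or as NRRD with spacings in the header (via SimpleITK).
Segmentation masks use the same containers with integer labels
{0 background, 1 IRF, 2 SRF}.  Visit tables and biomarker metrics are
CSV with fixed, validated column sets; cohort exports are bound together
by a JSON manifest keyed on patient id and acquisition week.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .biomarkers import SegmentationMask
from .cohort import Decision, DeviceProfile, PatientRecord
from .preprocess import LayerSet, OCTVolume
from .render import render_scan

__all__ = [
    "VISITS_COLUMNS",
    "METRICS_COLUMNS",
    "LABELS_COLUMNS",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "visits_to_frame",
    "validate_columns",
    "export_cohort",
    "import_visits",
    "file_sha256",
]

VISITS_COLUMNS = ("patient_id", "week", "injection_given", "assigned_interval_weeks", "decision")
METRICS_COLUMNS = ("scan_id", "patient_id", "week", "irf_volume_nl", "srf_volume_nl",
                   "srf_max_height_um", "irf_present", "srf_present", "srf_ge_50um")
LABELS_COLUMNS = ("patient_id", "first_interval", "year1_need", "year2_need", "final_interval")


def validate_columns(df: pd.DataFrame, columns: Sequence[str], what: str = "table") -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: OCTVolume, path) -> Path:
    """Write a volume as multi-page TIFF (+ JSON sidecar) or NRRD.

    TIFF stores float32 pages unless the volume was quantized to uint8
    upstream; NRRD carries the spacings in its header.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, vol.intensities, photometric="minisblack")
        sidecar = {
            "spacings_um": [float(s) for s in vol.spacings],
            "meta": _jsonable(vol.meta),
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True, indent=1))
    elif path.suffix.lower() == ".nrrd":
        img = sitk.GetImageFromArray(vol.intensities)
        bsp, ax, lat = vol.spacings
        img.SetSpacing((float(lat), float(ax), float(bsp)))
        for k, v in _jsonable(vol.meta).items():
            img.SetMetaData(str(k), json.dumps(v))
        sitk.WriteImage(img, str(path), useCompression=False)
    else:
        raise ValueError(f"unknown volume format: {path.suffix}")
    return path


def read_volume(path) -> OCTVolume:
    """Read a TIFF (+ sidecar) or NRRD volume; spacings are mandatory."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"TIFF volume {path.name} has no spacing sidecar: expected {sidecar}")
        info = json.loads(sidecar.read_text())
        if "spacings_um" not in info:
            raise ValueError(f"sidecar {sidecar} lacks 'spacings_um'")
        data = tifffile.imread(path)
        if data.dtype == np.uint8:
            data = data.astype(np.float32) / 255.0
        return OCTVolume(np.asarray(data, dtype=np.float32),
                         tuple(info["spacings_um"]), meta=info.get("meta", {}))
    if path.suffix.lower() == ".nrrd":
        img = sitk.ReadImage(str(path))
        lat, ax, bsp = img.GetSpacing()
        data = sitk.GetArrayFromImage(img)
        if data.dtype == np.uint8:
            data = data.astype(np.float32) / 255.0
        meta = {}
        for k in img.GetMetaDataKeys():
            if k.startswith(("NRRD", "ITK", "space", "kinds", "type", "dimension", "sizes")):
                continue
            try:
                meta[k] = json.loads(img.GetMetaData(k))
            except (json.JSONDecodeError, TypeError):
                meta[k] = img.GetMetaData(k)
        return OCTVolume(np.asarray(data, dtype=np.float32), (bsp, ax, lat), meta=meta)
    raise ValueError(f"unknown volume format: {path.suffix}")


def write_mask(mask: SegmentationMask, path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, mask.labels.astype(np.uint8), photometric="minisblack")
        sidecar = {"spacings_um": [float(s) for s in mask.spacings], "meta": _jsonable(mask.meta)}
        if mask.layers is not None:
            sidecar["layers"] = {k: np.round(v, 4).tolist() for k, v in mask.layers.surfaces.items()}
        _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True))
    elif path.suffix.lower() == ".nrrd":
        img = sitk.GetImageFromArray(mask.labels.astype(np.uint8))
        bsp, ax, lat = mask.spacings
        img.SetSpacing((float(lat), float(ax), float(bsp)))
        sitk.WriteImage(img, str(path), useCompression=False)
    else:
        raise ValueError(f"unknown mask format: {path.suffix}")
    return path


def read_mask(path) -> SegmentationMask:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"mask {path.name} has no sidecar: expected {sidecar}")
        info = json.loads(sidecar.read_text())
        layers = None
        if "layers" in info:
            layers = LayerSet({k: np.asarray(v) for k, v in info["layers"].items()})
        return SegmentationMask(tifffile.imread(path), tuple(info["spacings_um"]),
                                layers=layers, meta=info.get("meta", {}))
    if path.suffix.lower() == ".nrrd":
        img = sitk.ReadImage(str(path))
        lat, ax, bsp = img.GetSpacing()
        return SegmentationMask(sitk.GetArrayFromImage(img), (bsp, ax, lat))
    raise ValueError(f"unknown mask format: {path.suffix}")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()
                if not isinstance(v, (np.ndarray, DeviceProfile))}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def visits_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        for v in p.visits:
            rows.append({
                "patient_id": p.patient_id,
                "week": v.week,
                "injection_given": v.injection_given,
                "assigned_interval_weeks": (v.assigned_interval_weeks
                                            if v.assigned_interval_weeks is not None else ""),
                "decision": v.decision.value if v.decision is not None else "",
            })
    df = pd.DataFrame(rows, columns=list(VISITS_COLUMNS))
    validate_columns(df, VISITS_COLUMNS, "visits table")
    return df


def import_visits(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    validate_columns(df, VISITS_COLUMNS, "visits table")
    return df


def export_cohort(
    cohort: Sequence[PatientRecord],
    out_dir,
    device: Optional[DeviceProfile] = None,
    seed: int = 0,
    weeks: Tuple[int, ...] = (8, 16),
    fmt: str = "tiff",
    quantize: bool = True,
) -> Path:
    """Render and write a cohort to disk; returns the manifest path.

    Per scan one volume file (8-bit grayscale by default) and one mask
    file are written; the visit trajectories go to ``visits.csv`` and a
    JSON manifest binds scan files to visits by acquisition week.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scans_dir = out / "scans"
    scans_dir.mkdir(exist_ok=True)
    device = device or DeviceProfile()
    ext = {"tiff": ".tif", "nrrd": ".nrrd"}[fmt]

    manifest = {"seed": int(seed), "format": fmt, "patients": []}
    for i, p in enumerate(cohort):
        entry = {"patient_id": p.patient_id, "arm": p.arm.value, "scans": []}
        for week in weeks:
            state = p.fluid_at_week(week)
            scan_seed = int(np.random.SeedSequence([seed, i, week]).generate_state(1)[0] % (2**31))
            vol, mask = render_scan(state, device, scan_seed,
                                    meta={"scan_id": f"{p.patient_id}_wk{week:03d}",
                                          "patient_id": p.patient_id, "week": week})
            if quantize and fmt == "tiff":
                q = np.round(vol.intensities * 255).astype(np.uint8)
                vol = OCTVolume(q.astype(np.float32) / 255.0, vol.spacings, vol.meta)
                vol_path = scans_dir / f"{p.patient_id}_wk{week:03d}{ext}"
                tifffile.imwrite(vol_path, q, photometric="minisblack")
                _sidecar_path(vol_path).write_text(json.dumps(
                    {"spacings_um": [float(s) for s in vol.spacings],
                     "meta": _jsonable(vol.meta)}, sort_keys=True))
            else:
                vol_path = write_volume(vol, scans_dir / f"{p.patient_id}_wk{week:03d}{ext}")
            mask_path = write_mask(mask, scans_dir / f"{p.patient_id}_wk{week:03d}_mask{ext}")
            entry["scans"].append({
                "week": week,
                "scan": str(vol_path.relative_to(out)),
                "mask": str(mask_path.relative_to(out)),
                "render_seed": scan_seed,
            })
        manifest["patients"].append(entry)

    visits_to_frame(cohort).to_csv(out / "visits.csv", index=False)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest_path


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
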