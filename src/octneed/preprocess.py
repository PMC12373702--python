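"""B-scan preprocessing chain producing fixed-size model inputs.

A raw SD-OCT volume (any device geometry) is turned into the
28 x 52 x 72 input grid consumed by the volumetric network:

1. geometric normalization — resample to a reference axial/lateral pitch
   and crop/pad the en-face field of view to 3.36 mm;
2. selection of the 28 B-scans around the central B-scan;
3. region-of-interest detection from the segmented layer surfaces
   (ILM above, Bruch's membrane below, plus a margin);
4. per-B-scan CLAHE contrast enhancement;
5. slice alignment — flattening Bruch's membrane to a reference row;
6. resize of each B-scan to 128 x 128 and a fixed 52 x 72 crop.

Every geometric operation optionally co-transforms the layer surfaces
and a ground-truth fluid mask (nearest-neighbour for labels), so that
synthetic ground truth stays registered with the preprocessed volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

__all__ = [
    "OCTVolume",
    "LayerSet",
    "ModelInput",
    "PreprocessConfig",
    "normalize_geometry",
    "select_central_bscans",
    "detect_roi",
    "crop_to_roi",
    "apply_clahe",
    "align_slices",
    "build_model_input",
    "preprocess_volume",
]

LAYER_ORDER = ("ilm", "ipl", "opl", "rpe", "bm")

# Final model-input geometry: each B-scan is resized to RESIZE_PX**2, the
# flattened Bruch's membrane sits at BM_REFERENCE_ROW, and the crop keeps
# CROP_ROWS rows (48 above the membrane, 4 below) and CROP_COLS centred
# columns (the central ~1.9 mm).
RESIZE_PX = 128
BM_REFERENCE_ROW = 90
CROP_ROWS = (BM_REFERENCE_ROW - 48, BM_REFERENCE_ROW + 4)   # (42, 94) -> 52 rows
CROP_COLS = ((RESIZE_PX - 72) // 2, (RESIZE_PX + 72) // 2)  # (28, 100) -> 72 cols
MODEL_INPUT_SHAPE = (28, CROP_ROWS[1] - CROP_ROWS[0], CROP_COLS[1] - CROP_COLS[0])


@dataclass
class OCTVolume:
    """One SD-OCT examination: B-scans x rows x columns in [0, 1].

    ``spacings`` is (bscan_spacing_um, axial_um_per_px, lateral_um_per_px).
    """

    intensities: np.ndarray
    spacings: Tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D (bscans, rows, cols) array")
        if len(self.spacings) != 3 or min(self.spacings) <= 0:
            raise ValueError("spacings must be three positive values")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        lo = float(self.intensities.min(initial=0.0))
        hi = float(self.intensities.max(initial=0.0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[0]


@dataclass
class LayerSet:
    """Per-B-scan boundary curves: row index as a function of column.

    ``surfaces`` maps layer names (ilm, ipl, opl, rpe, bm, optionally pr
    for the photoreceptor band) to float arrays of shape
    (n_bscans, n_cols).  NaN marks columns where a boundary was not traced.
    """

    surfaces: Dict[str, np.ndarray]

    def __post_init__(self):
        for name in LAYER_ORDER:
            if name not in self.surfaces:
                raise ValueError(f"missing layer surface: {name}")
        shapes = {np.asarray(s).shape for s in self.surfaces.values()}
        if len(shapes) != 1:
            raise ValueError("all layer surfaces must share one shape")
        self.surfaces = {k: np.asarray(v, dtype=np.float64) for k, v in self.surfaces.items()}
        self.validate_ordering()

    def validate_ordering(self, tol: float = 1e-6) -> None:
        """Boundaries must be monotonically ordered in depth at every column."""
        prev = None
        for name in LAYER_ORDER:
            cur = self.surfaces[name]
            if prev is not None:
                bad = (cur - prev) < -tol
                if np.any(bad & np.isfinite(cur) & np.isfinite(prev)):
                    raise ValueError(f"layer ordering violated at {name}")
            prev = cur

    def __getitem__(self, name: str) -> np.ndarray:
        return self.surfaces[name]

    def __contains__(self, name: str) -> bool:
        return name in self.surfaces

    @property
    def shape(self):
        return self.surfaces["ilm"].shape

    def map(self, fn) -> "LayerSet":
        return LayerSet({k: fn(v) for k, v in self.surfaces.items()})


@dataclass
class ModelInput:
    """Fixed-size network input volume with provenance of its geometry."""

    volume: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=np.float32)
        if self.volume.shape != MODEL_INPUT_SHAPE:
            raise ValueError(f"model input must have shape {MODEL_INPUT_SHAPE}")


@dataclass(frozen=True)
class PreprocessConfig:
    reference_axial_um: float = 7.0
    reference_lateral_um: float = 26.25   # 3.36 mm over 128 px
    fov_mm: float = 3.36
    n_bscans: int = 28
    roi_margin_um: float = 220.0
    clahe_clip_limit: float = 0.01
    clahe_tile_grid: Tuple[int, int] = (8, 8)
    apply_clahe: bool = True


def _zoom_cols(curve: np.ndarray, new_cols: int) -> np.ndarray:
    """Resample a (n_bscans, cols) curve stack to a new column count."""
    old_cols = curve.shape[1]
    if old_cols == new_cols:
        return curve.copy()
    x_new = np.linspace(0, old_cols - 1, new_cols)
    out = np.empty((curve.shape[0], new_cols))
    x_old = np.arange(old_cols)
    for k in range(curve.shape[0]):
        out[k] = np.interp(x_new, x_old, curve[k])
    return out


def _resample_mask(mask: np.ndarray, zoom_factors) -> np.ndarray:
    """Mass-conserving label resampling.

    Each label is interpolated linearly and re-binarized by keeping the
    top-k interpolated voxels, with k chosen so the label's physical
    volume is conserved (count scales with the grid-density ratio).
    Plain nearest-neighbour or 0.5-thresholding loses one-voxel-thick
    structures such as the rim of a flat subretinal dome.
    """
    out = None
    scale = float(np.prod(zoom_factors))
    for lab in np.unique(mask):
        if lab == 0:
            continue
        binary = (mask == lab).astype(np.float32)
        f = ndimage.zoom(binary, zoom_factors, order=1, mode="nearest")
        if out is None:
            out = np.zeros(f.shape, dtype=mask.dtype)
        target = int(round(binary.sum() * scale))
        pos = np.flatnonzero(f.ravel() > 0.05)
        if pos.size == 0 or target == 0:
            continue
        if pos.size > target:
            order = np.argsort(f.ravel()[pos], kind="stable")[::-1]
            pos = pos[order[:target]]
        out.ravel()[pos] = lab
    if out is None:
        out = np.zeros(ndimage.zoom(np.zeros_like(mask, dtype=np.float32),
                                    zoom_factors, order=0).shape, dtype=mask.dtype)
    return out


def _crop_pad_cols(arr: np.ndarray, width: int, pad_value=0.0):
    cols = arr.shape[-1]
    if cols == width:
        return arr, 0
    if cols > width:
        start = (cols - width) // 2
        return arr[..., start:start + width], -start
    pad = width - cols
    left = pad // 2
    widths = [(0, 0)] * (arr.ndim - 1) + [(left, pad - left)]
    return np.pad(arr, widths, constant_values=pad_value), left


def normalize_geometry(
    vol: OCTVolume,
    layers: Optional[LayerSet] = None,
    mask: Optional[np.ndarray] = None,
    config: PreprocessConfig = PreprocessConfig(),
):
    """Resample to the reference pitch and fix the lateral field of view.

    Linear interpolation for intensities, nearest-neighbour for the mask;
    layer curves are resampled laterally and rescaled axially.  Returns
    ``(volume, layers, mask)`` with omitted inputs passed through as None.
    """
    bsp, ax, lat = vol.spacings
    f_ax = ax / config.reference_axial_um
    f_lat = lat / config.reference_lateral_um
    identity = abs(f_ax - 1) < 1e-9 and abs(f_lat - 1) < 1e-9
    if identity:
        data = vol.intensities.copy()
    else:
        data = ndimage.zoom(vol.intensities, (1.0, f_ax, f_lat), order=1, mode="nearest")
    data = np.clip(data, 0.0, 1.0)
    zoomed_cols = data.shape[2]

    width = int(round(config.fov_mm * 1000.0 / config.reference_lateral_um))
    data, col_shift = _crop_pad_cols(data, width)

    new_layers = None
    if layers is not None:
        def tf(curve):
            c = _zoom_cols(curve, zoomed_cols) * f_ax
            c, _ = _crop_pad_cols(c, width, pad_value=np.nan)
            return c
        new_layers = layers.map(tf)

    new_mask = None
    if mask is not None:
        if identity:
            new_mask = mask.copy()
        else:
            new_mask = _resample_mask(mask, (1.0, f_ax, f_lat))
        new_mask, _ = _crop_pad_cols(new_mask, width, pad_value=0)

    out = OCTVolume(
        intensities=data,
        spacings=(bsp, config.reference_axial_um, config.reference_lateral_um),
        meta={**vol.meta, "normalized": True, "col_shift": col_shift},
    )
    return out, new_layers, new_mask


def select_central_bscans(
    vol: OCTVolume,
    n: int = 28,
    layers: Optional[LayerSet] = None,
    mask: Optional[np.ndarray] = None,
):
    """The ``n`` B-scans centred on index floor(count / 2).

    With ambiguity from parity the window starts at ``center - n // 2``
    (ties broken toward the lower index).
    """
    count = vol.n_bscans
    if count < n:
        raise ValueError(f"volume has {count} B-scans; {n} required")
    center = count // 2
    start = center - n // 2
    start = max(0, min(start, count - n))
    sl = slice(start, start + n)
    out = OCTVolume(vol.intensities[sl], vol.spacings,
                    {**vol.meta, "bscan_window": (start, start + n)})
    return (
        out,
        layers.map(lambda c: c[sl]) if layers is not None else None,
        mask[sl] if mask is not None else None,
    )


def detect_roi(vol: OCTVolume, layers: LayerSet, margin_um: float = 300.0) -> np.ndarray:
    """Per-B-scan crop boxes (row0, row1, col0, col1), identical across scans.

    The row span runs from the extreme ILM row minus the margin to the
    extreme Bruch's-membrane row plus the margin, over all B-scans and
    columns, clamped to the image; the column span is the full width.
    """
    _, ax, _ = vol.spacings
    ilm, bm = layers["ilm"], layers["bm"]
    if not (np.any(np.isfinite(ilm)) and np.any(np.isfinite(bm))):
        raise ValueError("degenerate layers: no finite ILM/BM samples")
    m = margin_um / ax
    row0 = max(int(np.floor(np.nanmin(ilm) - m)), 0)
    row1 = min(int(np.ceil(np.nanmax(bm) + m)) + 1, vol.shape[1])
    if row1 <= row0:
        raise ValueError("degenerate layers: empty ROI")
    return np.tile([row0, row1, 0, vol.shape[2]], (vol.n_bscans, 1))


def _round_roi_rows(boxes: np.ndarray, target: int, n_rows: int) -> np.ndarray:
    """Grow/shrink the ROI row span symmetrically to ``target`` rows.

    When the image is tall enough this makes the subsequent per-B-scan
    resize an identity in rows, which keeps thin fluid masks lossless.
    """
    boxes = boxes.copy()
    row0, row1 = int(boxes[0, 0]), int(boxes[0, 1])
    span = row1 - row0
    diff = target - span
    if diff != 0 and n_rows >= target:
        row0 = row0 - diff // 2
        row1 = row0 + target
        if row0 < 0:
            row0, row1 = 0, target
        elif row1 > n_rows:
            row0, row1 = n_rows - target, n_rows
    boxes[:, 0], boxes[:, 1] = row0, row1
    return boxes


def crop_to_roi(
    vol: OCTVolume,
    boxes: np.ndarray,
    layers: Optional[LayerSet] = None,
    mask: Optional[np.ndarray] = None,
):
    """Apply a shared ROI box to the volume (and layers/mask)."""
    row0, row1, col0, col1 = (int(v) for v in boxes[0])
    out = OCTVolume(vol.intensities[:, row0:row1, col0:col1], vol.spacings,
                    {**vol.meta, "roi_box": (row0, row1, col0, col1)})
    new_layers = layers.map(lambda c: c[:, col0:col1] - row0) if layers is not None else None
    new_mask = mask[:, row0:row1, col0:col1] if mask is not None else None
    return out, new_layers, new_mask


def apply_clahe(image: np.ndarray, clip_limit: float = 0.01,
                tile_grid: Tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one B-scan."""
    if clip_limit <= 0:
        raise ValueError("clip limit must be positive")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("apply_clahe expects a single 2-D B-scan")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("image must lie in [0, 1]")
    if np.ptp(img) == 0:
        return np.asarray(image).copy()
    kernel = (max(1, img.shape[0] // tile_grid[0]), max(1, img.shape[1] // tile_grid[1]))
    out = exposure.equalize_adapthist(np.clip(img, 0, 1), kernel_size=kernel,
                                      clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _interp_bm_row(bm_row: np.ndarray) -> np.ndarray:
    """Fill NaN columns of one B-scan's BM curve by lateral interpolation."""
    finite = np.isfinite(bm_row)
    if not finite.any():
        raise ValueError("Bruch's membrane missing for an entire B-scan")
    if finite.all():
        return bm_row
    x = np.arange(bm_row.size)
    return np.interp(x, x[finite], bm_row[finite])


def align_slices(
    vol: OCTVolume,
    layers: LayerSet,
    reference_row: int,
    mask: Optional[np.ndarray] = None,
):
    """Flatten Bruch's membrane: shift every A-scan so BM sits at reference_row.

    Shifts are integer (rounded) per column; rows shifted in from outside
    the image are zero-filled.  Layer curves are shifted accordingly.
    """
    n, rows, cols = vol.shape
    data = np.zeros_like(vol.intensities)
    new_mask = np.zeros_like(mask) if mask is not None else None
    shifts = np.zeros((n, cols))
    for k in range(n):
        bm_row = _interp_bm_row(layers["bm"][k])
        shift = np.round(reference_row - bm_row).astype(int)
        shifts[k] = shift
        for j in range(cols):
            s = shift[j]
            src0, src1 = max(0, -s), min(rows, rows - s)
            if src1 <= src0:
                continue
            data[k, src0 + s:src1 + s, j] = vol.intensities[k, src0:src1, j]
            if mask is not None:
                new_mask[k, src0 + s:src1 + s, j] = mask[k, src0:src1, j]
    new_layers = LayerSet({name: layers[name] + shifts for name in layers.surfaces})
    out = OCTVolume(data, vol.spacings, {**vol.meta, "aligned_to_row": reference_row})
    return out, new_layers, new_mask


def build_model_input(
    vol: OCTVolume,
    mask: Optional[np.ndarray] = None,
):
    """Resize each of the 28 B-scans to 128 x 128, then crop to 52 x 72.

    The crop keeps rows ``CROP_ROWS`` (placed around the flattened
    membrane row) and the centred ``CROP_COLS`` columns.  Returns
    ``(ModelInput, cropped_mask_or_None)``.
    """
    if vol.n_bscans != MODEL_INPUT_SHAPE[0]:
        raise ValueError(f"expected {MODEL_INPUT_SHAPE[0]} B-scans, got {vol.n_bscans}")
    r0, r1 = CROP_ROWS
    c0, c1 = CROP_COLS
    out = np.empty(MODEL_INPUT_SHAPE, dtype=np.float32)
    out_mask = np.zeros(MODEL_INPUT_SHAPE, dtype=np.uint8) if mask is not None else None
    for k in range(vol.n_bscans):
        big = transform.resize(vol.intensities[k], (RESIZE_PX, RESIZE_PX), order=1,
                               mode="edge", anti_aliasing=False, preserve_range=True)
        out[k] = np.clip(big[r0:r1, c0:c1], 0.0, 1.0)
        if mask is not None:
            if mask[k].shape == (RESIZE_PX, RESIZE_PX):
                out_mask[k] = mask[k][r0:r1, c0:c1]
            else:
                zf = (RESIZE_PX / mask[k].shape[0], RESIZE_PX / mask[k].shape[1])
                out_mask[k] = _resample_mask(mask[k], zf)[r0:r1, c0:c1]
    prov = {
        "resize_px": RESIZE_PX,
        "crop_rows": CROP_ROWS,
        "crop_cols": CROP_COLS,
        "pre_resize_shape": vol.shape[1:],
    }
    return ModelInput(volume=out, provenance=prov), out_mask


def preprocess_volume(
    vol: OCTVolume,
    layers: LayerSet,
    mask: Optional[np.ndarray] = None,
    config: PreprocessConfig = PreprocessConfig(),
) -> ModelInput:
    """Full preprocessing chain from raw volume to model input.

    Geometric normalization, central-B-scan selection, ROI crop, CLAHE,
    membrane flattening, resize and crop, with the ground-truth mask
    (when given) co-transformed and attached to the provenance under
    ``"mask"``.
    """
    v, l, m = normalize_geometry(vol, layers, mask, config)
    v, l, m = select_central_bscans(v, config.n_bscans, l, m)
    boxes = detect_roi(v, l, config.roi_margin_um)
    boxes = _round_roi_rows(boxes, RESIZE_PX, v.shape[1])
    v, l, m = crop_to_roi(v, boxes, l, m)
    if config.apply_clahe:
        data = np.stack([
            apply_clahe(v.intensities[k], config.clahe_clip_limit, config.clahe_tile_grid)
            for k in range(v.n_bscans)
        ])
        v = OCTVolume(data, v.spacings, v.meta)
    # place BM so that it lands on BM_REFERENCE_ROW after the 128-px resize
    ref = int(round(BM_REFERENCE_ROW / RESIZE_PX * v.shape[1]))
    v, l, m = align_slices(v, l, ref, m)
    mi, mi_mask = build_model_input(v, m)
    mi.provenance.update({
        "scan_id": vol.meta.get("scan_id"),
        "spacings_um": tuple(float(s) for s in vol.spacings),
    })
    if mi_mask is not None:
        mi.provenance["mask"] = mi_mask
    return mi
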