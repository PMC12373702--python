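"""Fluid biomarker quantification, threshold calibration, grader agreement.

IRF/SRF segmentation masks are reduced to the quantities the T&E
protocol's anatomic criteria use: fluid volume in nanolitres, the
maximum subretinal fluid height in micrometres (longest contiguous SRF
run along an A-scan), and presence flags.  Presence thresholds (6.0 nL
for IRF, 16 nL for SRF by default) are calibrated against reference
grades at the equal error rate, the threshold where false-positive and
false-negative rates coincide.  ``agreement_analysis`` compares two
graders' presence flags as a confusion matrix with sensitivity,
specificity and balanced accuracy; the module ships the published
ARIES grader-agreement counts (study site and automated segmentation,
each against the central reading center) for that analysis.

A rule-based stand-in segmenter is included for synthetic volumes: it
thresholds hypo-reflective voxels between the anatomically admissible
boundary surfaces.  Its contract is geometric overlap with the
renderer's ground truth, not clinical fidelity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .preprocess import LayerSet, OCTVolume

__all__ = [
    "IRF_LABEL",
    "SRF_LABEL",
    "DEFAULT_THRESHOLDS_NL",
    "SegmentationMask",
    "FluidMetrics",
    "ConfusionMatrix",
    "AgreementResult",
    "SegmentationParams",
    "segment_fluid_standin",
    "fluid_volume_nl",
    "srf_max_height_um",
    "calibrate_eer_threshold",
    "presence_flags",
    "agreement_analysis",
    "dice_coefficient",
    "ARIES_GRADER_AGREEMENT",
]

IRF_LABEL = 1
SRF_LABEL = 2
_LABEL_BY_NAME = {"irf": IRF_LABEL, "srf": SRF_LABEL}

DEFAULT_THRESHOLDS_NL = {"irf": 6.0, "srf": 16.0}
SRF_HEIGHT_CUTOFF_UM = 50.0


@dataclass
class SegmentationMask:
    """Per-voxel fluid labels aligned with an :class:`OCTVolume`.

    Labels: 0 background, 1 IRF, 2 SRF.  ``layers`` optionally carries the
    boundary surfaces of the same scan (the synthetic renderer fills it).
    """

    labels: np.ndarray
    spacings: Tuple[float, float, float]
    layers: Optional[LayerSet] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D (bscans, rows, cols)")
        if not np.isin(np.unique(self.labels), (0, IRF_LABEL, SRF_LABEL)).all():
            raise ValueError("labels must be in {0, 1, 2}")
        if len(self.spacings) != 3 or min(self.spacings) <= 0:
            raise ValueError("spacings must be three positive values")
        self.labels = self.labels.astype(np.uint8)

    @property
    def voxel_volume_um3(self) -> float:
        b, a, l = self.spacings
        return b * a * l


@dataclass(frozen=True)
class FluidMetrics:
    """Scan-level fluid quantities and presence flags."""

    irf_volume_nl: float
    srf_volume_nl: float
    srf_max_height_um: float
    irf_present: bool = False
    srf_present: bool = False
    srf_ge_50um: bool = False

    def __post_init__(self):
        if self.irf_volume_nl < 0 or self.srf_volume_nl < 0 or self.srf_max_height_um < 0:
            raise ValueError("fluid quantities must be nonnegative")


def _resolve_label(label) -> int:
    if isinstance(label, str):
        try:
            return _LABEL_BY_NAME[label.lower()]
        except KeyError:
            raise ValueError(f"unknown fluid label {label!r}") from None
    if label in (IRF_LABEL, SRF_LABEL):
        return int(label)
    raise ValueError(f"unknown fluid label {label!r}")


def fluid_volume_nl(mask: SegmentationMask, label) -> float:
    """Fluid volume in nanolitres: voxel count x voxel volume / 1e6 um^3."""
    lab = _resolve_label(label)
    count = int(np.count_nonzero(mask.labels == lab))
    return count * mask.voxel_volume_um3 / 1e6


def srf_max_height_um(mask: SegmentationMask) -> float:
    """Tallest contiguous SRF run along any A-scan, in micrometres.

    Disjoint runs within one column are not summed — height means the
    vertical extent of a single connected fluid pocket along that A-scan.
    """
    _, axial, _ = mask.spacings
    srf = mask.labels == SRF_LABEL
    if not srf.any():
        return 0.0
    best = 0
    for k in range(srf.shape[0]):
        sl = srf[k]
        run = np.zeros(sl.shape[1], dtype=np.int64)
        mx = np.zeros(sl.shape[1], dtype=np.int64)
        for i in range(sl.shape[0]):
            run = np.where(sl[i], run + 1, 0)
            np.maximum(mx, run, out=mx)
        best = max(best, int(mx.max()))
    return best * axial


def calibrate_eer_threshold(values: Sequence[float], ref_labels: Sequence[bool]) -> float:
    """Presence threshold at the equal error rate against reference grades.

    Candidates are the midpoints between consecutive sorted unique values
    (a value >= threshold is called positive); the threshold minimizing
    |FPR - FNR| is returned, ties broken toward the lower threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(ref_labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and ref_labels must be equal-length 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to calibrate a threshold")
    uniq = np.unique(v)
    if uniq.size < 2:
        raise ValueError("values are constant; no threshold separates them")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_gap = None, np.inf
    for t in candidates:  # ascending, so strict improvement keeps the lowest tie
        pred = v >= t
        fpr = np.count_nonzero(pred & ~y) / n_neg
        fnr = np.count_nonzero(~pred & y) / n_pos
        gap = abs(fpr - fnr)
        if gap < best_gap - 1e-12:
            best_gap, best_t = gap, float(t)
    return best_t


def presence_flags(
    metrics: FluidMetrics,
    thresholds: Optional[Dict[str, float]] = None,
) -> FluidMetrics:
    """Set presence flags by inclusive (>=) comparison against thresholds."""
    thr = dict(DEFAULT_THRESHOLDS_NL)
    if thresholds:
        thr.update(thresholds)
    if thr["irf"] < 0 or thr["srf"] < 0:
        raise ValueError("thresholds must be nonnegative")
    return FluidMetrics(
        irf_volume_nl=metrics.irf_volume_nl,
        srf_volume_nl=metrics.srf_volume_nl,
        srf_max_height_um=metrics.srf_max_height_um,
        irf_present=metrics.irf_volume_nl >= thr["irf"],
        srf_present=metrics.srf_volume_nl >= thr["srf"],
        srf_ge_50um=metrics.srf_max_height_um >= SRF_HEIGHT_CUTOFF_UM,
    )


def compute_fluid_metrics(
    mask: SegmentationMask,
    thresholds: Optional[Dict[str, float]] = None,
) -> FluidMetrics:
    """Volumes, SRF height and presence flags for one segmented scan."""
    raw = FluidMetrics(
        irf_volume_nl=fluid_volume_nl(mask, IRF_LABEL),
        srf_volume_nl=fluid_volume_nl(mask, SRF_LABEL),
        srf_max_height_um=srf_max_height_um(mask),
    )
    return presence_flags(raw, thresholds)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 agreement counts with the reference rater as truth."""

    tn: int
    fn: int
    fp: int
    tp: int

    def __post_init__(self):
        if min(self.tn, self.fn, self.fp, self.tp) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tn + self.fn + self.fp + self.tp

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    def to_flags(self) -> Tuple[np.ndarray, np.ndarray]:
        """Expand counts back into (rater, reference) boolean flag arrays."""
        rater = np.concatenate([
            np.zeros(self.tn, bool), np.zeros(self.fn, bool),
            np.ones(self.fp, bool), np.ones(self.tp, bool),
        ])
        ref = np.concatenate([
            np.zeros(self.tn, bool), np.ones(self.fn, bool),
            np.zeros(self.fp, bool), np.ones(self.tp, bool),
        ])
        return rater, ref


@dataclass(frozen=True)
class AgreementResult:
    matrix: ConfusionMatrix
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    accuracy: float


def agreement_analysis(flags_a: Sequence[bool], flags_ref: Sequence[bool]) -> AgreementResult:
    """Agreement of one rater against a reference rater (taken as truth)."""
    a = np.asarray(flags_a, dtype=bool)
    r = np.asarray(flags_ref, dtype=bool)
    if a.shape != r.shape or a.ndim != 1:
        raise ValueError("flag sequences must be 1-D and equally long")
    if a.size == 0:
        raise ValueError("empty input")
    cm = ConfusionMatrix(
        tn=int(np.count_nonzero(~a & ~r)),
        fn=int(np.count_nonzero(~a & r)),
        fp=int(np.count_nonzero(a & ~r)),
        tp=int(np.count_nonzero(a & r)),
    )
    return AgreementResult(
        matrix=cm,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        balanced_accuracy=cm.balanced_accuracy,
        accuracy=cm.accuracy,
    )


# Published ARIES grader-agreement counts: study-site and automated (AI)
# biomarker grades, each compared against the central reading center
# (reference), as (tn, fn, fp, tp).  SRF presence was not graded at the
# study sites.
ARIES_GRADER_AGREEMENT: Dict[Tuple[str, str], ConfusionMatrix] = {
    ("study_site", "irf_presence"): ConfusionMatrix(tn=984, fn=30, fp=582, tp=208),
    ("study_site", "srf_height_ge_50um"): ConfusionMatrix(tn=1063, fn=143, fp=153, tp=414),
    ("ai", "irf_presence"): ConfusionMatrix(tn=1340, fn=35, fp=226, tp=221),
    ("ai", "srf_height_ge_50um"): ConfusionMatrix(tn=731, fn=9, fp=485, tp=548),
    ("ai", "srf_presence"): ConfusionMatrix(tn=812, fn=138, fp=144, tp=728),
}


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the rule-based stand-in segmenter."""

    relative_threshold: float = 0.45   # of the median intra-retinal intensity
    min_size: int = 20                 # voxels; smaller components are dropped
    smooth_sigma: float = 0.4          # in-plane Gaussian sigma (px); larger
                                       # values blur one-voxel fluid rims into
                                       # the bright bands and lose them
    boundary_margin_px: float = 0.0    # keep-out from the bounding surfaces


def _row_grid(shape) -> np.ndarray:
    return np.arange(shape[1], dtype=float)[None, :, None]


def segment_fluid_standin(
    vol: OCTVolume,
    layers: LayerSet,
    params: SegmentationParams = SegmentationParams(),
) -> SegmentationMask:
    """Rule-based IRF/SRF segmentation of a synthetic volume.

    Hypo-reflective voxels (below a fraction of the median intra-retinal
    intensity after light smoothing) are labelled IRF between the ILM and
    OPL surfaces and SRF between the photoreceptor band and the RPE;
    connected components below ``min_size`` voxels are discarded.
    """
    if layers is None:
        raise ValueError("layer surfaces are required")
    data = vol.intensities.astype(np.float32)
    if params.smooth_sigma > 0:
        data = ndimage.gaussian_filter(data, sigma=(0, params.smooth_sigma, params.smooth_sigma))

    rows = _row_grid(vol.shape)
    ilm = layers["ilm"][:, None, :]
    opl = layers["opl"][:, None, :]
    rpe = layers["rpe"][:, None, :]
    if "pr" in layers:
        pr = layers["pr"][:, None, :]
    else:
        # photoreceptor band not traced: assume it sits ~45 um above the RPE
        pr = rpe - 45.0 / vol.spacings[1]
    bm = layers["bm"][:, None, :]

    retina = (rows >= ilm) & (rows <= bm)
    if not retina.any():
        raise ValueError("degenerate layers: empty retina")
    med = float(np.median(data[np.broadcast_to(retina, data.shape)]))
    hypo = data < params.relative_threshold * med

    m = params.boundary_margin_px
    irf_zone = (rows > ilm + m) & (rows < opl - m)
    srf_zone = (rows > pr + m) & (rows < rpe - m)

    out = np.zeros(vol.shape, dtype=np.uint8)
    structure = np.ones((3, 3, 3), bool)
    for zone, lab in ((irf_zone, IRF_LABEL), (srf_zone, SRF_LABEL)):
        cand = hypo & np.broadcast_to(zone, data.shape)
        comp, n = ndimage.label(cand, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())
        keep = np.flatnonzero(sizes >= params.min_size)
        keep = keep[keep > 0]
        if keep.size:
            out[np.isin(comp, keep)] = lab
    return SegmentationMask(out, vol.spacings, layers=layers, meta=dict(vol.meta))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Voxelwise Dice overlap of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom
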