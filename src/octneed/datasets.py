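"""Assembly of analysis-ready datasets from simulated cohorts.

Bridges the simulator and the predictors: for every patient the Week-8
and Week-16 fluid states are rendered to volumes (or read off the
ground truth directly), quantified, and paired with the endpoint labels.
Two representations are produced:

* feature datasets — eight fluid features per patient for the logistic
  model, either from the ground-truth fluid states (``source="truth"``)
  or through the full render → segment → quantify pipeline
  (``source="scans"``);
* volume datasets — preprocessed 2 x 28 x 52 x 72 model-input pairs for
  the volumetric network.

The surrogate source task used for pretraining labels each patient by
fluid persistence at Week 16 (any IRF or SRF presence by the protocol
thresholds), a related but distinct signal from the target endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from . import biomarkers as bm
from .cohort import Arm, CohortConfig, DeviceProfile, FluidState, PatientRecord, simulate_cohort
from .labels import Interval, LabelSet, Need, label_patient
from .models import FEATURE_NAMES, featurize
from .preprocess import PreprocessConfig, preprocess_volume
from .render import render_scan

__all__ = [
    "EXPERIMENTS",
    "CohortDataset",
    "truth_metrics",
    "scan_metrics",
    "build_feature_dataset",
    "build_volume_dataset",
    "surrogate_source_labels",
]

# experiment id -> (LabelSet attribute, positive level, eligible arms)
EXPERIMENTS = {
    "1": ("first_interval", Interval.SHORT, (Arm.EARLY_START,)),
    "2y1": ("year1_need", Need.HIGH, (Arm.EARLY_START,)),
    "2y2": ("year2_need", Need.HIGH, (Arm.EARLY_START, Arm.LATE_START)),
    "3": ("final_interval", Interval.SHORT, (Arm.EARLY_START, Arm.LATE_START)),
}


@dataclass
class CohortDataset:
    """Per-patient predictors plus all endpoint labels."""

    patient_ids: np.ndarray
    arms: np.ndarray
    label_sets: list
    features: Optional[np.ndarray] = None     # (n, 8)
    volumes: Optional[np.ndarray] = None      # (n, 2, 28, 52, 72) float32
    feature_names: Tuple[str, ...] = FEATURE_NAMES
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patient_ids)

    def predictor_matrix(self, kind: str) -> np.ndarray:
        x = self.features if kind == "features" else self.volumes
        if x is None:
            raise ValueError(f"dataset carries no {kind}")
        return x

    def experiment_labels(self, experiment_id: str):
        """(defined_mask, binary_labels) for one experiment id."""
        try:
            attr, positive, arms = EXPERIMENTS[experiment_id]
        except KeyError:
            raise ValueError(f"unknown experiment id {experiment_id!r}") from None
        arm_names = {a.value for a in arms}
        defined = np.zeros(len(self), dtype=bool)
        y = np.zeros(len(self), dtype=int)
        for i, ls in enumerate(self.label_sets):
            val = getattr(ls, attr)
            if val is not None and self.arms[i] in arm_names:
                defined[i] = True
                y[i] = int(val == positive)
        return defined, y


def truth_metrics(state: FluidState) -> bm.FluidMetrics:
    """Ground-truth fluid metrics (volumes, height, protocol flags)."""
    raw = bm.FluidMetrics(
        irf_volume_nl=state.irf_volume_nl,
        srf_volume_nl=state.srf_volume_nl,
        srf_max_height_um=state.srf_height_um,
    )
    return bm.presence_flags(raw)


def _scan_seed(seed: int, patient_index: int, week: int) -> int:
    return int(np.random.SeedSequence([seed, patient_index, week]).generate_state(1)[0] % (2**31))


def scan_metrics(
    patient: PatientRecord,
    patient_index: int,
    device: DeviceProfile,
    seed: int,
    params: Optional[bm.SegmentationParams] = None,
    week: int = 8,
) -> bm.FluidMetrics:
    """Metrics measured through the render -> segment -> quantify pipeline."""
    state = patient.fluid_at_week(week)
    vol, mask = render_scan(state, device, _scan_seed(seed, patient_index, week))
    seg = bm.segment_fluid_standin(vol, mask.layers, params or bm.SegmentationParams())
    return bm.compute_fluid_metrics(seg)


def build_feature_dataset(
    cohort: Sequence[PatientRecord],
    source: str = "truth",
    device: Optional[DeviceProfile] = None,
    seed: int = 0,
    segmentation_params: Optional[bm.SegmentationParams] = None,
) -> CohortDataset:
    """Fluid-feature dataset for the logistic model.

    ``source="truth"`` reads the simulator's fluid states directly;
    ``source="scans"`` renders and re-measures them with the stand-in
    segmenter (slower, includes measurement error).
    """
    if source not in ("truth", "scans"):
        raise ValueError("source must be 'truth' or 'scans'")
    device = device or DeviceProfile()
    feats, ids, arms, lsets = [], [], [], []
    for i, p in enumerate(cohort):
        if source == "truth":
            m8 = truth_metrics(p.fluid_at_week(8))
            m16 = truth_metrics(p.fluid_at_week(16))
        else:
            m8 = scan_metrics(p, i, device, seed, segmentation_params, week=8)
            m16 = scan_metrics(p, i, device, seed, segmentation_params, week=16)
        feats.append(featurize(m8, m16).as_array())
        ids.append(p.patient_id)
        arms.append(p.arm.value)
        lsets.append(label_patient(p))
    return CohortDataset(
        patient_ids=np.array(ids),
        arms=np.array(arms),
        label_sets=lsets,
        features=np.stack(feats) if feats else np.zeros((0, len(FEATURE_NAMES))),
        meta={"source": source, "seed": seed},
    )


def build_volume_dataset(
    cohort: Sequence[PatientRecord],
    device: Optional[DeviceProfile] = None,
    seed: int = 0,
    preprocess_config: Optional[PreprocessConfig] = None,
) -> CohortDataset:
    """Preprocessed Week-8/Week-16 model-input pairs for the network."""
    device = device or DeviceProfile()
    cfg = preprocess_config or PreprocessConfig()
    vols, ids, arms, lsets = [], [], [], []
    for i, p in enumerate(cohort):
        pair = []
        for week in (8, 16):
            state = p.fluid_at_week(week)
            vol, mask = render_scan(state, device, _scan_seed(seed, i, week))
            mi = preprocess_volume(vol, mask.layers, config=cfg)
            pair.append(mi.volume)
        vols.append(np.stack(pair))
        ids.append(p.patient_id)
        arms.append(p.arm.value)
        lsets.append(label_patient(p))
    return CohortDataset(
        patient_ids=np.array(ids),
        arms=np.array(arms),
        label_sets=lsets,
        volumes=np.stack(vols).astype(np.float32) if vols else None,
        meta={"seed": seed, "device": device},
    )


def surrogate_source_labels(cohort: Sequence[PatientRecord]) -> np.ndarray:
    """Source-task labels: fluid persistence (IRF or SRF presence) at Week 16."""
    y = []
    for p in cohort:
        m = truth_metrics(p.fluid_at_week(16))
        y.append(int(m.irf_present or m.srf_present))
    return np.array(y, dtype=int)
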