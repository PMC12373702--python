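"""Synthetic treat-and-extend (T&E) cohort simulation.

Generates per-patient anti-VEGF injection trajectories over a two-year
horizon together with the intraretinal-fluid (IRF) and subretinal-fluid
(SRF) state at every visit.  The simulator emulates a proactive T&E
protocol for neovascular AMD: three monthly loading injections at weeks
0, 4 and 8, then an injection at every visit with the inter-visit
interval extended, maintained or shortened by a fixed step according to
anatomic SD-OCT dryness criteria, clamped to protocol caps.

The disease model is deliberately minimal.  Each patient carries one
positive latent activity level (nL scale).  Fluid rebounds after every
injection following a saturating-exponential curve and is observed with
multiplicative lognormal noise, so the fluid seen at a visit is

    amplitude x (1 - exp(-decay_rate * weeks_since_injection)) x noise.

Noise multipliers are pre-drawn per calendar week at patient creation,
which makes the fluid trajectory a deterministic, monotone function of
latent activity even when treatment schedules diverge.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Decision",
    "Arm",
    "FluidState",
    "VisitRecord",
    "PatientRecord",
    "CohortConfig",
    "DeviceProfile",
    "srf_height_from_volume",
    "srf_volume_from_height",
    "protocol_decision",
    "simulate_trajectory",
    "simulate_patient",
    "simulate_cohort",
]

# Dryness criteria used by the simulated protocol (anatomic SD-OCT rules):
# IRF is called present at >= 6.0 nL, SRF at >= 16 nL, and SRF height
# >= 50 um blocks extension regardless of IRF.
IRF_PRESENCE_NL = 6.0
SRF_PRESENCE_NL = 16.0
SRF_HEIGHT_CUTOFF_UM = 50.0

# Aspect ratio of the subretinal dome: lateral semi-axis = k * height.
# k = 10 gives a flat dome where 16 nL of SRF stands ~42 um tall and the
# 50 um height cutoff corresponds to ~26 nL.
SRF_DOME_ASPECT = 10.0


class Decision(str, enum.Enum):
    EXTEND = "extend"
    MAINTAIN = "maintain"
    SHORTEN = "shorten"


class Arm(str, enum.Enum):
    EARLY_START = "early_start"
    LATE_START = "late_start"


def srf_height_from_volume(volume_nl: float, aspect: float = SRF_DOME_ASPECT) -> float:
    """Height (um) of a half-ellipsoid dome of the given volume.

    The dome has lateral semi-axes a = b = aspect * h, so
    V = (2/3) * pi * a * b * h = (2/3) * pi * aspect**2 * h**3.
    """
    if volume_nl <= 0:
        return 0.0
    v_um3 = float(volume_nl) * 1e6
    return (3.0 * v_um3 / (2.0 * np.pi * aspect**2)) ** (1.0 / 3.0)


def srf_volume_from_height(height_um: float, aspect: float = SRF_DOME_ASPECT) -> float:
    """Inverse of :func:`srf_height_from_volume`, in nL."""
    if height_um <= 0:
        return 0.0
    return (2.0 / 3.0) * np.pi * aspect**2 * float(height_um) ** 3 / 1e6


@dataclass(frozen=True)
class FluidState:
    """Ground-truth fluid content of one eye at one visit."""

    irf_volume_nl: float
    srf_volume_nl: float
    srf_height_um: float
    pocket_spec: Optional[tuple] = None  # filled by the renderer

    def __post_init__(self):
        if not (np.isfinite(self.irf_volume_nl) and np.isfinite(self.srf_volume_nl)):
            raise ValueError("fluid volumes must be finite")
        if self.irf_volume_nl < 0 or self.srf_volume_nl < 0:
            raise ValueError("fluid volumes must be nonnegative")
        if (self.srf_height_um == 0) != (self.srf_volume_nl == 0):
            raise ValueError("srf_height_um must be zero iff srf_volume_nl is zero")

    @classmethod
    def from_volumes(cls, irf_volume_nl: float, srf_volume_nl: float) -> "FluidState":
        return cls(
            irf_volume_nl=float(irf_volume_nl),
            srf_volume_nl=float(srf_volume_nl),
            srf_height_um=srf_height_from_volume(srf_volume_nl),
        )


@dataclass(frozen=True)
class VisitRecord:
    week: int
    injection_given: bool
    fluid_state: FluidState
    assigned_interval_weeks: Optional[int] = None
    decision: Optional[Decision] = None


@dataclass
class PatientRecord:
    patient_id: str
    arm: Arm
    visits: list  # of VisitRecord, sorted by week
    latent_activity: float
    irf_fraction: float = 0.5

    @property
    def injection_weeks(self) -> list:
        return [v.week for v in self.visits if v.injection_given]

    def fluid_at_week(self, week: int) -> FluidState:
        for v in self.visits:
            if v.week == week:
                return v.fluid_state
        raise KeyError(f"no visit at week {week} for {self.patient_id}")

    def decisions_from_visit4(self, n: int = 4) -> list:
        """Decisions at the first ``n`` interval-adjustment visits (Visit 4 on)."""
        ds = [v.decision for v in self.visits if v.decision is not None]
        return ds[:n]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the simulated T&E cohort.

    ``activity_mu``/``activity_sigma`` parameterise the per-patient latent
    activity lognormal (nL scale); ``decay_rate`` is the post-injection
    fluid rebound rate per week; ``noise_sd`` the lognormal sigma of the
    visit-level measurement noise.
    """

    n_patients: int
    step_weeks: int = 2
    min_interval_weeks: int = 8
    max_interval_weeks: int = 16
    activity_mu: float = 2.5
    activity_sigma: float = 1.1
    decay_rate: float = 0.15
    noise_sd: float = 0.35
    srf_gain: float = 2.5
    horizon_weeks: int = 104
    late_start_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.step_weeks <= 0:
            raise ValueError("step_weeks must be positive")
        if self.min_interval_weeks > self.max_interval_weeks:
            raise ValueError("min_interval_weeks must not exceed max_interval_weeks")
        if self.horizon_weeks < 52:
            raise ValueError("horizon_weeks must cover at least one year")


@dataclass(frozen=True)
class DeviceProfile:
    """Acquisition geometry and noise character of one SD-OCT device."""

    axial_um_per_px: float = 7.0
    lateral_um_per_px: float = 23.3333333333
    bscan_spacing_um: float = 120.0
    n_bscans: int = 31
    height_px: int = 192
    width_px: int = 144
    intensity_gamma: float = 1.0
    speckle_sd: float = 0.22

    def __post_init__(self):
        if min(self.axial_um_per_px, self.lateral_um_per_px, self.bscan_spacing_um) <= 0:
            raise ValueError("all spacings must be positive")
        if self.n_bscans < 28:
            raise ValueError("need at least 28 B-scans")
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        return self.axial_um_per_px * self.lateral_um_per_px * self.bscan_spacing_um


def protocol_decision(state: FluidState) -> Decision:
    """Interval decision from the anatomic dryness criteria.

    Shorten when IRF is present (>= 6 nL) or the SRF dome stands >= 50 um;
    maintain when SRF is present (>= 16 nL) but below 50 um; extend when dry.
    """
    if state.irf_volume_nl >= IRF_PRESENCE_NL or state.srf_height_um >= SRF_HEIGHT_CUTOFF_UM:
        return Decision.SHORTEN
    if state.srf_volume_nl >= SRF_PRESENCE_NL:
        return Decision.MAINTAIN
    return Decision.EXTEND


def _rebound(weeks_since_injection: float, decay_rate: float) -> float:
    if weeks_since_injection is None:
        return 1.0
    return 1.0 - np.exp(-decay_rate * max(weeks_since_injection, 0.0))


def simulate_trajectory(
    patient_id: str,
    arm: Arm,
    config: CohortConfig,
    activity: float,
    irf_frac: float,
    noise: np.ndarray,
) -> PatientRecord:
    """Deterministic visit trajectory given latent state and noise multipliers.

    ``noise`` holds one (IRF, SRF) multiplier pair per calendar week and must
    cover ``horizon_weeks + max_interval_weeks`` weeks.
    """
    if activity < 0:
        raise ValueError("latent activity must be nonnegative")
    n_weeks = config.horizon_weeks + config.max_interval_weeks + 1
    if noise.shape[0] < n_weeks or noise.shape[1] != 2:
        raise ValueError("noise array must have shape (>= horizon + max interval + 1, 2)")

    def fluid_at(week: int, last_injection: Optional[int]) -> FluidState:
        dt = None if last_injection is None else week - last_injection
        reb = _rebound(dt, config.decay_rate)
        irf = activity * irf_frac * reb * noise[week, 0]
        srf = activity * (1.0 - irf_frac) * config.srf_gain * reb * noise[week, 1]
        return FluidState.from_volumes(irf, srf)

    visits = []
    # Loading phase: injections at weeks 0, 4, 8; no interval decisions yet.
    last_inj = None
    for week in (0, 4):
        visits.append(VisitRecord(week=week, injection_given=True, fluid_state=fluid_at(week, last_inj)))
        last_inj = week
    interval = config.min_interval_weeks
    visits.append(
        VisitRecord(week=8, injection_given=True, fluid_state=fluid_at(8, last_inj),
                    assigned_interval_weeks=interval)
    )
    last_inj = 8

    week = 8 + interval
    while week <= config.horizon_weeks:
        state = fluid_at(week, last_inj)
        decision = protocol_decision(state)
        if decision is Decision.EXTEND:
            interval = min(interval + config.step_weeks, config.max_interval_weeks)
        elif decision is Decision.SHORTEN:
            interval = max(interval - config.step_weeks, config.min_interval_weeks)
        visits.append(
            VisitRecord(week=week, injection_given=True, fluid_state=state,
                        assigned_interval_weeks=interval, decision=decision)
        )
        last_inj = week
        week += interval

    return PatientRecord(
        patient_id=patient_id,
        arm=arm,
        visits=visits,
        latent_activity=activity,
        irf_fraction=irf_frac,
    )


def simulate_patient(
    patient_id: str,
    arm: Arm,
    config: CohortConfig,
    rng: np.random.Generator,
) -> PatientRecord:
    """Draw one patient's latent state and simulate their trajectory."""
    activity = float(np.exp(rng.normal(config.activity_mu, config.activity_sigma)))
    irf_frac = float(rng.beta(2.0, 2.0))
    # Per-week multiplicative noise, pre-drawn so that the trajectory is a
    # deterministic monotone function of `activity`.
    n_weeks = config.horizon_weeks + config.max_interval_weeks + 1
    noise = np.exp(rng.normal(0.0, config.noise_sd, size=(n_weeks, 2)))
    return simulate_trajectory(patient_id, arm, config, activity, irf_frac, noise)


def simulate_cohort(config: CohortConfig) -> list:
    """Simulate the full cohort; deterministic for a fixed config seed.

    All randomness flows from ``config.seed`` through one spawned child
    stream per patient, so any subset of patients reproduces exactly.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients)
    patients = []
    n_late = int(round(config.n_patients * config.late_start_fraction))
    for i, child in enumerate(children):
        arm = Arm.LATE_START if i < n_late else Arm.EARLY_START
        rng = np.random.default_rng(child)
        patients.append(simulate_patient(f"P{i:04d}", arm, config, rng))
    return patients
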