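"""Synthetic SD-OCT volume renderer with exact fluid ground truth.

Stands in for real image acquisition: given a ground-truth
:class:`~octneed.cohort.FluidState` and a :class:`~octneed.cohort.DeviceProfile`,
it produces a speckled B-scan stack with smooth bright layer bands
(ILM, IPL, OPL, photoreceptor band, RPE/Bruch's complex) drawn as
low-order polynomial surfaces, hypo-reflective IRF ellipsoids strictly
between the ILM and OPL, and a hypo-reflective SRF dome lifting the
neurosensory retina off the RPE.  The returned segmentation mask is the
exact rendered voxel set: pocket extents are adjusted so that the mask
volume matches the requested nanolitre volume to within half a voxel.

Voxel centres sit at ``index x spacing`` along each axis
(bscan, axial, lateral), which is also the convention of
:func:`rasterize_ellipsoid`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .biomarkers import IRF_LABEL, SRF_LABEL, SegmentationMask
from .cohort import SRF_DOME_ASPECT, DeviceProfile, FluidState
from .preprocess import LayerSet, OCTVolume

__all__ = [
    "RenderError",
    "PocketSpec",
    "rasterize_ellipsoid",
    "plan_pockets",
    "render_scan",
]


class RenderError(ValueError):
    """A fluid pocket cannot be placed inside its retinal compartment."""


# Layer stack depths (um below the ILM base surface).
ILM_BASE_UM = 420.0
THICKNESS_UM = {"ipl": 100.0, "opl": 160.0, "pr": 250.0, "rpe": 275.0, "bm": 290.0}

# Reflectivity of each tissue class before speckle.
_I_VITREOUS = 0.05
_I_RETINA = 0.32
_I_CHOROID = 0.18
_I_ILM_LINE = 0.80
_I_PLEXIFORM = 0.55
_I_PR_BAND = 0.85
_I_RPE_BAND = 0.92
_I_FLUID = 0.06

_BAND_HALF_UM = 8.0     # half-thickness of the plexiform bands
_ILM_LINE_UM = 8.0
_PR_BAND_UM = 12.0
_COMPARTMENT_MARGIN_UM = 4.0
_INFLATE = 1.35         # candidate-pool inflation for exact-count filling


@dataclass(frozen=True)
class PocketSpec:
    """One ellipsoidal fluid pocket: compartment, centre and semi-axes (um).

    ``center`` and ``semiaxes`` are (bscan_um, axial_um, lateral_um)
    coordinates; SRF pockets are half-ellipsoid domes whose flat face
    rests on the RPE (the axial semi-axis is the dome height).
    """

    compartment: str            # "irf" | "srf"
    center: Tuple[float, float, float]
    semiaxes: Tuple[float, float, float]
    volume_nl: float


def rasterize_ellipsoid(
    center_um: Tuple[float, float, float],
    semiaxes_um: Tuple[float, float, float],
    spacings_um: Tuple[float, float, float],
    shape: Tuple[int, int, int],
) -> np.ndarray:
    """Boolean mask of voxel centres inside an axis-aligned ellipsoid."""
    if min(spacings_um) <= 0:
        raise ValueError("spacings must be positive")
    coords = [np.arange(n) * s for n, s in zip(shape, spacings_um)]
    r2 = np.zeros(shape)
    for axis, (c, a) in enumerate(zip(center_um, semiaxes_um)):
        d = (coords[axis] - c) / a
        sh = [1, 1, 1]
        sh[axis] = -1
        r2 = r2 + (d * d).reshape(sh)
    return r2 <= 1.0


def _surface_stack(device: DeviceProfile, rng: np.random.Generator) -> dict:
    """Low-order polynomial layer surfaces (um depth), incl. a foveal dip."""
    ny, nx = device.n_bscans, device.width_px
    y = np.linspace(-1.0, 1.0, ny)[:, None]
    x = np.linspace(-1.0, 1.0, nx)[None, :]
    tilt = rng.normal(0.0, 18.0, size=2)
    curve = rng.normal(0.0, 12.0, size=3)
    base = tilt[0] * x + tilt[1] * y + curve[0] * x * x + curve[1] * y * y + curve[2] * x * y
    ilm = ILM_BASE_UM + base
    # foveal depression on the inner surface only
    xc = rng.normal(0.0, 0.1)
    yc = rng.normal(0.0, 0.1)
    x_um = (x - xc) * device.width_px * device.lateral_um_per_px / 2.0
    y_um = (y - yc) * device.n_bscans * device.bscan_spacing_um / 2.0
    r2 = x_um**2 + y_um**2
    dip = rng.uniform(35.0, 65.0) * np.exp(-r2 / (2 * 450.0**2))
    surfaces = {"ilm": ilm + dip}
    for name, th in THICKNESS_UM.items():
        surfaces[name] = ilm + th
    return surfaces


def plan_pockets(
    state: FluidState,
    device: DeviceProfile,
    rng: np.random.Generator,
) -> Tuple[PocketSpec, ...]:
    """Ellipsoid descriptors realising the requested IRF/SRF volumes.

    IRF is split over 1-3 ellipsoids (more for larger volumes) centred in
    the inner-retina compartment near the fovea; SRF is one dome with the
    height carried by the fluid state.
    """
    specs = []
    w_um = device.width_px * device.lateral_um_per_px
    d_um = device.n_bscans * device.bscan_spacing_um
    cx0, cy0 = w_um / 2.0, d_um / 2.0

    if state.irf_volume_nl > 0:
        v_um3 = state.irf_volume_nl * 1e6
        n_pockets = int(min(3, 1 + state.irf_volume_nl // 15))
        fractions = rng.dirichlet(np.full(n_pockets, 4.0)) if n_pockets > 1 else np.array([1.0])
        comp_thickness = THICKNESS_UM["opl"]  # ILM -> OPL
        c_cap = min(0.5 * comp_thickness - _COMPARTMENT_MARGIN_UM - 12.0, 62.0)
        aspect = 2.5   # lateral/axial semi-axis ratio of small cysts
        for frac in fractions:
            v = v_um3 * frac
            c_ax = float(np.clip((3.0 * v / (4.0 * np.pi * aspect**2)) ** (1.0 / 3.0),
                                 8.0, c_cap))
            a_lat = np.sqrt(3.0 * v / (4.0 * np.pi * c_ax))
            cx = cx0 + rng.uniform(-0.45, 0.45) * max(
                w_um / 2.0 - a_lat - 2 * device.lateral_um_per_px, 0.0)
            cy = cy0 + rng.uniform(-0.45, 0.45) * max(
                d_um / 2.0 - a_lat - 2 * device.bscan_spacing_um, 0.0)
            specs.append(PocketSpec("irf", (cy, 0.0, cx), (a_lat, c_ax, a_lat),
                                    volume_nl=v / 1e6))
    if state.srf_volume_nl > 0:
        h = state.srf_height_um
        a = SRF_DOME_ASPECT * h
        # an extreme dome wider than the scan is narrowed (taller) to fit
        a_max = min(w_um / 2.0 - 3 * device.lateral_um_per_px,
                    d_um / 2.0 - 3 * device.bscan_spacing_um)
        if a > a_max:
            a = a_max
            h = 3.0 * state.srf_volume_nl * 1e6 / (2.0 * np.pi * a * a)
        cx = cx0 + rng.uniform(-0.3, 0.3) * max(w_um / 2.0 - a - 2 * device.lateral_um_per_px, 0.0)
        cy = cy0 + rng.uniform(-0.3, 0.3) * max(d_um / 2.0 - a - 2 * device.bscan_spacing_um, 0.0)
        specs.append(PocketSpec("srf", (cy, h, cx), (a, h, a), volume_nl=state.srf_volume_nl))
    return tuple(specs)


def _fill_to_count(rho2: np.ndarray, admissible: np.ndarray, target: int) -> np.ndarray:
    """Select the `target` innermost admissible voxels of a pocket.

    ``rho2`` is the squared normalized radius of every voxel in the pocket's
    bounding box; voxels are admitted innermost-first until the requested
    count is reached, which pins the discretized volume to the requested
    one within half a voxel.
    """
    pool = admissible
    n_pool = int(pool.sum())
    if n_pool < target:
        raise RenderError("pocket extends outside its retinal compartment")
    flat = np.flatnonzero(pool.ravel())
    order = np.argsort(rho2.ravel()[flat], kind="stable")
    chosen = flat[order[:target]]
    out = np.zeros(rho2.size, dtype=bool)
    out[chosen] = True
    return out.reshape(rho2.shape)


def render_scan(
    state: FluidState,
    device: DeviceProfile,
    seed: int,
    meta: Optional[dict] = None,
) -> Tuple[OCTVolume, SegmentationMask]:
    """Render one SD-OCT volume and its exact fluid segmentation mask.

    Deterministic for fixed (state, device, seed).  The mask's ``layers``
    field carries the rendered boundary surfaces (row indices per column)
    including the photoreceptor band under the key ``"pr"``.
    """
    rng = np.random.default_rng(seed)
    ny, nz, nx = device.n_bscans, device.height_px, device.width_px
    bsp, ax, lat = device.bscan_spacing_um, device.axial_um_per_px, device.lateral_um_per_px
    voxvol = device.voxel_volume_um3

    surf = _surface_stack(device, rng)
    specs = state.pocket_spec or plan_pockets(state, device, rng)
    specs = tuple(specs)

    # SRF dome field lifts the neurosensory retina (ILM..PR) off the RPE.
    dome = np.zeros((ny, nx))
    for sp in specs:
        if sp.compartment != "srf":
            continue
        cy, h, cx = sp.center
        a = sp.semiaxes[0]
        yy = (np.arange(ny) * bsp - cy)[:, None] / a
        xx = (np.arange(nx) * lat - cx)[None, :] / a
        r2 = yy * yy + xx * xx
        dome += h * np.sqrt(np.clip(1.0 - r2, 0.0, None))

    z_ilm = surf["ilm"] - dome
    z_ipl = surf["ipl"] - dome
    z_opl = surf["opl"] - dome
    z_pr = surf["pr"] - dome
    z_rpe = surf["rpe"]
    z_bm = surf["bm"]
    max_depth = (nz - 1) * ax
    if np.nanmax(z_bm) + 60.0 > max_depth or np.nanmin(z_ilm) < 40.0:
        raise RenderError("retina does not fit inside the imaging window")

    # --- fluid voxel sets -------------------------------------------------
    coords_y = np.arange(ny) * bsp
    coords_z = np.arange(nz) * ax
    coords_x = np.arange(nx) * lat
    labels = np.zeros((ny, nz, nx), dtype=np.uint8)

    for sp in specs:
        target = int(round(sp.volume_nl * 1e6 / voxvol))
        if target == 0:
            continue
        cy, cz_or_h, cx = sp.center
        a_y, c_ax, a_x = sp.semiaxes[0], sp.semiaxes[1], sp.semiaxes[2]
        # bounding box (inflated, at least a few voxels wide) keeps the
        # exact-count search local
        ky0 = max(int((cy - _INFLATE * a_y) / bsp) - 2, 0)
        ky1 = min(int((cy + _INFLATE * a_y) / bsp) + 3, ny)
        jx0 = max(int((cx - _INFLATE * a_x) / lat) - 2, 0)
        jx1 = min(int((cx + _INFLATE * a_x) / lat) + 3, nx)
        cy_s = coords_y[ky0:ky1]
        cx_s = coords_x[jx0:jx1]
        if sp.compartment == "irf":
            # axial centre: middle of the local ILM-OPL compartment
            jx = int(np.clip(round(cx / lat), 0, nx - 1))
            ky = int(np.clip(round(cy / bsp), 0, ny - 1))
            cz = 0.5 * (z_ilm[ky, jx] + z_opl[ky, jx])
            iz0 = max(int((cz - _INFLATE * c_ax) / ax) - 1, 0)
            iz1 = min(int((cz + _INFLATE * c_ax) / ax) + 2, nz)
            cz_s = coords_z[iz0:iz1]
            dz = (cz_s - cz)[None, :, None] / c_ax
            dy = (cy_s - cy)[:, None, None] / a_y
            dx = (cx_s - cx)[None, None, :] / a_x
            rho2 = dz * dz + dy * dy + dx * dx
            zg = cz_s[None, :, None]
            lo = (z_ilm + _COMPARTMENT_MARGIN_UM)[ky0:ky1, None, jx0:jx1]
            hi = (z_opl - _COMPARTMENT_MARGIN_UM)[ky0:ky1, None, jx0:jx1]
            admissible = (zg > lo) & (zg < hi)
        else:
            h = cz_or_h
            rpe_box = z_rpe[ky0:ky1, jx0:jx1]
            iz0 = max(int((rpe_box.min() - _INFLATE * h) / ax) - 1, 0)
            iz1 = min(int(rpe_box.max() / ax) + 2, nz)
            cz_s = coords_z[iz0:iz1]
            zg = cz_s[None, :, None]
            rpe = rpe_box[:, None, :]
            dz = (rpe - zg) / h           # dome height coordinate, >= 0 below RPE
            dy = (cy_s - cy)[:, None, None] / a_y
            dx = (cx_s - cx)[None, None, :] / a_x
            rho2 = np.where(dz >= 0, dz * dz + dy * dy + dx * dx, np.inf)
            pr = z_pr[ky0:ky1, None, jx0:jx1]
            admissible = (zg < rpe) & (zg > pr + _PR_BAND_UM + 1.0)
        box = (slice(ky0, ky1), slice(iz0, iz1), slice(jx0, jx1))
        chosen = _fill_to_count(rho2, admissible & (labels[box] == 0), target)
        labels[box][chosen] = IRF_LABEL if sp.compartment == "irf" else SRF_LABEL

    # --- intensities ------------------------------------------------------
    vol = np.full((ny, nz, nx), _I_VITREOUS, dtype=np.float64)
    Z = coords_z[None, :, None]

    def _between(lo, hi):
        return (Z >= lo[:, None, :]) & (Z < hi[:, None, :])

    vol[_between(z_ilm, z_rpe)] = _I_RETINA
    vol[_between(z_ipl - _BAND_HALF_UM, z_ipl + _BAND_HALF_UM)] = _I_PLEXIFORM
    vol[_between(z_opl - _BAND_HALF_UM, z_opl + _BAND_HALF_UM)] = _I_PLEXIFORM
    vol[_between(z_ilm, z_ilm + _ILM_LINE_UM)] = _I_ILM_LINE
    vol[_between(z_pr, z_pr + _PR_BAND_UM)] = _I_PR_BAND
    vol[_between(z_rpe, z_bm + ax)] = _I_RPE_BAND
    vol[Z >= (z_bm + ax)[:, None, :]] = _I_CHOROID
    vol[labels > 0] = _I_FLUID

    if device.speckle_sd > 0:
        s = device.speckle_sd
        speckle = np.exp(rng.normal(-0.5 * s * s, s, size=vol.shape))
        vol = vol * speckle
    if device.intensity_gamma != 1.0:
        vol = np.clip(vol, 0.0, None) ** device.intensity_gamma
    vol = np.clip(vol, 0.0, 1.0).astype(np.float32)

    spacings = (bsp, ax, lat)
    layer_rows = LayerSet({
        "ilm": np.broadcast_to(z_ilm / ax, (ny, nx)).copy(),
        "ipl": np.broadcast_to(z_ipl / ax, (ny, nx)).copy(),
        "opl": np.broadcast_to(z_opl / ax, (ny, nx)).copy(),
        "pr": np.broadcast_to(z_pr / ax, (ny, nx)).copy(),
        "rpe": np.broadcast_to(z_rpe / ax, (ny, nx)).copy(),
        "bm": np.broadcast_to(z_bm / ax, (ny, nx)).copy(),
    })
    base_meta = dict(meta or {})
    base_meta.setdefault("render_seed", int(seed))
    ovol = OCTVolume(vol, spacings, meta=base_meta)
    mask = SegmentationMask(labels, spacings, layers=layer_rows, meta=dict(base_meta))
    return ovol, mask
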