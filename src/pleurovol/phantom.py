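"""Synthetic chest-CT phantoms with analytic ground truth.

A phantom is a torso of soft tissue (default 40 HU) standing in exterior
air (-1000 HU), containing two ellipsoidal aerated lungs (-850 HU), a
trachea/main-bronchus air tree opening at the superior face, and — on the
affected side — a pleural rind of soft-tissue HU of controlled thickness.
The rind is carved per craniocaudal level as a uniform inward offset of the
lung cross-section (an exact Euclidean-distance offset in each axial
slice), so its thickness perpendicular to the chest wall equals the
requested ``rind_mm`` everywhere, which keeps the ground truth analytic.

Ground truth (per-side aerated volume, airway volume, disease burden under
the default substitution rules) is defined on the noise-free generating
masks; Gaussian HU noise, if requested, is added afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import CTVolume

__all__ = ["PhantomSpec", "PhantomTruth", "PhantomGeometryError", "generate_phantom"]

#: lesions thinner than this (mm) are "too small to measure" and take the
#: 5 mm default; matches one 3 mm acquisition slice.
MEASURABLE_FLOOR_MM = 3.0
DEFAULT_SMALL_MM = 5.0


class PhantomGeometryError(ValueError):
    """Requested phantom geometry does not fit the voxel grid."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic chest CT.

    Defaults emulate a post-chemotherapy staging CT: 3 mm slices, 1.5 mm
    in-plane voxels, ~1.4 L lungs, a 9 mm-radius trachea.  ``level_planes``
    are the two axial indices standing in for the inferior aortic-arch
    margin and the left-atrium floor, splitting the hemithorax into the
    upper/middle/lower measurement levels.
    """

    grid_shape: tuple[int, int, int] = (75, 128, 192)
    spacing_mm: tuple[float, float, float] = (3.0, 1.5, 1.5)
    body_hu: float = 40.0
    lung_hu: float = -850.0
    air_hu: float = -1000.0
    lung_semiaxes_mm: tuple[float, float, float] = (95.0, 75.0, 55.0)  # (z, y, x)
    affected_side: str = "right"
    rind_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (upper, middle, lower)
    airway_radius_mm: float = 9.0
    noise_sd_hu: float = 0.0
    seed: int = 0
    level_planes: tuple[int, int] = (30, 50)
    # secondary geometry knobs
    mediastinum_gap_mm: float = 30.0  # lung-to-lung gap housing trachea
    chest_wall_mm: float = 15.0       # body tissue outside the pleural cavity
    apex_margin_mm: float = 25.0      # superior body tissue above the lung apex

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 4:
            raise PhantomGeometryError(f"grid_shape too small: {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomGeometryError("spacing_mm must be positive")
        if any(r < 0 for r in self.rind_mm) or len(self.rind_mm) != 3:
            raise PhantomGeometryError("rind_mm must be three values >= 0")
        if self.noise_sd_hu < 0:
            raise PhantomGeometryError("noise_sd_hu must be >= 0")
        if self.airway_radius_mm < 0:
            raise PhantomGeometryError("airway_radius_mm must be >= 0")
        if self.affected_side not in ("left", "right"):
            raise PhantomGeometryError("affected_side must be 'left' or 'right'")
        p1, p2 = self.level_planes
        if not (0 < p1 < p2 < self.grid_shape[0]):
            raise PhantomGeometryError(
                f"level_planes must be strictly increasing inside the grid, got {self.level_planes}"
            )
        if self.airway_radius_mm > 0 and 2 * self.airway_radius_mm >= self.mediastinum_gap_mm:
            raise PhantomGeometryError("airway does not fit inside the mediastinal gap")
        az, ay, ax = self.lung_semiaxes_mm
        if min(az, ay, ax) <= 0:
            raise PhantomGeometryError("lung semi-axes must be positive")
        nz, ny, nx = self.grid_shape
        sz, sy, sx = self.spacing_mm
        ext_z, ext_y, ext_x = nz * sz, ny * sy, nx * sx
        rx_body = ax + self.mediastinum_gap_mm / 2 + ax + self.chest_wall_mm
        ry_body = ay + self.chest_wall_mm
        # require >= 2 voxels of exterior air around the torso and below the lungs
        if rx_body + 2 * sx > ext_x / 2 or ry_body + 2 * sy > ext_y / 2:
            raise PhantomGeometryError(
                f"torso (semi-axes {rx_body:.0f}x{ry_body:.0f} mm) does not fit the "
                f"{ext_x:.0f}x{ext_y:.0f} mm grid cross-section"
            )
        if self.apex_margin_mm + 2 * az + 2 * sz > ext_z:
            raise PhantomGeometryError("lungs do not fit the grid craniocaudally")


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom, defined on the noise-free masks."""

    true_lung_volume_cm3: dict[str, float]      # {"left": ..., "right": ...}
    true_airway_volume_cm3: float
    true_burden_mm: float
    true_level_slots_mm: tuple[tuple[float, float], ...]  # three (t1, t2) pairs
    left_lung_mask: np.ndarray = field(repr=False)
    right_lung_mask: np.ndarray = field(repr=False)
    airway_mask: np.ndarray = field(repr=False)
    body_mask: np.ndarray = field(repr=False)


def _slot_values(t: float) -> tuple[float, float]:
    """Two per-level measurement slots under the default substitution rules."""
    if t <= 0:
        return (0.0, 0.0)
    if t < MEASURABLE_FLOOR_MM:
        return (DEFAULT_SMALL_MM, DEFAULT_SMALL_MM)
    return (float(t), float(t))


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Build a phantom volume plus its ground truth.

    The airway is a trachea cylinder from the superior face down to the
    carina, with two main bronchi running laterally into each lung; the
    lumen carries a one-voxel soft-tissue bronchial wall and opens into the
    aerated lung at its distal end, so thresholding connects the lungs only
    through the airway tree.
    """
    nz, ny, nx = spec.grid_shape
    sz, sy, sx = spec.spacing_mm
    az, ay, ax = spec.lung_semiaxes_mm

    # voxel-centre physical coordinates; +0.5 keeps the grid mirror-symmetric
    zc = (np.arange(nz) + 0.5) * sz
    yc = (np.arange(ny) + 0.5) * sy
    xc = (np.arange(nx) + 0.5) * sx
    cy_mm, cx_mm = ny * sy / 2, nx * sx / 2

    dx = ax + spec.mediastinum_gap_mm / 2
    centers_x = {"right": cx_mm - dx, "left": cx_mm + dx}  # x grows to patient's left
    lcz = spec.apex_margin_mm + az  # lung centre, craniocaudal

    yy, xx = np.meshgrid(yc, xc, indexing="ij")
    # torso cross-section: the widest lung cross-sections plus the trachea,
    # dilated by the chest-wall thickness (exact Euclidean dilation, so the
    # wall is uniform even on oblique directions)
    union2d = np.zeros((ny, nx), dtype=bool)
    for lcx in centers_x.values():
        union2d |= ((yy - cy_mm) / ay) ** 2 + ((xx - lcx) / ax) ** 2 <= 1.0
    if spec.airway_radius_mm > 0:
        union2d |= (yy - cy_mm) ** 2 + (xx - cx_mm) ** 2 <= (
            spec.airway_radius_mm + max(sy, sx)
        ) ** 2
    torso2d = union2d | (
        ndimage.distance_transform_edt(~union2d, sampling=(sy, sx)) <= spec.chest_wall_mm
    )

    def level_rind(zi: int) -> float:
        p1, p2 = spec.level_planes
        if zi < p1:
            return spec.rind_mm[0]
        if zi < p2:
            return spec.rind_mm[1]
        return spec.rind_mm[2]

    aerated = {s: np.zeros(spec.grid_shape, dtype=bool) for s in ("left", "right")}
    hosted_t = np.zeros(nz)  # rind thickness actually carved per slice
    for zi in range(nz):
        f = 1.0 - ((zc[zi] - lcz) / az) ** 2
        if f <= 0:
            continue
        ey, ex = ay * np.sqrt(f), ax * np.sqrt(f)
        for side, lcx in centers_x.items():
            ell = ((yy - cy_mm) / ey) ** 2 + ((xx - lcx) / ex) ** 2 <= 1.0
            t = level_rind(zi) if side == spec.affected_side else 0.0
            if t > 0 and ell.any():
                # an inward offset by t is only a uniform-thickness shell while
                # t stays below the pole radius of curvature B^2/A; cap the
                # per-slice rind there so the apex/base caps carry a thinner,
                # still uniform rind instead of an ill-posed one
                big, small = max(ey, ex), min(ey, ex)
                cap = small * small / big - 2.0 * max(sy, sx)
                tz = min(t, max(cap, 0.0))
                if tz > 0:
                    d_in = ndimage.distance_transform_edt(ell, sampling=(sy, sx))
                    ell &= d_in > tz  # rind = the carved-off uniform shell
                    hosted_t[zi] = tz
            aerated[side][zi] = ell
    for li, (z_lo, z_hi) in enumerate(
        ((0, spec.level_planes[0]), spec.level_planes, (spec.level_planes[1], nz))
    ):
        t = spec.rind_mm[li]
        if t > 0 and (z_hi <= z_lo or hosted_t[z_lo:z_hi].max() < t):
            raise PhantomGeometryError(
                f"rind {t} mm cannot be hosted at full thickness anywhere in "
                f"level {li} (lung cross-sections too small there)"
            )

    # ---- airway tree -------------------------------------------------------
    r = spec.airway_radius_mm
    lumen = np.zeros(spec.grid_shape, dtype=bool)
    wall = np.zeros(spec.grid_shape, dtype=bool)
    if r > 0:
        wt = max(sy, sx)  # one in-plane voxel of bronchial wall
        carina_zi = int(np.searchsorted(zc, lcz))
        trachea2d = (yy - cy_mm) ** 2 + (xx - cx_mm) ** 2 <= r**2
        trachea2d_w = (yy - cy_mm) ** 2 + (xx - cx_mm) ** 2 <= (r + wt) ** 2
        lumen[: carina_zi + 1] |= trachea2d
        wall[: carina_zi + 1] |= trachea2d_w & ~trachea2d
        # main bronchi: cylinders along x at carina height, open distal ends
        zz2, yy2 = np.meshgrid(zc, yc, indexing="ij")
        bz = zc[carina_zi]
        tube = (zz2 - bz) ** 2 + (yy2 - cy_mm) ** 2 <= r**2
        tube_w = (zz2 - bz) ** 2 + (yy2 - cy_mm) ** 2 <= (r + wt) ** 2
        for side, lcx in centers_x.items():
            lo, hi = sorted((cx_mm, lcx))
            xsel = (xc >= lo) & (xc <= hi)
            lumen[:, :, xsel] |= tube[:, :, None]
            wall[:, :, xsel] |= (tube_w & ~tube)[:, :, None]
        wall &= ~lumen

    # ---- compose HU --------------------------------------------------------
    hu = np.full(spec.grid_shape, spec.air_hu, dtype=np.float32)
    hu[:, torso2d] = spec.body_hu
    for side in ("left", "right"):
        aerated[side] &= ~wall
        aerated[side] &= ~lumen
        hu[aerated[side]] = spec.lung_hu
    hu[wall] = spec.body_hu
    hu[lumen] = spec.air_hu

    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu = (hu + rng.normal(0.0, spec.noise_sd_hu, size=hu.shape)).astype(np.float32)

    if not (aerated["left"].any() and aerated["right"].any()):
        raise PhantomGeometryError("a lung vanished (rind thicker than the lung?)")

    voxvol_cm3 = (sz * sy * sx) / 1000.0
    slots = tuple(_slot_values(t) for t in spec.rind_mm)
    body_mask = np.broadcast_to(torso2d, spec.grid_shape).copy()
    body_mask |= wall
    body_mask &= ~(aerated["left"] | aerated["right"] | lumen)
    truth = PhantomTruth(
        true_lung_volume_cm3={s: float(aerated[s].sum() * voxvol_cm3) for s in ("left", "right")},
        true_airway_volume_cm3=float(lumen.sum() * voxvol_cm3),
        true_burden_mm=float(sum(a + b for a, b in slots)),
        true_level_slots_mm=slots,
        left_lung_mask=aerated["left"],
        right_lung_mask=aerated["right"],
        airway_mask=lumen,
        body_mask=body_mask,
    )
    vol = CTVolume(hu=hu, spacing_mm=spec.spacing_mm, affected_side=spec.affected_side)
    return vol, truth
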