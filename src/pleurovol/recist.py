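"""Pleural thickness per modified RECIST and the disease burden.

The affected hemithorax is split into three craniocaudal levels by two
axial landmarks (inferior margin of the aortic arch, floor of the left
atrium — supplied as slice indices, never auto-detected).  At each level
the two largest pleural thicknesses, taken on distinct axial slices and
perpendicular to the chest wall or mediastinum, are recorded; a lesion
too small to measure takes a 5 mm default, an absent lesion 0 mm; the sum
of the six values is the disease burden in mm.

Measuring thickness needs a reference for where the chest wall would be
if the pleural space were disease-free.  A radiologist reads this off the
bony thorax; here the expected pleural-cavity boundary on each axial
slice is estimated as the convex hull of the *contralateral* aerated lung
mirrored across the body midline.  Thickness at a cavity-boundary point
is then its in-plane Euclidean distance to the nearest aerated voxel of
the affected lung — for a rind of uniform thickness t this distance is
exactly t, realised along the boundary normal.  A candidate measurement
is discarded when the straight path from the wall to the lung crosses
non-soft-tissue (e.g. the air column of a main bronchus), mirroring the
rule that only solid pleural tissue is measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .segmentation import midsagittal_x
from .volume import CTVolume

__all__ = [
    "LevelPartition",
    "ThicknessPair",
    "BurdenMeasurement",
    "partition_levels",
    "measure_level_thickness",
    "disease_burden",
    "measure_burden",
]

MEASURABLE_FLOOR_MM = 3.0   # below this a lesion is "too small to measure"
DEFAULT_SMALL_MM = 5.0      # default for too-small lesions
DEFAULT_ABSENT_MM = 0.0     # default for absent lesions

LEVELS = ("upper", "middle", "lower")


@dataclass(frozen=True)
class LevelPartition:
    """Half-open axial slice intervals for the three measurement levels."""

    upper_range: tuple[int, int]
    middle_range: tuple[int, int]
    lower_range: tuple[int, int]

    def range_for(self, level: str) -> tuple[int, int]:
        return getattr(self, f"{level}_range")


@dataclass(frozen=True)
class ThicknessPair:
    """Two per-level thickness slots (mm) with their substitution flags.

    ``flags`` are each ``"measured"``, ``"default_small"`` (5 mm) or
    ``"absent"`` (0 mm); ``t1_mm >= t2_mm`` after substitution.
    """

    t1_mm: float
    t2_mm: float
    flags: tuple[str, str]

    @property
    def max_mm(self) -> float:
        return self.t1_mm


@dataclass(frozen=True)
class BurdenMeasurement:
    levels: dict[str, ThicknessPair]
    burden_mm: float
    per_level_max_mm: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "burden_mm": self.burden_mm,
            "per_level_max_mm": dict(self.per_level_max_mm),
            "levels": {
                lv: {"t1_mm": p.t1_mm, "t2_mm": p.t2_mm, "flags": list(p.flags)}
                for lv, p in self.levels.items()
            },
        }


def partition_levels(
    landmarks: tuple[int, int],
    z_extent: tuple[int, int] | None = None,
    lung_mask: np.ndarray | None = None,
) -> LevelPartition:
    """Split the hemithorax's axial extent at two landmark slice indices.

    ``z_extent`` is half-open ``[z0, z1)``; if omitted it is taken from the
    axial extent of ``lung_mask``.  The landmarks must fall strictly inside
    the extent and leave all three levels non-empty.
    """
    if z_extent is None:
        if lung_mask is None:
            raise ValueError("provide z_extent or lung_mask")
        zs = np.flatnonzero(lung_mask.any(axis=(1, 2)))
        if zs.size == 0:
            raise ValueError("lung mask empty; no axial extent")
        z_extent = (int(zs[0]), int(zs[-1]) + 1)
    z0, z1 = int(z_extent[0]), int(z_extent[1])
    p1, p2 = int(landmarks[0]), int(landmarks[1])
    if not (z0 < p1 < p2 < z1):
        raise ValueError(
            f"landmarks {landmarks} must be strictly increasing inside the "
            f"axial extent [{z0}, {z1}) and leave every level non-empty"
        )
    return LevelPartition((z0, p1), (p1, p2), (p2, z1))


def _mirror_columns(sl: np.ndarray, mid: float) -> np.ndarray:
    """Reflect a 2D mask about the vertical line x = mid (voxel indices)."""
    nx = sl.shape[1]
    out = np.zeros_like(sl)
    src = np.flatnonzero(sl.any(axis=0))
    if src.size == 0:
        return out
    dst = np.round(2.0 * mid - src).astype(int)
    ok = (dst >= 0) & (dst < nx)
    out[:, dst[ok]] = sl[:, src[ok]]
    return out


def measure_level_thickness(
    vol: CTVolume,
    lung_masks: dict[str, np.ndarray],
    partition: LevelPartition,
    level: str,
    side: str | None = None,
    measurable_floor_mm: float = MEASURABLE_FLOOR_MM,
    soft_hu: float = -250.0,
) -> ThicknessPair:
    """Two largest pleural thicknesses at one level, on distinct slices.

    ``lung_masks`` maps ``"left"``/``"right"`` to aerated-lung masks from
    segmentation.  ``side`` defaults to the volume's ``affected_side``.
    """
    side = side or vol.affected_side
    if side not in ("left", "right"):
        raise ValueError("affected side must be known")
    if side not in lung_masks or lung_masks[side] is None:
        raise ValueError(f"missing lung mask for affected side {side!r}")
    contra = "right" if side == "left" else "left"
    if contra not in lung_masks or lung_masks[contra] is None:
        raise ValueError(f"missing lung mask for contralateral side {contra!r}")
    z0, z1 = partition.range_for(level)
    if z1 <= z0:
        raise ValueError(f"empty level {level!r}: range [{z0}, {z1})")

    _, sy, sx = vol.spacing_mm
    s_vox = (sy + sx) / 2.0
    # raw centre-to-centre distances at or below this are boundary
    # discretisation, not lesion
    presence_floor_mm = 0.75 * s_vox
    mid = midsagittal_x(vol)
    affected = lung_masks[side]
    contra_mask = lung_masks[contra]
    cross = ndimage.generate_binary_structure(2, 1)

    slice_max: list[float] = []
    for zi in range(z0, z1):
        a = affected[zi]
        c = contra_mask[zi]
        if not a.any() or not c.any():
            continue
        mirrored = _mirror_columns(c, mid)
        cavity = convex_hull_image(mirrored)
        if not cavity.any():
            continue
        boundary = cavity & ~ndimage.binary_erosion(cavity, structure=cross)
        # keep only boundary points that belong to the mirrored lung itself:
        # voxels the hull bridged in (bronchus mouth, discretisation
        # concavities) are not chest wall and must not seed measurements
        boundary &= mirrored
        dist, inds = ndimage.distance_transform_edt(
            ~a, sampling=(sy, sx), return_indices=True
        )
        # depth of each cavity voxel below the cavity surface; adding it to
        # the centre-to-centre lung distance and removing one voxel of
        # half-voxel surface offsets reconstructs surface-to-surface thickness
        edt_cav = ndimage.distance_transform_edt(mirrored, sampling=(sy, sx))
        best = 0.0
        hu2 = vol.hu[zi]
        for py, px in np.argwhere(boundary):
            d = float(dist[py, px])
            if d <= presence_floor_mm:
                continue
            t_hat = d + float(edt_cav[py, px]) - s_vox
            if t_hat <= best:
                continue
            # validate: straight wall-to-lung path must be soft tissue
            ty, tx = int(inds[0, py, px]), int(inds[1, py, px])
            nstep = max(2, int(np.ceil(d / min(sy, sx))) + 1)
            ys = np.round(np.linspace(py, ty, nstep)).astype(int)
            xs = np.round(np.linspace(px, tx, nstep)).astype(int)
            samp = hu2[ys, xs]
            in_lung = a[ys, xs]
            if np.any((samp <= soft_hu) & ~in_lung):
                continue
            best = t_hat
        slice_max.append(best)
    if not slice_max:
        # level has no measurable aerated reference at all
        return ThicknessPair(DEFAULT_ABSENT_MM, DEFAULT_ABSENT_MM, ("absent", "absent"))

    slice_max.sort(reverse=True)
    raw = [slice_max[0], slice_max[1] if len(slice_max) > 1 else 0.0]

    def substitute(m: float) -> tuple[float, str]:
        if m <= 0.0:
            return DEFAULT_ABSENT_MM, "absent"
        if m < measurable_floor_mm:
            return DEFAULT_SMALL_MM, "default_small"
        return float(m), "measured"

    pairs = sorted((substitute(m) for m in raw), key=lambda t: -t[0])
    return ThicknessPair(pairs[0][0], pairs[1][0], (pairs[0][1], pairs[1][1]))


def disease_burden(levels: dict[str, ThicknessPair]) -> BurdenMeasurement:
    """Sum the six per-slot values into the disease burden (mm)."""
    missing = [lv for lv in LEVELS if lv not in levels]
    if missing:
        raise ValueError(f"missing level measurement(s): {missing}")
    burden = float(sum(levels[lv].t1_mm + levels[lv].t2_mm for lv in LEVELS))
    return BurdenMeasurement(
        levels={lv: levels[lv] for lv in LEVELS},
        burden_mm=burden,
        per_level_max_mm={lv: levels[lv].max_mm for lv in LEVELS},
    )


def measure_burden(
    vol: CTVolume,
    lung_masks: dict[str, np.ndarray],
    landmarks: tuple[int, int],
    side: str | None = None,
) -> BurdenMeasurement:
    """Convenience wrapper: partition, measure all three levels, sum."""
    side = side or vol.affected_side
    part = partition_levels(landmarks, lung_mask=lung_masks[side])
    return disease_burden(
        {lv: measure_level_thickness(vol, lung_masks, part, lv, side) for lv in LEVELS}
    )
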