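"""Semi-automated aerated-lung segmentation and volumetry.

The pipeline mirrors the classic threshold-based workflow: apply a
Hounsfield-unit window (default -1020..-250, endpoints inclusive) that
keeps air, airway lumen and aerated lung while rejecting soft tissue;
discard exterior air (components touching the lateral faces of the
volume); identify and crop the trachea/main-bronchus tree by seeded
region growing from the most superior in-body air voxel; split the
remaining components into left and right lungs about the body midline;
and report per-lung volumes plus the contralateral-minus-ipsilateral
difference in cm3 and percent.

Percent difference is taken relative to the contralateral lung:
``diff_pct = 100 * (contra - ipsi) / contra``.  This is the convention
under which a severely contracted hemithorax approaches 100% and an
ipsilateral lung larger than the contralateral one goes negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import CTVolume

__all__ = [
    "SegmentationError",
    "SegmentationResult",
    "threshold_mask",
    "remove_exterior_and_airways",
    "split_left_right",
    "volumetry",
    "segment_lungs",
]

#: HU below which a voxel counts as airway-lumen air when growing the
#: tracheobronchial tree; midpoint of aerated lung (~-850) and air (-1000).
AIRWAY_HU_MAX = -925.0

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


class SegmentationError(RuntimeError):
    pass


@dataclass
class SegmentationResult:
    left_mask: np.ndarray = field(repr=False)
    right_mask: np.ndarray = field(repr=False)
    airway_mask: np.ndarray = field(repr=False)
    left_volume_cm3: float = 0.0
    right_volume_cm3: float = 0.0
    ipsilateral_volume_cm3: float = 0.0
    contralateral_volume_cm3: float = 0.0
    diff_cm3: float = 0.0
    diff_pct: float = 0.0
    affected_side: str = "unknown"

    def as_dict(self) -> dict:
        return {
            "left_volume_cm3": self.left_volume_cm3,
            "right_volume_cm3": self.right_volume_cm3,
            "ipsilateral_volume_cm3": self.ipsilateral_volume_cm3,
            "contralateral_volume_cm3": self.contralateral_volume_cm3,
            "diff_cm3": self.diff_cm3,
            "diff_pct": self.diff_pct,
            "affected_side": self.affected_side,
        }


def threshold_mask(vol: CTVolume, lo_hu: float = -1020.0, hi_hu: float = -250.0) -> np.ndarray:
    """Voxels with ``lo_hu <= HU <= hi_hu`` (inclusive endpoints)."""
    if not lo_hu < hi_hu:
        raise ValueError(f"lo_hu must be < hi_hu, got {lo_hu}, {hi_hu}")
    if not np.isfinite(vol.hu).all():
        raise ValueError("volume contains non-finite HU")
    return (vol.hu >= lo_hu) & (vol.hu <= hi_hu)


def body_mask(vol: CTVolume, soft_hu: float = -250.0) -> np.ndarray:
    """Largest connected soft-tissue component — the torso."""
    soft = vol.hu > soft_hu
    lab, n = ndimage.label(soft, structure=_STRUCT26)
    if n == 0:
        raise SegmentationError("no soft tissue in volume — no body found")
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (int(np.argmax(sizes)) + 1)


def midsagittal_x(vol: CTVolume) -> float:
    """x index of the body midline, from the hole-filled torso outline.

    Filling the pleural cavities first makes the estimate invariant to
    one-sided disease (a thick rind adds soft tissue on the affected side
    and would otherwise pull a plain tissue centroid toward it).
    """
    body = body_mask(vol)
    filled = np.stack([ndimage.binary_fill_holes(sl) for sl in body])
    return float(np.argwhere(filled)[:, 2].mean())


_midline_x = midsagittal_x


def remove_exterior_and_airways(
    mask: np.ndarray,
    vol: CTVolume,
    airway_hu_max: float = AIRWAY_HU_MAX,
    min_component_cm3: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Strip exterior air and crop the tracheobronchial tree.

    Exterior air is every thresholded component touching a lateral (x or y)
    face of the volume.  The airway is found by region growing over
    lumen-density voxels (``HU <= airway_hu_max``) from the most superior
    such voxel left after exterior removal — the tracheal lumen, which by
    convention opens at the superior face of the scan.  The grown tree is
    dilated by one voxel before subtraction so noisy lumen-boundary voxels
    do not leak into the lungs; the dilation margin only claims voxels that
    are themselves lumen-density, leaving aerated lung untouched.

    Returns ``(lung_mask, airway_mask)``.
    """
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 0:
        raise SegmentationError("no lung found: threshold mask is empty")
    exterior_labels = set()
    for face in (lab[:, 0, :], lab[:, -1, :], lab[:, :, 0], lab[:, :, -1]):
        exterior_labels |= set(np.unique(face[face > 0]).tolist())
    candidates = mask & ~np.isin(lab, sorted(exterior_labels))
    # drop speckle (isolated noise components)
    min_vox = int(round(min_component_cm3 * 1000.0 / vol.voxel_volume_mm3))
    if min_vox > 1:
        lab2, n2 = ndimage.label(candidates, structure=_STRUCT26)
        if n2:
            sizes = np.bincount(lab2.ravel())
            small = np.flatnonzero(sizes < min_vox)
            candidates &= ~np.isin(lab2, small[small > 0])
    if not candidates.any():
        raise SegmentationError("no lung found: all thresholded air is exterior")

    lumenlike = candidates & (vol.hu <= airway_hu_max)
    airway = np.zeros_like(candidates)
    if lumenlike.any():
        pts = np.argwhere(lumenlike)
        top = pts[pts[:, 0] == pts[:, 0].min()]
        cy, cx = np.array(vol.shape[1:]) / 2.0
        seed = tuple(top[np.argmin((top[:, 1] - cy) ** 2 + (top[:, 2] - cx) ** 2)])
        lab3, _ = ndimage.label(lumenlike, structure=_STRUCT26)
        grown = lab3 == lab3[seed]
        margin = ndimage.binary_dilation(grown, structure=_STRUCT26)
        airway = margin & lumenlike
    else:
        warnings.warn("airway seed not found; no airway cropped", stacklevel=2)
    lung = candidates & ~airway
    if not lung.any():
        raise SegmentationError("no lung found after airway cropping")
    return lung, airway


def split_left_right(
    lung_mask: np.ndarray, vol: CTVolume, fused_margin_voxels: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Assign candidate components to left/right by centroid vs body midline.

    ``x`` increases toward the patient's left in the canonical frame.  A
    single component straddling the midline by more than ``fused_margin_voxels``
    on both sides is split by the midsagittal plane with a warning.
    """
    if not lung_mask.any():
        raise SegmentationError("empty lung mask")
    mid = _midline_x(vol)
    lab, n = ndimage.label(lung_mask, structure=_STRUCT26)
    left = np.zeros_like(lung_mask)
    right = np.zeros_like(lung_mask)
    xs = np.arange(lung_mask.shape[2])
    for i in range(1, n + 1):
        comp = lab == i
        colx = xs[comp.any(axis=(0, 1))]
        if colx.min() < mid - fused_margin_voxels and colx.max() > mid + fused_margin_voxels:
            cmin, cmax = colx.min(), colx.max()
            # fused across the midline only if it has real bulk on both sides
            centroid = float(np.argwhere(comp)[:, 2].mean())
            if cmax - cmin > 2 * fused_margin_voxels and (
                comp[:, :, : int(np.floor(mid))].sum() > 0
                and comp[:, :, int(np.ceil(mid)) :].sum() > 0
            ):
                warnings.warn(
                    "fused lung component spans the midline; splitting by the "
                    "midsagittal plane",
                    stacklevel=2,
                )
                right_part = comp.copy()
                right_part[:, :, int(np.round(mid)) :] = False
                right |= right_part
                left |= comp & ~right_part
                continue
        centroid = float(np.argwhere(comp)[:, 2].mean())
        if centroid > mid:
            left |= comp
        else:
            right |= comp
    return left, right


def volumetry(
    left_mask: np.ndarray,
    right_mask: np.ndarray,
    airway_mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
    affected_side: str,
) -> SegmentationResult:
    """Per-lung volumes (voxel count x voxel volume) and the volumetric
    difference of the contralateral minus the disease-affected lung."""
    if affected_side not in ("left", "right"):
        raise ValueError(f"affected_side must be known, got {affected_side!r}")
    voxvol_cm3 = float(np.prod(spacing_mm)) / 1000.0
    lv = float(left_mask.sum()) * voxvol_cm3
    rv = float(right_mask.sum()) * voxvol_cm3
    ipsi, contra = (lv, rv) if affected_side == "left" else (rv, lv)
    if contra <= 0:
        raise SegmentationError("contralateral lung volume is zero; diff_pct undefined")
    diff = contra - ipsi
    return SegmentationResult(
        left_mask=left_mask,
        right_mask=right_mask,
        airway_mask=airway_mask,
        left_volume_cm3=lv,
        right_volume_cm3=rv,
        ipsilateral_volume_cm3=ipsi,
        contralateral_volume_cm3=contra,
        diff_cm3=diff,
        diff_pct=100.0 * diff / contra,
        affected_side=affected_side,
    )


def segment_lungs(
    vol: CTVolume,
    lo_hu: float = -1020.0,
    hi_hu: float = -250.0,
    airway_hu_max: float = AIRWAY_HU_MAX,
) -> SegmentationResult:
    """Full pipeline: threshold, crop exterior/airways, split, measure."""
    mask = threshold_mask(vol, lo_hu, hi_hu)
    lung, airway = remove_exterior_and_airways(mask, vol, airway_hu_max=airway_hu_max)
    left, right = split_left_right(lung, vol)
    return volumetry(left, right, airway, vol.spacing_mm, vol.affected_side)
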