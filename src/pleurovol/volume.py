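"""CT volume container and NIfTI I/O.

The package uses one fixed array convention for every volume:

* axis order ``(z, y, x)``;
* ``z`` is craniocaudal with index 0 the most **superior** slice;
* ``x`` increases toward the patient's **left** (so on an axial slice the
  patient's right lung sits at low ``x``);
* ``spacing_mm`` is the per-axis voxel size in millimetres, ordered like
  the array axes.

Volumes read from disk are re-oriented into this convention regardless of
how they were stored; writing inverts the mapping, so a write/read
round-trip is the identity on both voxel values and spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["CTVolume", "VolumeFormatError", "read_volume", "write_volume"]


class VolumeFormatError(ValueError):
    """Raised when a volume file is malformed or missing required metadata."""


@dataclass
class CTVolume:
    """A 3D CT scan in Hounsfield units.

    Parameters
    ----------
    hu
        3D array of Hounsfield units, canonical ``(z, y, x)`` order.
    spacing_mm
        Voxel size per axis ``(z, y, x)`` in mm, strictly positive.
    affected_side
        ``"left"``, ``"right"`` or ``"unknown"`` — the hemithorax carrying
        pleural disease.  Always supplied as metadata, never inferred from
        the image.
    """

    hu: np.ndarray
    spacing_mm: tuple[float, float, float]
    affected_side: str = "unknown"

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise ValueError(f"hu must be 3D, got shape {self.hu.shape}")
        if min(self.hu.shape) < 1:
            raise ValueError("zero-thickness volume")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive values, got {self.spacing_mm}")
        if not np.isfinite(self.hu).all():
            raise ValueError("hu contains non-finite values")
        if self.affected_side not in ("left", "right", "unknown"):
            raise ValueError(f"affected_side must be left|right|unknown, got {self.affected_side!r}")

    @property
    def voxel_volume_mm3(self) -> float:
        sz, sy, sx = self.spacing_mm
        return sz * sy * sx

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.hu.shape)


def _canonical_from_ras(data: np.ndarray) -> np.ndarray:
    # RAS+ array axes are (x->right, y->anterior, z->superior, all increasing);
    # canonical is (z sup->inf, y, x right->left).
    return np.ascontiguousarray(data.transpose(2, 1, 0)[::-1, :, ::-1])


def _ras_from_canonical(data: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(data[::-1, :, ::-1].transpose(2, 1, 0))


def write_volume(vol: CTVolume, path) -> None:
    """Write a :class:`CTVolume` as NIfTI (``.nii`` / ``.nii.gz``).

    Voxel values are stored as float32; HU values generated by this package
    are float32 already, so the round trip is exact.
    """
    ras = _ras_from_canonical(np.asarray(vol.hu, dtype=np.float32))
    sz, sy, sx = vol.spacing_mm
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(ras, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))


def read_volume(path, affected_side: str = "unknown") -> CTVolume:
    """Read a NIfTI volume and re-orient it into the canonical (z,y,x) frame.

    Any axis order/flip encoded in the affine is honoured, so volumes stored
    e.g. in (z,y,x) or flipped layouts come back in the package convention.

    Raises
    ------
    VolumeFormatError
        If the file cannot be parsed or its spacing metadata is missing
        (zero/negative voxel sizes).
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read volume {path!r}: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(
            f"missing or invalid spacing_mm metadata (voxel sizes {tuple(zooms)}) in {path!r}"
        )
    img = nib.as_closest_canonical(img)  # -> RAS+
    sx, sy, sz = img.header.get_zooms()[:3]
    data = np.asanyarray(img.dataobj).astype(np.float32, copy=False)
    if data.ndim != 3:
        raise VolumeFormatError(f"expected a 3D volume, got {data.ndim}D in {path!r}")
    hu = _canonical_from_ras(data)
    return CTVolume(hu=hu, spacing_mm=(float(sz), float(sy), float(sx)),
                    affected_side=affected_side)
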