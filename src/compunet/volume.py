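"""Volumetric image container and NIfTI-1 I/O.

All volumes in this package share one convention: the data array is indexed
``(z, y, x)`` — axial slice index first — with per-axis voxel spacing in mm
and a world origin in mm, so that ``world = index * spacing + origin`` per
axis.  Intensities are Hounsfield units (HU) for CT-calibrated data, or an
uncalibrated scanner scale for raw cone-beam volumes before intensity
matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: HU window every calibrated volume is clipped to; values outside are
#: discarded during preparation.
HU_MIN = -1200.0
HU_MAX = 3071.0
#: Dynamic range of the clip window, used as the SSIM ``L`` and as the
#: normalisation span mapping HU into [0, 1] for the network.
HU_RANGE = HU_MAX - HU_MIN

MODALITIES = ("mdct", "cbct", "predicted")


@dataclass
class Volume:
    """A 3D scalar grid with spacing, origin and a modality tag.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Voxel values, stored as float32.
    spacing : tuple of 3 float
        Voxel size in mm per axis, ``(z, y, x)`` order, strictly positive.
    origin : tuple of 3 float
        World coordinate (mm) of voxel ``(0, 0, 0)``.
    modality : {"mdct", "cbct", "predicted"}
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "mdct"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "Volume":
        """Copy of this volume with new voxel data on the same grid."""
        return replace(self, data=np.asarray(data, dtype=np.float32),
                       modality=self.modality if modality is None else modality)

    def center_world(self) -> np.ndarray:
        """World coordinate (mm) of the grid centre."""
        shape = np.asarray(self.shape, dtype=float)
        return (shape - 1.0) / 2.0 * np.asarray(self.spacing) + np.asarray(self.origin)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)


def save_nifti(vol: Volume, path) -> None:
    """Write a volume as NIfTI-1, spacing in the header.

    The array is transposed to the NIfTI ``(x, y, z)`` axis order; the affine
    is diagonal with the per-axis spacing and the world origin.
    """
    sz, sy, sx = vol.spacing
    oz, oy, ox = vol.origin
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = [ox, oy, oz]
    img = nib.Nifti1Image(np.asarray(vol.data.T, dtype=np.float32), affine)
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = vol.modality.encode()
    nib.save(img, str(path))


def load_nifti(path, modality: str | None = None) -> Volume:
    """Read a NIfTI-1 volume written by :func:`save_nifti` (or compatible)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float32).T
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    t = img.affine[:3, 3]
    origin = (float(t[2]), float(t[1]), float(t[0]))
    if modality is None:
        tag = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="ignore")
        modality = tag if tag in MODALITIES else "mdct"
    return Volume(data=data, spacing=spacing, origin=origin, modality=modality)


def load_dicom_series(directory, modality: str = "cbct") -> Volume:
    """Read a single-frame DICOM series from a directory (basic loader).

    Slices are ordered by ImagePositionPatient along the slice normal
    (falling back to InstanceNumber) and rescaled with RescaleSlope /
    RescaleIntercept.  Gantry tilt and variable slice spacing are not
    handled.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue
    datasets = [d for d in datasets if hasattr(d, "PixelData")]
    if not datasets:
        raise ValueError(f"no DICOM images found in {directory}")

    def sort_key(d):
        pos = getattr(d, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return float(getattr(d, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slope = float(getattr(datasets[0], "RescaleSlope", 1.0))
    icpt = float(getattr(datasets[0], "RescaleIntercept", 0.0))
    data = np.stack([d.pixel_array.astype(np.float64) * slope + icpt
                     for d in datasets])
    py, px = (float(v) for v in getattr(datasets[0], "PixelSpacing",
                                        [1.0, 1.0]))
    if len(datasets) > 1:
        dz = abs(sort_key(datasets[1]) - sort_key(datasets[0])) or 1.0
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)
    return Volume(data.astype(np.float32), spacing=(dz, py, px),
                  modality=modality)


def normalize(data: np.ndarray) -> np.ndarray:
    """Map HU in [HU_MIN, HU_MAX] to [0, 1] (float64)."""
    return (np.asarray(data, dtype=np.float64) - HU_MIN) / HU_RANGE


def denormalize(data: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize`, back to float32 HU.

    Computed in float64 and cast to float32 so that
    ``denormalize(normalize(v)) == v`` bit-exactly for float32 inputs.
    """
    return (np.asarray(data, dtype=np.float64) * HU_RANGE + HU_MIN).astype(np.float32)
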