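"""Voxel volume containers and file I/O.

A :class:`VoxelVolume` is a 3D scalar grid of attenuation values on a
Hounsfield-like scale, together with the physical voxel spacing (micrometres,
isotropic 16 um by default, the resolution of a typical small-animal microCT
acquisition) and the physical coordinate of voxel ``(0, 0, 0)``.  A
:class:`BinaryMask` is the thresholded counterpart (1 = vessel foreground).

Supported on-disk formats: multi-page TIFF stacks (via :mod:`tifffile`),
NIfTI (via :mod:`nibabel`), and raw binary arrays described by a JSON
sidecar.  A DICOM series can be converted with :func:`load_dicom_series`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "load_volume",
    "save_volume",
    "load_dicom_series",
]


def _as_triple(value, name: str) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ConfigError(f"{name} must be a scalar or length-3 sequence, got {value!r}")
    return tuple(float(v) for v in arr)


@dataclass
class VoxelVolume:
    """3D attenuation grid with physical voxel spacing.

    Parameters
    ----------
    data
        3D scalar array (Hounsfield-like units).
    spacing
        Physical edge length of a voxel per axis, in micrometres.  A scalar
        is broadcast to all three axes.
    origin
        Physical coordinate (um) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (16.0, 16.0, 16.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DataError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 2:
            raise DataError(f"volume must span >= 2 voxels per axis, got shape {self.data.shape}")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ConfigError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel (um^3)."""
        return float(np.prod(self.spacing))

    def physical_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map integer voxel indices ``(n, 3)`` to physical um coordinates."""
        idx = np.asarray(indices, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class BinaryMask:
    """Boolean vessel mask sharing shape/spacing with its source volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (16.0, 16.0, 16.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise DataError(f"mask data must be 3D, got ndim={self.data.ndim}")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ConfigError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def physical_coordinates(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


def load_volume(path: str | Path, spacing=None, origin=None) -> VoxelVolume:
    """Load a volume from TIFF, NIfTI or raw+JSON.

    ``spacing``/``origin`` override whatever the file header declares; for
    TIFF and raw inputs without metadata they are required (spacing defaults
    to 16 um with a log message otherwise).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"volume file not found: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        data = tifffile.imread(path)
        if spacing is None:
            logger.info("TIFF input %s carries no spacing; assuming 16 um isotropic", path.name)
            spacing = 16.0
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if spacing is None:
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    elif suffixes.endswith(".json"):
        return _load_raw(path, spacing, origin)
    else:
        raise DataError(f"unsupported volume format: {path}")
    return VoxelVolume(data=data, spacing=spacing if spacing is not None else 16.0,
                       origin=origin if origin is not None else (0.0, 0.0, 0.0))


def _load_raw(meta_path: Path, spacing, origin) -> VoxelVolume:
    try:
        meta = json.loads(meta_path.read_text())
        shape = tuple(meta["shape"])
        dtype = np.dtype(meta["dtype"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise DataError(f"invalid raw-volume metadata {meta_path}: {exc}") from exc
    raw_path = meta_path.with_suffix(".raw") if "raw_file" not in meta \
        else meta_path.parent / meta["raw_file"]
    if not raw_path.exists():
        raise DataError(f"raw data file not found: {raw_path}")
    data = np.fromfile(raw_path, dtype=dtype).reshape(shape)
    if spacing is None:
        spacing = meta.get("spacing", 16.0)
    if origin is None:
        origin = meta.get("origin", (0.0, 0.0, 0.0))
    return VoxelVolume(data=data, spacing=spacing, origin=origin)


def save_volume(vol: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as TIFF, NIfTI, or raw+JSON (chosen by extension)."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, np.asarray(vol.data))
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(np.asarray(vol.data), affine), str(path))
    elif suffixes.endswith(".json"):
        raw_path = path.with_suffix(".raw")
        np.asarray(vol.data).tofile(raw_path)
        meta = {
            "shape": list(vol.data.shape),
            "dtype": str(vol.data.dtype),
            "spacing": list(vol.spacing),
            "origin": list(vol.origin),
            "raw_file": raw_path.name,
        }
        path.write_text(json.dumps(meta, indent=2))
    else:
        raise DataError(f"unsupported volume format: {path}")
    return path


def load_dicom_series(directory: str | Path, spacing=None) -> VoxelVolume:
    """Convert a directory of single-frame DICOM files into a volume.

    Slices are ordered by ``InstanceNumber`` (falling back to filename).
    Spacing is taken from ``PixelSpacing``/``SliceThickness`` in mm and
    converted to micrometres unless overridden.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise DataError(f"no DICOM files in {directory}")
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception as exc:  # unreadable stray file
            logger.warning("skipping unreadable DICOM candidate %s: %s", p.name, exc)
    if not datasets:
        raise DataError(f"no readable DICOM files in {directory}")
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    stack = np.stack([d.pixel_array for d in datasets])
    if spacing is None:
        d0 = datasets[0]
        try:
            px = [float(v) for v in d0.PixelSpacing]
            dz = float(getattr(d0, "SliceThickness", px[0]))
            spacing = (dz * 1000.0, px[0] * 1000.0, px[1] * 1000.0)  # mm -> um
        except Exception:
            logger.info("DICOM series lacks spacing tags; assuming 16 um isotropic")
            spacing = 16.0
    return VoxelVolume(data=stack, spacing=spacing)
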