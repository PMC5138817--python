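"""Image volumes, ROI masks and feature tables: in-memory containers and file IO.

Conventions
-----------
Voxel arrays are indexed ``(slice, row, column)`` (z, y, x), 0-based.
``spacing`` and ``origin`` follow the same axis order, in millimetres.
NIfTI/NRRD reading and writing is delegated to SimpleITK; SimpleITK's
(x, y, z) spacing/origin are reversed on the way in and out so that a single
convention holds throughout the package.

Readers never resample: a mask whose geometry does not match its volume is
rejected with an error naming both geometries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "ROIMask",
    "FeatureTable",
    "GeometryError",
    "read_volume",
    "read_mask",
    "read_dicom_series",
    "write_volume",
    "write_mask",
]


class GeometryError(ValueError):
    """Raised when two spatial objects disagree in shape or spacing."""


def _as_tuple3(x, name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(x))
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D intensity grid (HU-like) with physical voxel spacing.

    Parameters
    ----------
    intensities : ndarray, shape (nz, ny, nx)
        Voxel intensities; must be finite.
    spacing : tuple of float
        Voxel size in mm per axis, (slice, row, column) order.
    origin : tuple of float
        World coordinate of voxel (0, 0, 0) in mm.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be 3D, got shape {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        self.spacing = _as_tuple3(self.spacing, "spacing")
        self.origin = _as_tuple3(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass
class ROIMask:
    """A binary tumor mask sharing its volume's grid geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.voxels.shape}")
        self.spacing = _as_tuple3(self.spacing, "spacing")
        self.origin = _as_tuple3(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def check_matches(self, volume: ImageVolume) -> None:
        """Raise GeometryError unless geometry matches `volume` exactly."""
        if self.shape != volume.shape or not np.allclose(
            self.spacing, volume.spacing
        ):
            raise GeometryError(
                "mask geometry does not match volume geometry: "
                f"mask shape={self.shape} spacing={self.spacing}; "
                f"volume shape={volume.shape} spacing={volume.spacing}"
            )


@dataclass
class FeatureTable:
    """Patients x named descriptors.

    Thin wrapper over a pandas DataFrame (index = patient ids, columns =
    canonical feature names). NaN marks a missing (undefined) feature value;
    every non-missing value must be finite.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data.index.name = "id"
        if not self.data.index.is_unique:
            raise ValueError("patient ids must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("feature names must be unique")
        vals = self.data.to_numpy(dtype=float, copy=False)
        if vals.size and np.any(np.isinf(vals)):
            raise ValueError("feature values must be finite or NaN")

    @classmethod
    def from_rows(cls, rows: dict[str, dict[str, float]]) -> "FeatureTable":
        return cls(pd.DataFrame.from_dict(rows, orient="index"))

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.data.to_csv(path, index_label="id")

    @classmethod
    def read_csv(cls, path: str | os.PathLike) -> "FeatureTable":
        return cls(pd.read_csv(path, index_col="id"))


# ---------------------------------------------------------------------------
# File IO (SimpleITK backend)
# ---------------------------------------------------------------------------

def _to_sitk(arr: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(tuple(reversed(spacing)))
    img.SetOrigin(tuple(reversed(origin)))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return arr, spacing, origin


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or NRRD (.nrrd), by extension."""
    sitk.WriteImage(_to_sitk(volume.intensities, volume.spacing, volume.origin),
                    os.fspath(path))


def write_mask(mask: ROIMask, path: str | os.PathLike) -> None:
    sitk.WriteImage(
        _to_sitk(mask.voxels.astype(np.uint8), mask.spacing, mask.origin),
        os.fspath(path),
    )


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI or NRRD volume; spacing and origin are honored."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:  # SimpleITK wraps unreadable files
        raise ValueError(f"unreadable image file {path!r}: {exc}") from exc
    arr, spacing, origin = _from_sitk(img)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D image, got {arr.ndim}D in {path!r}")
    return ImageVolume(arr.astype(np.float64), spacing, origin)


def read_mask(path: str | os.PathLike, volume: ImageVolume) -> ROIMask:
    """Read a binary mask and verify it shares `volume`'s geometry.

    Resampling is deliberately refused: a geometry mismatch raises
    GeometryError naming both geometries.
    """
    vol = read_volume(path)
    mask = ROIMask(vol.intensities > 0.5, vol.spacing, vol.origin)
    mask.check_matches(volume)
    return mask


def read_dicom_series(directory: str | os.PathLike) -> ImageVolume:
    """Optional DICOM-series read (a directory of .dcm slices)."""
    directory = os.fspath(directory)
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(directory)
    if not files:
        raise ValueError(f"no DICOM series found in {directory!r}")
    reader.SetFileNames(files)
    arr, spacing, origin = _from_sitk(reader.Execute())
    return ImageVolume(arr.astype(np.float64), spacing, origin)
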