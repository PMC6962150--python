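"""Domain types shared by every pipeline stage, plus file I/O.

The in-memory containers are deliberately thin: an :class:`ImageVolume` is a
3D scalar grid with physical voxel spacing, a :class:`BinaryMask` is a boolean
grid on the same lattice, a :class:`LesionCase` bundles one lesion's image,
ground truth and per-rater contours, and a :class:`FeatureTable` is a long
pandas frame of (lesion, source, gray-levels, feature, value) records.

Coordinate convention: arrays are indexed ``[i, j, k] == [x, y, z]`` with the
x index fastest-varying, spacing is ``(sx, sy, sz)`` in millimetres and the
origin is in millimetres.  Surface distances elsewhere in the package are
reported in voxel units; multiply by the spacing for millimetres.

Volumes and masks are serialized through SimpleITK, so any format it knows
(NIfTI ``.nii``/``.nii.gz`` and NRRD ``.nrrd`` are the supported ones) works.
Masks are stored as unsigned 8-bit 0/1 volumes; any nonzero voxel is
foreground on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "FormatError",
    "GridMismatchError",
    "EmptyMaskError",
    "ConfigurationError",
    "SimulationError",
    "ImageVolume",
    "BinaryMask",
    "LesionCase",
    "FeatureTable",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "grid_compatible",
]

SPACING_RTOL = 1e-3  # relative tolerance when comparing voxel spacings


class FormatError(ValueError):
    """A file is unreadable or not a 3D scalar image / well-formed table."""


class GridMismatchError(ValueError):
    """Two objects do not live on the same voxel lattice."""


class EmptyMaskError(ValueError):
    """An operation that needs foreground voxels received an empty mask."""


class ConfigurationError(ValueError):
    """User-supplied parameters are inconsistent or unreachable."""


class SimulationError(RuntimeError):
    """The synthetic generator failed to produce a valid object."""


def _as_triple(t) -> tuple[float, float, float]:
    out = tuple(float(x) for x in t)
    if len(out) != 3:
        raise ValueError(f"expected 3 components, got {len(out)}")
    return out  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data
        3D float array of intensities (arbitrary activity units).
    spacing
        Voxel size ``(sx, sy, sz)`` in mm; all components positive.
    origin
        Physical coordinate of voxel ``(0, 0, 0)`` in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("volume intensities must be finite")
        self.spacing = _as_triple(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_triple(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm³ (spacing product / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class BinaryMask:
    """A boolean VOI on the same lattice as its companion volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing = _as_triple(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_triple(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def volume_cm3(self) -> float:
        """Foreground volume: voxel count × voxel volume."""
        return self.n_voxels * self.voxel_volume_cm3


def grid_compatible(a: ImageVolume | BinaryMask, b: ImageVolume | BinaryMask) -> bool:
    """Whether two grids share shape and spacing (spacing to relative tol)."""
    return a.shape == b.shape and np.allclose(
        a.spacing, b.spacing, rtol=SPACING_RTOL, atol=0.0
    )


def require_compatible(a, b, what: str = "mask") -> None:
    if not grid_compatible(a, b):
        raise GridMismatchError(
            f"{what} grid {a.shape} @ {a.spacing} mm incompatible with "
            f"reference {b.shape} @ {b.spacing} mm"
        )


@dataclass
class LesionCase:
    """One lesion: simulated image, exact ground truth, per-rater contours."""

    lesion_id: str
    image: ImageVolume
    ground_truth: BinaryMask
    rater_masks: dict[str, BinaryMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        require_compatible(self.ground_truth, self.image, "ground-truth mask")
        for rid, m in self.rater_masks.items():
            require_compatible(m, self.image, f"rater '{rid}' mask")


# ---------------------------------------------------------------------------
# Image / mask serialization


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI/NRRD image into an :class:`ImageVolume`.

    Raises :class:`FormatError` if the file cannot be read or is not 3D.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps all reader failures
        raise FormatError(f"unreadable image {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected 3D image, got {img.GetDimension()}D")
    # SimpleITK arrays come back [z, y, x]; transpose to our [x, y, z].
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(data, spacing=img.GetSpacing(), origin=img.GetOrigin())


def write_volume(v: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` (float) to NIfTI/NRRD; overwrites."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
    img.SetSpacing(v.spacing)
    img.SetOrigin(v.origin)
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path, reference: ImageVolume) -> BinaryMask:
    """Read a mask and check it against ``reference``'s lattice.

    Nonzero voxels become foreground.  Raises :class:`GridMismatchError`
    (naming both shapes) if shape or spacing differ from the reference.
    """
    raw = read_volume(path)
    mask = BinaryMask(raw.data != 0, spacing=raw.spacing, origin=raw.origin)
    require_compatible(mask, reference, f"mask {path}")
    return mask


def write_mask(m: BinaryMask, path: str | Path) -> None:
    """Write a mask as an unsigned 8-bit 0/1 volume."""
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(m.data.transpose(2, 1, 0).astype(np.uint8))
    )
    img.SetSpacing(m.spacing)
    img.SetOrigin(m.origin)
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Feature table

FEATURE_TABLE_COLUMNS = ["lesion_id", "source", "gray_levels", "feature", "value"]
GROUND_TRUTH_SOURCE = "ground_truth"


@dataclass
class FeatureTable:
    """Long-format radiomics feature records.

    One row per (lesion, contour source, gray-level count, feature name);
    ``source`` is either ``"ground_truth"`` or a rater id.  The key must be
    unique across rows.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"feature table missing column(s): {missing}")
        self.df = self.df[FEATURE_TABLE_COLUMNS].copy()
        self.df["gray_levels"] = self.df["gray_levels"].astype(int)
        self.df["value"] = self.df["value"].astype(float)
        key = ["lesion_id", "source", "gray_levels", "feature"]
        dup = self.df.duplicated(subset=key)
        if dup.any():
            first = self.df.loc[dup, key].iloc[0].tolist()
            raise FormatError(f"duplicate feature record, e.g. {first}")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records) -> "FeatureTable":
        return cls(pd.DataFrame(list(records), columns=FEATURE_TABLE_COLUMNS))

    @classmethod
    def concat(cls, tables: list["FeatureTable"]) -> "FeatureTable":
        return cls(pd.concat([t.df for t in tables], ignore_index=True))

    def write_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        return cls(pd.read_csv(path))
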