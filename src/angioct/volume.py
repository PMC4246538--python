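"""Volume container and file IO.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)``, 0-based;
* a voxel's physical position is its *center*, at ``index * spacing`` μm
  relative to the volume origin;
* voxel spacing is isotropic and expressed in micrometres.  Anisotropic
  files are rejected rather than silently resampled, because every
  downstream measurement (distance transforms, Hessian scales, surface
  areas) assumes isotropy.

Supported formats: MetaImage (``.mha``/``.mhd``), NIfTI (``.nii``/
``.nii.gz``) through SimpleITK, and multipage TIFF stacks through
tifffile.  TIFF carries no reliable spacing metadata, so a spacing must
be supplied explicitly when reading TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile

__all__ = ["ScalarVolume", "read_volume", "write_volume", "read_mask", "write_mask"]

_SITK_SUFFIXES = {".mha", ".mhd", ".nii"}
_ISO_RTOL = 1e-3


@dataclass
class ScalarVolume:
    """A 3D intensity grid with isotropic voxel spacing.

    Parameters
    ----------
    data:
        ``(z, y, x)`` array of intensities (arbitrary CT units).
    spacing:
        Isotropic voxel edge length in μm.
    origin:
        Physical position of voxel ``(0, 0, 0)`` in μm, ``(z, y, x)``.
    """

    data: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = tuple(float(c) for c in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.spacing * 1e-3) ** 3

    def voxel_centers_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinate vectors in μm."""
        return tuple(
            self.origin[i] + np.arange(self.shape[i]) * self.spacing for i in range(3)
        )


def _suffix(path: Path) -> str:
    if path.name.endswith(".nii.gz"):
        return ".nii"
    return path.suffix.lower()


def _check_isotropic(spacing_zyx: np.ndarray, path: Path) -> float:
    s = np.asarray(spacing_zyx, dtype=float)
    if not np.allclose(s, s[0], rtol=_ISO_RTOL):
        raise ValueError(
            f"{path}: anisotropic voxel spacing {tuple(s)} is not supported; "
            "the framework assumes an isotropic voxel size"
        )
    return float(s[0])


def read_volume(path: str | Path, spacing: float | None = None) -> ScalarVolume:
    """Read a volume from MetaImage, NIfTI or a multipage TIFF stack.

    ``spacing`` (μm) is required for TIFF, which has no trustworthy
    spacing header; for the other formats it is read from the file and
    may not be overridden.
    """
    path = Path(path)
    suffix = _suffix(path)
    if suffix in (".tif", ".tiff"):
        if spacing is None:
            raise ValueError(
                f"{path}: TIFF stacks carry no voxel spacing; pass spacing explicitly"
            )
        data = np.asarray(tifffile.imread(path))
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3D TIFF stack, got shape {data.shape}")
        return ScalarVolume(data, float(spacing))
    if suffix in _SITK_SUFFIXES:
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        sp = _check_isotropic(np.asarray(img.GetSpacing())[::-1], path)
        origin = tuple(np.asarray(img.GetOrigin())[::-1])
        return ScalarVolume(data, sp, origin)
    raise ValueError(f"{path}: unsupported volume format '{suffix}'")


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Write a volume; format chosen from the file suffix."""
    path = Path(path)
    suffix = _suffix(path)
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(vol.data))
        return
    if suffix in _SITK_SUFFIXES:
        img = sitk.GetImageFromArray(np.asarray(vol.data))
        img.SetSpacing(tuple(float(vol.spacing) for _ in range(3)))
        img.SetOrigin(tuple(float(c) for c in vol.origin[::-1]))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"{path}: unsupported volume format '{suffix}'")


def write_mask(mask: np.ndarray, spacing: float, path: str | Path,
               origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> None:
    """Write a binary mask as an 8-bit {0, 255} volume."""
    data = np.where(np.asarray(mask, dtype=bool), np.uint8(255), np.uint8(0))
    write_volume(ScalarVolume(data, spacing, origin), path)


def read_mask(path: str | Path, spacing: float | None = None) -> tuple[np.ndarray, float]:
    """Read a binary mask; returns ``(bool array, spacing μm)``.

    Any nonzero voxel is foreground.
    """
    vol = read_volume(path, spacing=spacing)
    return np.asarray(vol.data) != 0, vol.spacing
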