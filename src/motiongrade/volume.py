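"""Reading, writing and canonicalizing 3D CT volumes.

Every downstream module consumes the :class:`Volume` container: a float
array indexed as (axial slice, row, column) with voxel spacing in µm.
NIfTI-1 (via nibabel) and multi-page TIFF (via tifffile) are supported on
disk; NIfTI stores spacing in mm, TIFF carries no spacing, so missing
metadata falls back to the 60.7 µm isotropic voxels of second-generation
HR-pQCT with a warning.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DEFAULT_SPACING_UM",
    "Volume",
    "StackSpec",
    "read_volume",
    "write_volume",
    "normalize_intensity",
    "split_into_stacks",
]

#: HR-pQCT (XtremeCT II) isotropic voxel size in µm, used when a file
#: carries no spacing metadata.
DEFAULT_SPACING_UM = 60.7

_NIFTI_EXT = (".nii", ".nii.gz")
_TIFF_EXT = (".tif", ".tiff")


@dataclass
class Volume:
    """A 3D scalar intensity grid.

    Attributes
    ----------
    data:
        Float array indexed as (axial slice, row, column).
    spacing:
        Per-axis voxel size in µm, same axis order as ``data``.
    meta:
        Free-form provenance strings (source path, format, seed lineage).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (
        DEFAULT_SPACING_UM,
        DEFAULT_SPACING_UM,
        DEFAULT_SPACING_UM,
    )
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite (no NaN/Inf)")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, dict(self.meta))


@dataclass(frozen=True)
class StackSpec:
    """How to partition a scan into axial acquisition stacks.

    The scanner acquires contiguous blocks of 168 slices (10.2 mm at
    60.7 µm); a scaphoid needs three to four such stacks.
    """

    slices_per_stack: int = 168
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.slices_per_stack < 1:
            raise ValueError("slices_per_stack must be >= 1")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")
        if self.overlap >= self.slices_per_stack:
            raise ValueError("overlap must be smaller than slices_per_stack")


def _infer_format(path: str, format_hint: str | None) -> str:
    if format_hint is not None:
        if format_hint not in ("nifti", "tiff_stack"):
            raise ValueError(
                f"unsupported format {format_hint!r}; supported: nifti, tiff_stack"
            )
        return format_hint
    lower = path.lower()
    if lower.endswith(_NIFTI_EXT):
        return "nifti"
    if lower.endswith(_TIFF_EXT):
        return "tiff_stack"
    raise ValueError(
        f"cannot infer format of {path!r}; supported extensions: "
        f"{_NIFTI_EXT + _TIFF_EXT} (or pass format_hint)"
    )


def read_volume(path: str, format_hint: str | None = None) -> Volume:
    """Read a NIfTI or multi-page TIFF volume into canonical axis order.

    NIfTI data (x, y, z with z = slice direction) is transposed to
    (slice, row, column); its header spacing is converted from mm to µm.
    TIFF pages are already one axial slice each.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    fmt = _infer_format(path, format_hint)
    try:
        if fmt == "nifti":
            import nibabel as nib

            img = nib.load(path)
            data = np.asanyarray(img.dataobj).astype(np.float32)
            if data.ndim != 3:
                raise ValueError(f"expected a 3D NIfTI, got ndim={data.ndim}: {path}")
            # NIfTI is (x, y, z); canonical order is (z=slice, y=row, x=col).
            data = np.transpose(data, (2, 1, 0))
            zooms = img.header.get_zooms()[:3]
            if all(z > 0 for z in zooms):
                spacing = (zooms[2] * 1000.0, zooms[1] * 1000.0, zooms[0] * 1000.0)
            else:
                warnings.warn(
                    f"{path}: no voxel spacing in header; "
                    f"assuming {DEFAULT_SPACING_UM} µm isotropic",
                    stacklevel=2,
                )
                spacing = (DEFAULT_SPACING_UM,) * 3
        else:
            import tifffile

            data = tifffile.imread(path).astype(np.float32)
            if data.ndim == 2:
                data = data[None]
            if data.ndim != 3:
                raise ValueError(f"expected a TIFF stack, got ndim={data.ndim}: {path}")
            warnings.warn(
                f"{path}: TIFF carries no voxel spacing; "
                f"assuming {DEFAULT_SPACING_UM} µm isotropic",
                stacklevel=2,
            )
            spacing = (DEFAULT_SPACING_UM,) * 3
    except (ValueError, FileNotFoundError):
        raise
    except Exception as exc:  # corrupt/unreadable file
        raise OSError(f"failed to read volume {path!r}: {exc}") from exc
    return Volume(data, spacing, meta={"source": path, "format": fmt})


def write_volume(volume: Volume, path: str, format: str | None = None) -> None:
    """Write a volume to NIfTI or TIFF; round-trips losslessly at float32."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"directory does not exist: {parent}")
    fmt = _infer_format(path, format)
    data = volume.data.astype(np.float32)
    if fmt == "nifti":
        import nibabel as nib

        # canonical (slice, row, col) back to NIfTI (x=col, y=row, z=slice)
        arr = np.transpose(data, (2, 1, 0))
        affine = np.diag(
            [volume.spacing[2] / 1000.0, volume.spacing[1] / 1000.0,
             volume.spacing[0] / 1000.0, 1.0]
        )
        img = nib.Nifti1Image(arr, affine)
        img.header.set_zooms(
            (volume.spacing[2] / 1000.0, volume.spacing[1] / 1000.0,
             volume.spacing[0] / 1000.0)
        )
        nib.save(img, path)
    else:
        import tifffile

        tifffile.imwrite(path, data)


def normalize_intensity(
    volume: Volume, low_pct: float = 0.5, high_pct: float = 99.5
) -> Volume:
    """Percentile-clip then rescale intensities to [0, 1].

    Values are clipped to [P_low, P_high] of the input and mapped affinely
    onto [0, 1]. A constant volume (degenerate percentile range) maps to
    all zeros rather than dividing by zero.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(f"need 0 <= low_pct < high_pct <= 100, got ({low_pct}, {high_pct})")
    data = volume.data
    lo, hi = np.percentile(data, [low_pct, high_pct])
    if hi <= lo:
        out = np.zeros_like(data, dtype=np.float32)
    else:
        out = (np.clip(data, lo, hi) - lo) / (hi - lo)
        out = out.astype(np.float32)
    return replace(volume.copy(), data=out)


def split_into_stacks(volume: Volume, spec: StackSpec = StackSpec()) -> list[Volume]:
    """Partition a scan into consecutive axial stacks.

    With ``overlap=0`` (default) the blocks are disjoint, the last stack
    may be shorter, and concatenating the outputs along the axial axis
    reproduces the input exactly.
    """
    n = volume.shape[0]
    step = spec.slices_per_stack - spec.overlap
    stacks: list[Volume] = []
    start = 0
    idx = 0
    while start < n:
        block = volume.data[start : start + spec.slices_per_stack]
        meta = dict(volume.meta)
        meta["stack_index"] = str(idx)
        stacks.append(Volume(block.copy(), volume.spacing, meta))
        if start + spec.slices_per_stack >= n:
            break
        start += step
        idx += 1
    return stacks
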