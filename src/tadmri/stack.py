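"""Image containers, signal normalization, SNR and file I/O.

Conventions: arrays are indexed (z, y, x) with 0-based indices; a 4D stack
is (z, y, x, volume); voxel size is carried in mm; microscopy pixel size
in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .protocol import AcquisitionProtocol


class StackValidationError(ValueError):
    pass


@dataclass
class DWIStack:
    """A 4D diffusion-weighted series bound to its acquisition protocol."""

    data: np.ndarray                  # (z, y, x, n_volumes)
    voxel_size: tuple                 # mm per axis (z, y, x)
    protocol: AcquisitionProtocol
    mask: np.ndarray = None           # (z, y, x) boolean validity volume

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise StackValidationError("stack data must be 4D (z, y, x, volume)")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise StackValidationError("mask shape does not match spatial shape")
        n_expected = self.protocol.n_volumes
        if self.data.shape[-1] != n_expected:
            raise StackValidationError(
                f"stack has {self.data.shape[-1]} volumes but the protocol "
                f"lists {n_expected}"
            )
        bad = ~np.isfinite(self.data) | (self.data < 0)
        if bad.any():
            idx = sorted(set(np.argwhere(bad)[:, -1].tolist()))
            raise StackValidationError(
                f"non-finite or negative intensities in volumes {idx}"
            )

    @property
    def index(self):
        """Per-volume acquisition table (direction, Delta, g, b, RG)."""
        return self.protocol.volumes()


@dataclass
class ParametricMap:
    """A named scalar map (e.g. Mgamma, MD, R2*) with units and a mask."""

    name: str
    units: str
    values: np.ndarray
    mask: np.ndarray = None
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.isfinite(self.values[self.mask]).all():
            raise StackValidationError(
                f"map {self.name!r} has non-finite values inside its mask"
            )


def normalize_attenuation(stack: DWIStack, background_roi=None, s0_index: int = 0):
    """Background-subtract, receiver-gain-correct and S0-normalize a stack.

    Each volume k has the mean background intensity subtracted, is scaled by
    RG0/RGk (receiver gains from the protocol), then divided voxel-wise by
    the corrected S0 volume.  Voxels where the corrected S0 is not positive
    are flagged invalid in the returned mask rather than raising.

    Returns
    -------
    (normalized, valid_mask) : 4D array in ~[0, 1+noise], 3D boolean mask
    """
    data = stack.data.astype(float).copy()
    n_vol = data.shape[-1]
    rg = stack.index["rg"].to_numpy()
    if background_roi is not None:
        background_roi = np.asarray(background_roi, dtype=bool)
        if not background_roi.any():
            raise ValueError("background ROI is empty")
        bg = data[background_roi].mean(axis=0)  # per volume
        data -= bg[None, None, None, :]
    data *= (rg[0] / rg)[None, None, None, :]
    s0 = data[..., s0_index]
    valid = stack.mask & (s0 > 0)
    out = np.zeros_like(data)
    out[valid] = data[valid] / s0[valid, None]
    return out, valid


def roi_snr(image, roi, background) -> float:
    """SNR as ROI mean over background standard deviation."""
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    background = np.asarray(background, dtype=bool)
    if not roi.any() or not background.any():
        raise ValueError("ROI and background masks must both be non-empty")
    if (roi & background).any():
        raise ValueError("ROI and background masks overlap")
    sd = image[background].std()
    if sd == 0:
        raise ZeroDivisionError(
            "background standard deviation is zero; SNR is undefined"
        )
    return float(image[roi].mean() / sd)


# ---------------------------------------------------------------------------
# File I/O: NIfTI-1 for stacks and maps, TIFF/PNG for microscopy.
# ---------------------------------------------------------------------------

def _affine(voxel_size):
    # (z, y, x) voxel sizes onto a diagonal RAS affine
    vz, vy, vx = voxel_size
    return np.diag([vx, vy, vz, 1.0])


def write_dwi_series(stack: DWIStack, path, protocol_path=None) -> None:
    img = nib.Nifti1Image(np.asarray(stack.data, dtype=np.float32), _affine(stack.voxel_size))
    nib.save(img, str(path))
    if protocol_path is not None:
        stack.protocol.save(protocol_path)


def read_dwi_series(path, protocol_path) -> DWIStack:
    """Load a 4D NIfTI and its protocol file; validate them against each other."""
    img = nib.load(str(path))
    protocol = AcquisitionProtocol.load(protocol_path)
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    voxel_size = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return DWIStack(data=data, voxel_size=voxel_size, protocol=protocol)


def write_map(pmap: ParametricMap, path, voxel_size=(1.0, 1.0, 1.0)) -> None:
    values = np.asarray(pmap.values, dtype=np.float32)
    if values.ndim == 2:
        values = values[None]
    img = nib.Nifti1Image(values, _affine(voxel_size))
    img.header["descrip"] = f"{pmap.name} [{pmap.units}]".encode()[:80]
    nib.save(img, str(path))


def read_map(path, name: str = "", units: str = "") -> ParametricMap:
    img = nib.load(str(path))
    return ParametricMap(name=name, units=units, values=np.asarray(img.dataobj, float))


def read_microscopy(path, pixel_size_um: float = 0.033):
    """Read a 2D microscopy image (TIFF/PNG); returns (image, pixel size in um)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        image = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        image = iio.imread(str(path))
    image = np.asarray(image)
    if image.ndim == 3:  # collapse RGB
        image = image[..., :3].mean(axis=-1)
    return image.astype(float), float(pixel_size_um)


def write_microscopy(image, path) -> None:
    path = Path(path)
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), arr)
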