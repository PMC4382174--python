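"""Focus-stack container and TIFF I/O.

A focus stack is a 3D bright-field volume (z, y, x) covering both hair-bearing
surfaces of a Drosophila wing.  Axes are stored in (z, y, x) order, matching
the on-disk page layout of multi-page TIFF; physical voxel sizes are carried
alongside so that all downstream geometry is done in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile


@dataclass
class FocusStack:
    """3D intensity volume with physical voxel sizes.

    Parameters
    ----------
    data : ndarray, shape (z, y, x)
        Intensity volume (float32 or any numeric dtype).
    voxel_size_um : tuple of float
        Physical voxel size ``(z, y, x)`` in micrometres.
    background_mean, background_sd : float, optional
        Robust background statistics; filled in by
        :func:`wingspot.segmentation.estimate_background`.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    background_mean: float | None = None
    background_sd: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got ndim={self.data.ndim}")
        if self.data.shape[0] < 2:
            raise ValueError("stack needs at least 2 z-slices")
        vz, vy, vx = self.voxel_size_um
        if not (vz > 0 and vy > 0 and vx > 0):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size_um}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) in micrometres."""
        return tuple(n * v for n, v in zip(self.data.shape, self.voxel_size_um))


def write_stack(path, stack: FocusStack) -> None:
    """Write a stack as multi-page TIFF with voxel sizes in ImageJ metadata."""
    vz, vy, vx = stack.voxel_size_um
    data = stack.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / vx, 1.0 / vy),
        metadata={"spacing": vz, "unit": "um", "axes": "ZYX"},
    )


def read_stack(path) -> FocusStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        vz = 1.0
        vx = vy = 1.0
        if tif.imagej_metadata is not None:
            vz = float(tif.imagej_metadata.get("spacing", 1.0))
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        if res is not None:
            num, den = res.value
            if num:
                vx = den / num
        res = page.tags.get("YResolution")
        if res is not None:
            num, den = res.value
            if num:
                vy = den / num
    return FocusStack(data=data, voxel_size_um=(vz, vy, vx))
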