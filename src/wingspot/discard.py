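"""Discard mask: exclude veins, wing borders, and off-wing background.

Wing veins carry hairs whose density and morphology differ from the open
wing blade, and regions outside the wing contain no analyzable hairs at
all.  Both are excluded through a 2D structure-density analysis of the
stack's maxima projection: medium density marks analyzable blade, high
density marks veins, low density marks off-wing background.  A third rule
flags extended high-intensity structures (vein bands) on a locally
normalized projection.  Any segmented hair whose x-y footprint touches the
discard mask by at least one pixel is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DiscardParams",
    "DiscardMask",
    "maxima_projection",
    "structure_density",
    "build_discard_mask",
    "apply_discard",
]

# provenance codes
LOW_DENSITY = 1
HIGH_DENSITY = 2
HIGH_INTENSITY = 3


@dataclass
class DiscardParams:
    """Density thresholds are fractions of smoothed structure coverage."""

    density_sigma_um: float = 25.0     # 2 x inter-hair distance
    low_threshold: float = 0.15
    high_threshold: float = 0.55
    intensity_threshold: float = 0.60  # on the smoothed, locally normalized projection
    tile_px: int = 128                 # local normalization window


@dataclass
class DiscardMask:
    """2D exclusion mask aligned to the stack's x-y grid.

    ``provenance`` holds, per discarded pixel, which rule fired
    (1 = low density, 2 = high density, 3 = high-intensity structure).
    """

    mask: np.ndarray          # bool (y, x)
    provenance: np.ndarray    # uint8 (y, x)

    @property
    def discard_fraction(self) -> float:
        return float(self.mask.mean())


def maxima_projection(volume: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along z: out(y, x) = max_z volume."""
    volume = np.asarray(volume)
    if volume.size == 0:
        raise ValueError("empty stack")
    return volume.max(axis=0)


def structure_density(
    projection: np.ndarray,
    mask_threshold: float,
    sigma_um: float,
    voxel_xy_um: float,
) -> np.ndarray:
    """Local structure coverage fraction in [0, 1].

    Thresholds the projection into a structure mask and smooths it with a
    Gaussian of ``sigma_um`` (default 2 x the inter-hair distance), yielding
    the local fraction of area covered by structures.
    """
    if sigma_um <= 0:
        raise ValueError("density sigma must be > 0")
    structure = (projection > mask_threshold).astype(np.float64)
    if not structure.any():
        return np.zeros_like(structure)
    sigma_px = sigma_um / voxel_xy_um
    return ndimage.gaussian_filter(structure, sigma=sigma_px, mode="nearest")


def _local_normalize(projection: np.ndarray, tile_px: int) -> np.ndarray:
    """Per-tile min-max stretch to correct local heterogeneity."""
    lo = ndimage.minimum_filter(projection, size=tile_px, mode="nearest")
    hi = ndimage.maximum_filter(projection, size=tile_px, mode="nearest")
    rng = hi - lo
    rng[rng <= 0] = 1.0
    return (projection - lo) / rng


def build_discard_mask(
    density: np.ndarray,
    projection: np.ndarray,
    voxel_xy_um: float,
    params: DiscardParams | None = None,
) -> DiscardMask:
    """Combine the three discard rules into one mask with provenance.

    A pixel is discarded iff its structure density is below the low
    threshold, above the high threshold, or the smoothed locally-normalized
    projection exceeds the intensity threshold.
    """
    p = params or DiscardParams()
    for thr in (p.low_threshold, p.high_threshold, p.intensity_threshold):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    if p.low_threshold >= p.high_threshold:
        raise ValueError("low threshold must be below high threshold")
    prov = np.zeros(density.shape, dtype=np.uint8)
    low = density < p.low_threshold
    high = density > p.high_threshold
    norm = _local_normalize(np.asarray(projection, dtype=np.float64), p.tile_px)
    norm_smooth = ndimage.gaussian_filter(
        norm, sigma=p.density_sigma_um / voxel_xy_um, mode="nearest"
    )
    bright = norm_smooth > p.intensity_threshold
    prov[bright] = HIGH_INTENSITY
    prov[high] = HIGH_DENSITY
    prov[low] = LOW_DENSITY
    return DiscardMask(mask=prov > 0, provenance=prov)


def apply_discard(hairs, mask: DiscardMask, labels: np.ndarray):
    """Flag hairs whose region footprint has >= 1 pixel in the discard mask.

    ``hairs`` is a list of HairVector; ``labels`` the watershed label volume
    aligned with the mask's x-y grid.  Returns the same list with
    ``discarded``/``discard_reason`` set (monotone: growing the mask never
    un-flags a hair).
    """
    if labels.shape[1:] != mask.mask.shape:
        raise ValueError("label volume and mask x-y shapes differ")
    if mask.mask.any():
        hit = np.unique(labels[:, mask.mask])
        hit = set(int(v) for v in hit if v != 0)
    else:
        hit = set()
    for hv in hairs:
        if hv.label in hit and not hv.discarded:
            hv.discarded = True
            hv.discard_reason = "discard-mask"
    return hairs
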