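"""Hair segmentation in wing focus stacks.

The pipeline is: per-slice top-hat filtering to remove the slowly varying
out-of-focus background, 3D Gaussian smoothing, h-maxima seed detection
(local maxima with topographic prominence of at least h), and a seeded
watershed that floods from the seeds in decreasing intensity order until a
stop level (background mean + 2 SD by default).  Each labeled region is then
reduced to a hair vector: root at the region's intensity maximum, direction
and length from the region's position covariance computed in physical
(micrometre) coordinates so that the 0.32--0.64 um planar versus 1 um axial
voxel anisotropy does not bias orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk, reconstruction, white_tophat

from .stack import FocusStack

__all__ = [
    "SegmentationParams",
    "HairVector",
    "preprocess_stack",
    "estimate_background",
    "resolve_h",
    "find_h_maxima",
    "watershed_segment",
    "characterize_hair",
    "segment_stack",
    "hairs_to_frame",
]

_FULL_3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass
class SegmentationParams:
    """Filtering and segmentation settings (all lengths in micrometres).

    The top-hat radius must exceed the hair width (~2 um) so hairs survive
    the background opening; the Gaussian sigma is a fraction of the hair
    width.  ``h_fraction`` is the h-maxima prominence expressed as a fraction
    of the mean height of candidate maxima; ``stop_sd_multiple`` sets the
    watershed stop level at background + k SD.
    """

    top_hat_radius_um: float = 3.0
    gaussian_sigma_um: float = 0.8   # a fraction of the 2 um hair width
    h_fraction: float = 0.10
    stop_sd_multiple: float = 2.0
    hair_width_um: float = 2.0

    def validate(self) -> None:
        if self.top_hat_radius_um <= 0 or self.gaussian_sigma_um <= 0:
            raise ValueError("top-hat radius and Gaussian sigma must be > 0")
        if self.top_hat_radius_um <= self.hair_width_um:
            raise ValueError("top-hat radius must exceed the hair width")
        if self.gaussian_sigma_um >= self.hair_width_um:
            raise ValueError("Gaussian sigma must be below the hair width")


@dataclass
class HairVector:
    """One segmented hair: root, orientation, size and shape descriptors."""

    label: int
    root_um: tuple[float, float, float]        # (x, y, z)
    direction: tuple[float, float, float]      # unit vector, root -> tip
    length_um: float                           # sqrt of first covariance eigenvalue
    n_voxels: int
    anisotropy: float                          # lambda1 / lambda2
    ambiguous: bool = False                    # near-isotropic region
    discarded: bool = False
    discard_reason: str = ""


def preprocess_stack(stack: FocusStack, params: SegmentationParams) -> np.ndarray:
    """Top-hat (per z-slice, 2D) then 3D Gaussian blur; output is >= 0.

    The top-hat is applied slice-wise because the out-of-focus background
    varies with focus depth, not smoothly in 3D.
    """
    params.validate()
    vz, vy, vx = stack.voxel_size_um
    radius_px = max(1, int(round(params.top_hat_radius_um / vx)))
    footprint = disk(radius_px)
    data = np.asarray(stack.data, dtype=np.float32)
    out = np.empty_like(data)
    for i in range(data.shape[0]):
        out[i] = white_tophat(data[i], footprint=footprint)
    sigma = (
        params.gaussian_sigma_um / vz,
        params.gaussian_sigma_um / vy,
        params.gaussian_sigma_um / vx,
    )
    out = ndimage.gaussian_filter(out, sigma=sigma)
    np.clip(out, 0, None, out=out)
    return out


def estimate_background(volume: np.ndarray, n_bins: int = 256, n_iter: int = 5) -> tuple[float, float]:
    """Robust background (mean, SD) from the low-intensity mode.

    The histogram mode locates the background level (immune to a bright
    signal half); sigma-clipped statistics around the mode then give the
    mean and SD of the background population alone.
    """
    data = np.asarray(volume, dtype=np.float64).ravel()
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return lo, 0.0
    hist, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    left = data[data <= mode]
    sd = math.sqrt(np.mean((left - mode) ** 2)) if left.size else 0.0
    if sd <= 0:
        sd = (hi - lo) / n_bins
    mean = mode
    for _ in range(n_iter):
        sel = data[np.abs(data - mean) <= 3.0 * sd]
        if sel.size < 2:
            break
        new_mean, new_sd = float(sel.mean()), float(sel.std())
        if new_sd <= 0:
            break
        if abs(new_mean - mean) < 1e-12 and abs(new_sd - sd) < 1e-12:
            mean, sd = new_mean, new_sd
            break
        mean, sd = new_mean, new_sd
    return float(mean), float(sd)


def _local_maxima(volume: np.ndarray) -> np.ndarray:
    return volume >= ndimage.maximum_filter(volume, footprint=_FULL_3D, mode="constant", cval=-np.inf)


def resolve_h(volume: np.ndarray, h_fraction: float, floor: float | None = None) -> float:
    """Absolute h from a fraction of the average structure-maxima height.

    Candidates are plain local maxima of the filtered volume above ``floor``
    (the watershed stop level).  Their height distribution is bimodal --
    residual noise bumps just above the stop level versus hair peaks -- so
    the average is taken over the upper (structure) class, separated by an
    Otsu split of the maxima heights.  Without the split, the sheer number
    of noise maxima would drag the average (and h) toward the noise floor.
    """
    from skimage.filters import threshold_otsu

    maxima = _local_maxima(volume)
    vals = volume[maxima]
    if floor is not None:
        vals = vals[vals >= floor]
    if vals.size == 0:
        return np.inf
    if vals.size > 2 and vals.max() > vals.min():
        try:
            split = threshold_otsu(vals)
            upper = vals[vals > split]
            if upper.size:
                vals = upper
        except ValueError:
            pass
    return float(h_fraction * vals.mean())


def find_h_maxima(volume: np.ndarray, h: float) -> np.ndarray:
    """Labeled h-maxima seeds: regional maxima of the h-reconstruction.

    A maximum survives iff its prominence -- the drop to the highest saddle
    connecting it to strictly higher terrain -- exceeds h; its seed
    region is the surrounding superlevel component down to (peak - h), so
    maxima closer than h in height that share a shallow saddle merge into
    one seed.  Computed as the regional maxima of the grayscale
    reconstruction of (volume - h) under volume.  Returns an int32 label
    volume of seed components (26-connected).
    """
    from skimage.morphology import local_maxima

    if h <= 0:
        raise ValueError("h must be > 0")
    volume = np.asarray(volume, dtype=np.float64)
    if not np.isfinite(h) or h > volume.max() - volume.min():
        return np.zeros(volume.shape, dtype=np.int32)
    rec = reconstruction(volume - h, volume, method="dilation", footprint=_FULL_3D)
    seed_mask = local_maxima(rec, footprint=_FULL_3D)
    labels, _ = ndimage.label(seed_mask, structure=_FULL_3D)
    return labels.astype(np.int32)


def watershed_segment(
    volume: np.ndarray, seeds: np.ndarray, stop_level: float
) -> np.ndarray:
    """Seeded watershed flooding down to ``stop_level``.

    Voxels below the stop level stay background (label 0).  Regions are
    26-connected and disjoint; each contains exactly one seed component.
    """
    from skimage.segmentation import watershed

    if seeds.max() == 0:
        return np.zeros(volume.shape, dtype=np.int32)
    mask = volume >= stop_level
    labels = watershed(-volume, markers=seeds, mask=mask, connectivity=_FULL_3D)
    return labels.astype(np.int32)


def characterize_hair(
    coords_vox: np.ndarray,
    intensities: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    label: int = 0,
    anisotropy_floor: float = 1.5,
    intensity_weighted: bool = True,
) -> HairVector:
    """Reduce one labeled region to a hair vector.

    ``coords_vox`` is (n, 3) in (z, y, x) voxel indices.  The root is the
    brightest voxel; the direction is the first eigenvector of the position
    covariance (physical um coordinates), sign-fixed to point from the root
    toward the centroid; the length is the square root of the first
    eigenvalue.  Near-isotropic regions (lambda1/lambda2 below
    ``anisotropy_floor``) are flagged ambiguous.

    With ``intensity_weighted`` (default) the covariance and centroid weight
    each voxel by its intensity, anchoring the orientation to the bright
    hair core rather than the dim watershed halo; this matters most inside
    mwh clusters, where watershed cells of adjacent hairs share halo.
    Set it False for the plain (unweighted) position covariance.
    """
    coords_vox = np.asarray(coords_vox)
    if coords_vox.shape[0] < 3:
        raise ValueError("region must have at least 3 voxels")
    vz, vy, vx = voxel_size_um
    # physical coordinates in (x, y, z) order
    pos = np.column_stack(
        [coords_vox[:, 2] * vx, coords_vox[:, 1] * vy, coords_vox[:, 0] * vz]
    )
    root = pos[int(np.argmax(intensities))]
    if intensity_weighted:
        w = np.maximum(np.asarray(intensities, dtype=np.float64), 0.0)
        if w.sum() <= 0:
            w = np.ones(len(pos))
        w = w / w.sum()
        centroid = (pos * w[:, None]).sum(axis=0)
        diff = pos - centroid
        cov = (diff * w[:, None]).T @ diff
    else:
        centroid = pos.mean(axis=0)
        cov = np.cov(pos, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam1 = max(evals[0], 0.0)
    lam2 = max(evals[1], 1e-12)
    direction = evecs[:, 0]
    toward = centroid - root
    ambiguous = False
    if lam1 / lam2 < anisotropy_floor:
        ambiguous = True
    dot = float(direction @ toward)
    if dot < 0:
        direction = -direction
    elif dot == 0.0:
        ambiguous = True
    return HairVector(
        label=int(label),
        root_um=tuple(float(v) for v in root),
        direction=tuple(float(v) for v in direction),
        length_um=float(math.sqrt(lam1)),
        n_voxels=int(coords_vox.shape[0]),
        anisotropy=float(lam1 / lam2),
        ambiguous=ambiguous,
    )


def segment_stack(
    stack: FocusStack, params: SegmentationParams | None = None
) -> tuple[list[HairVector], np.ndarray, np.ndarray]:
    """Full segmentation: filter, seed, flood, characterize.

    Returns ``(hairs, label_volume, filtered_volume)``.  Regions with fewer
    than 3 voxels are dropped (they cannot carry a covariance direction).
    Also records the background estimate of the filtered stack on ``stack``.
    """
    params = params or SegmentationParams()
    filtered = preprocess_stack(stack, params)
    bg_mean, bg_sd = estimate_background(filtered)
    stack.background_mean, stack.background_sd = bg_mean, bg_sd
    stop = bg_mean + params.stop_sd_multiple * bg_sd
    h = resolve_h(filtered, params.h_fraction, floor=stop)
    seeds = find_h_maxima(filtered, h)
    # seeds below the stop level can never grow a region
    seeds[filtered < stop] = 0
    labels = watershed_segment(filtered, seeds, stop)
    hairs: list[HairVector] = []
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        if sub.sum() < 3:
            continue
        coords = np.argwhere(sub)
        coords += np.array([s.start for s in sl])
        vals = filtered[coords[:, 0], coords[:, 1], coords[:, 2]]
        hairs.append(
            characterize_hair(coords, vals, stack.voxel_size_um, label=lab)
        )
    return hairs, labels, filtered


def hairs_to_frame(hairs: list[HairVector]) -> pd.DataFrame:
    """Tabulate hair vectors, one row per hair (physical units)."""
    rows = []
    for hv in hairs:
        rows.append(
            dict(
                label=hv.label,
                root_x_um=hv.root_um[0],
                root_y_um=hv.root_um[1],
                root_z_um=hv.root_um[2],
                dir_x=hv.direction[0],
                dir_y=hv.direction[1],
                dir_z=hv.direction[2],
                length_um=hv.length_um,
                n_voxels=hv.n_voxels,
                anisotropy=hv.anisotropy,
                ambiguous=hv.ambiguous,
                discarded=hv.discarded,
                discard_reason=hv.discard_reason,
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "label", "root_x_um", "root_y_um", "root_z_um",
            "dir_x", "dir_y", "dir_z", "length_um", "n_voxels",
            "anisotropy", "ambiguous", "discarded", "discard_reason",
        ],
    )
    return frame
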