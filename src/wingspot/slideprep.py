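"""Slide preprocessing: from a low-resolution scan to acquisition positions.

A 300 dpi grayscale scan of the slide shows each mounted wing as a dark,
elongated blob.  The planner (1) thresholds the inverted scan at 15% of its
intensity range and labels connected regions, (2) keeps regions whose aspect
ratio (lambda1/lambda2 of the pixel-position covariance), area, and centroid
fall inside expected wing ranges, (3) finds each wing's origin (intensity
maximum after local blurring, the hinge) and axis (origin -> centre of
mass), (4) trims the hinge neighbourhood and the negative axis side,
(5) partitions the remaining pixels with k-means into acquisition positions,
the number of positions proportional to wing area, and (6) maps slide
coordinates into microscope stage coordinates with a similarity transform
X' = r * R_theta (X - X_c).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label
from skimage.morphology import closing, disk, opening

__all__ = [
    "SlideImage",
    "WingRegion",
    "StageTransform",
    "RegionFilterRanges",
    "segment_wings",
    "filter_regions",
    "locate_origin_and_axis",
    "trim_region",
    "partition_acquisitions",
    "to_stage_coords",
    "from_stage_coords",
    "estimate_stage_transform",
]


@dataclass
class SlideImage:
    """2D grayscale slide scan with its physical pixel pitch."""

    image: np.ndarray
    pixel_pitch_um: float = 25400.0 / 300.0  # 300 dpi

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 2 or self.image.size == 0:
            raise ValueError("slide image must be a non-empty 2D array")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be > 0")


@dataclass
class WingRegion:
    """One candidate wing region on the slide (pixel coordinates, x-y)."""

    label: int
    mask: np.ndarray                       # bool, full slide shape
    area_px: int
    centroid_xy: tuple[float, float]
    eigvals: tuple[float, float]           # lambda1 >= lambda2
    eigvecs: np.ndarray                    # columns, first = major axis
    aspect_ratio: float
    origin_xy: tuple[float, float] | None = None
    axis_xy: tuple[float, float] | None = None
    positions_xy: list[tuple[float, float]] = field(default_factory=list)
    degenerate: bool = False


@dataclass
class StageTransform:
    """Similarity map from slide pixels to microscope stage coordinates."""

    center_xy: tuple[float, float]
    theta_rad: float
    ratio: float  # microscope sampling / slide-image sampling

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("sampling ratio must be > 0")


@dataclass
class RegionFilterRanges:
    """Allowed intervals for region parameters (mean +/- 2 SD style)."""

    aspect: tuple[float, float] = (1.5, 12.0)
    area_px: tuple[float, float] = (80.0, 2000.0)
    centroid_x: tuple[float, float] = (-np.inf, np.inf)  # lamella selection
    centroid_y: tuple[float, float] = (-np.inf, np.inf)

    def validate(self):
        for lo, hi in (self.aspect, self.area_px, self.centroid_x, self.centroid_y):
            if not lo < hi:
                raise ValueError("filter intervals must be non-empty")


def _region_stats(mask: np.ndarray, label_id: int) -> WingRegion:
    ys, xs = np.nonzero(mask)
    area = xs.size
    cx, cy = float(xs.mean()), float(ys.mean())
    if area < 3:
        return WingRegion(
            label=label_id, mask=mask, area_px=area, centroid_xy=(cx, cy),
            eigvals=(0.0, 0.0), eigvecs=np.eye(2), aspect_ratio=np.inf,
            degenerate=True,
        )
    cov = np.cov(np.column_stack([xs, ys]), rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam1, lam2 = float(max(evals[0], 0)), float(max(evals[1], 0))
    degenerate = lam2 <= 1e-12
    aspect = np.inf if degenerate else lam1 / lam2
    return WingRegion(
        label=label_id, mask=mask, area_px=area, centroid_xy=(cx, cy),
        eigvals=(lam1, lam2), eigvecs=evecs, aspect_ratio=float(aspect),
        degenerate=degenerate,
    )


def segment_wings(
    slide: SlideImage,
    threshold_fraction: float = 0.15,
    regularize_radius_px: int = 2,
    min_area_px: int = 6,
    min_intensity_range: float = 48.0,
) -> list[WingRegion]:
    """Threshold the inverted scan and label candidate wing regions.

    The threshold sits at ``threshold_fraction`` (default 15%) of the
    inverted image's intensity range.  An optional morphological
    opening+closing with a disk regularizes contours.  A slide whose
    intensity range stays below ``min_intensity_range`` contains no dark
    object -- only scanner noise -- and yields no regions.
    """
    img = slide.image.astype(np.float64)
    inv = img.max() - img
    rng = inv.max() - inv.min()
    if rng < min_intensity_range:
        return []
    mask = inv > inv.min() + threshold_fraction * rng
    if regularize_radius_px > 0:
        fp = disk(regularize_radius_px)
        mask = closing(opening(mask, fp), fp)
    labels = sk_label(mask, connectivity=2)
    regions = []
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        if m.sum() < min_area_px:
            continue
        regions.append(_region_stats(m, lab))
    return regions


def filter_regions(
    regions: list[WingRegion], ranges: RegionFilterRanges
) -> tuple[list[WingRegion], list[tuple[WingRegion, list[str]]]]:
    """Keep regions whose aspect, area, and centroid all fall in range.

    Returns ``(kept, discarded)`` where each discard carries the list of
    failing criteria.  Degenerate (collinear / 1-px) regions are always
    discarded.
    """
    ranges.validate()
    kept, discarded = [], []
    for r in regions:
        reasons = []
        if r.degenerate:
            reasons.append("degenerate")
        if not ranges.aspect[0] <= r.aspect_ratio <= ranges.aspect[1]:
            reasons.append("aspect")
        if not ranges.area_px[0] <= r.area_px <= ranges.area_px[1]:
            reasons.append("area")
        if not (
            ranges.centroid_x[0] <= r.centroid_xy[0] <= ranges.centroid_x[1]
            and ranges.centroid_y[0] <= r.centroid_xy[1] <= ranges.centroid_y[1]
        ):
            reasons.append("position")
        if reasons:
            discarded.append((r, reasons))
        else:
            kept.append(r)
    return kept, discarded


def locate_origin_and_axis(
    region: WingRegion, slide: SlideImage, blur_sigma_px: float = 3.0
) -> WingRegion:
    """Set the wing origin (blurred intensity maximum) and axis.

    The blur is restricted to the wing region (masked Gaussian) so that the
    bright slide background cannot attract the maximum.  Ties break
    deterministically to the lowest row, then column.  The axis is the unit
    vector from the origin to the region's centre of mass; a coincident
    centroid raises ``ValueError`` (degenerate axis).
    """
    if not region.mask.any():
        raise ValueError("empty region mask")
    img = slide.image.astype(np.float64)
    m = region.mask.astype(np.float64)
    if blur_sigma_px > 0:
        num = ndimage.gaussian_filter(img * m, blur_sigma_px)
        den = ndimage.gaussian_filter(m, blur_sigma_px)
        blurred = np.where(den > 1e-12, num / np.maximum(den, 1e-12), -np.inf)
    else:
        blurred = img.copy()
    blurred[~region.mask] = -np.inf
    flat = int(np.argmax(blurred))  # row-major scan = lowest row, then column
    oy, ox = np.unravel_index(flat, blurred.shape)
    axis = np.array(region.centroid_xy) - np.array([ox, oy], dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("degenerate axis: origin coincides with the centroid")
    region.origin_xy = (float(ox), float(oy))
    region.axis_xy = tuple(axis / norm)
    return region


def trim_region(
    region: WingRegion,
    min_distance_um: float = 400.0,
    pixel_pitch_um: float = 25400.0 / 300.0,
) -> WingRegion:
    """Remove the origin neighbourhood and the negative axis side.

    Pixels closer than ``min_distance_um`` (~20% of a wing length) to the
    origin, or with negative projection on the wing axis, are dropped.
    Raises if the trim removes the whole mask.
    """
    if region.origin_xy is None or region.axis_xy is None:
        raise ValueError("origin and axis must be set before trimming")
    ys, xs = np.nonzero(region.mask)
    dx = (xs - region.origin_xy[0]) * pixel_pitch_um
    dy = (ys - region.origin_xy[1]) * pixel_pitch_um
    proj = dx * region.axis_xy[0] + dy * region.axis_xy[1]
    dist = np.hypot(dx, dy)
    keep = (dist >= min_distance_um) & (proj >= 0)
    if not keep.any():
        raise ValueError("wing fully trimmed")
    new_mask = np.zeros_like(region.mask)
    new_mask[ys[keep], xs[keep]] = True
    out = _region_stats(new_mask, region.label)
    out.origin_xy = region.origin_xy
    out.axis_xy = region.axis_xy
    return out


def partition_acquisitions(
    region: WingRegion,
    max_fields: int = 6,
    reference_area_px: float | None = None,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """k-means partition of the wing pixels into acquisition positions.

    k = round(max_fields * area / reference_area), clamped to
    [1, max_fields]; the mean position of each class is one acquisition
    position (slide coordinates, x-y).  Deterministic for a fixed seed.
    """
    from sklearn.cluster import KMeans

    ys, xs = np.nonzero(region.mask)
    if xs.size == 0:
        raise ValueError("empty region mask")
    ref = reference_area_px if reference_area_px else float(region.area_px)
    k = int(round(max_fields * region.area_px / ref))
    k = max(1, min(max_fields, k, xs.size))
    pts = np.column_stack([xs, ys]).astype(float)
    if k == 1:
        centers = pts.mean(axis=0)[None, :]
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(pts)
        centers = km.cluster_centers_
    positions = [(float(x), float(y)) for x, y in centers]
    positions.sort()
    region.positions_xy = positions
    return positions


def to_stage_coords(X, t: StageTransform) -> np.ndarray:
    """Map slide positions to stage coordinates: X' = r * R_theta (X - Xc)."""
    X = np.asarray(X, dtype=np.float64)
    c, s = math.cos(t.theta_rad), math.sin(t.theta_rad)
    R = np.array([[c, -s], [s, c]])
    return t.ratio * (X - np.asarray(t.center_xy)) @ R.T


def from_stage_coords(Xp, t: StageTransform) -> np.ndarray:
    """Inverse of :func:`to_stage_coords` (exact round trip)."""
    Xp = np.asarray(Xp, dtype=np.float64)
    c, s = math.cos(t.theta_rad), math.sin(t.theta_rad)
    R = np.array([[c, -s], [s, c]])
    return (Xp / t.ratio) @ R + np.asarray(t.center_xy)


def estimate_stage_transform(
    slide: SlideImage,
    ratio: float,
    dark_fraction: float = 0.5,
) -> StageTransform:
    """Rough slide frame estimate from the scan (a reconstruction).

    The published pipeline derives the slide centre and orientation from
    the scan's dark rectangular boundary with a procedure that is not fully
    specified; this estimator is a simple stand-in: the slide centre is the
    image centre of mass of dark pixels and the orientation is the dominant
    axis of that dark mask.  Prefer supplying a calibrated transform.
    """
    img = slide.image.astype(np.float64)
    thr = img.min() + dark_fraction * (img.max() - img.min())
    dark = img < thr
    if not dark.any():
        return StageTransform(
            center_xy=((img.shape[1] - 1) / 2.0, (img.shape[0] - 1) / 2.0),
            theta_rad=0.0, ratio=ratio,
        )
    ys, xs = np.nonzero(dark)
    cx, cy = float(xs.mean()), float(ys.mean())
    cov = np.cov(np.column_stack([xs, ys]), rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    theta = math.atan2(major[1], major[0])
    return StageTransform(center_xy=(cx, cy), theta_rad=theta, ratio=ratio)
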