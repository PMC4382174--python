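"""Independent brute-force oracles used by the test suite.

The prominence oracle recomputes h-maxima seeds by exhaustive superlevel-set
labeling, with no shared code with the reconstruction-based implementation
it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

def _full_structure(ndim):
    return np.ones((3,) * ndim, dtype=bool)


def regional_maxima_plateaus(volume: np.ndarray):
    """All regional-maximum plateaus: (mask, peak_value) pairs.

    A plateau is a connected component of equal value none of whose outside
    neighbours is higher.
    """
    st = _full_structure(volume.ndim)
    out = []
    for val in np.unique(volume):
        comp, n = ndimage.label(volume == val, structure=st)
        for i in range(1, n + 1):
            mask = comp == i
            ring = ndimage.binary_dilation(mask, structure=st) & ~mask
            if not ring.any() or volume[ring].max() < val:
                out.append((mask, float(val)))
    return out


def prominence(volume: np.ndarray, plateau_mask: np.ndarray, peak: float) -> float:
    """Drop from ``peak`` to the highest saddle reaching strictly higher terrain.

    Exhaustive: for each level descending, label the superlevel set and ask
    whether the plateau's component contains a strictly higher voxel.
    Returns ``inf`` for the global maximum.
    """
    st = _full_structure(volume.ndim)
    seed_idx = tuple(c[0] for c in np.nonzero(plateau_mask))
    levels = np.unique(volume)[::-1]
    for level in levels[levels <= peak]:
        comp, _ = ndimage.label(volume >= level, structure=st)
        cid = comp[seed_idx]
        if volume[comp == cid].max() > peak:
            return peak - float(level)
    return np.inf


def h_maxima_seeds_oracle(volume: np.ndarray, h: float) -> np.ndarray:
    """Union of seed regions of all maxima whose prominence exceeds h.

    Each surviving maximum contributes the connected component of the
    superlevel set {f >= peak - h} that contains it, so near-equal maxima
    joined by a shallow saddle merge into a single seed region.  At
    prominence exactly h a maximum's plateau touches the neighbouring
    basin's reconstruction level and is suppressed, hence the strict
    comparison (a measure-zero case for real-valued data).
    """
    st = _full_structure(volume.ndim)
    seeds = np.zeros(volume.shape, dtype=bool)
    # per-level superlevel labelings and per-component maxima, shared by all
    # maxima of the volume (pure speed; the logic stays exhaustive)
    levels = np.unique(volume)[::-1]
    comp_by_level = {}
    comp_max = {}
    for level in levels:
        comp, n = ndimage.label(volume >= level, structure=st)
        comp_by_level[level] = comp
        comp_max[level] = ndimage.maximum(volume, labels=comp, index=np.arange(1, n + 1))
    for mask, peak in regional_maxima_plateaus(volume):
        idx = tuple(c[0] for c in np.nonzero(mask))
        prom = np.inf
        for level in levels[levels <= peak]:
            cid = comp_by_level[level][idx]
            if comp_max[level][cid - 1] > peak:
                prom = peak - float(level)
                break
        if prom > h:
            # {f >= peak - h} equals the superlevel set at the lowest
            # occurring value still >= peak - h
            lv = levels[levels >= peak - h][-1]
            comp = comp_by_level[lv]
            cid = comp[idx]
            seeds |= comp == cid
    return seeds
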