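"""Wing-side assignment, consistency filters, and *mwh* phenotype calling.

Hairs grow on both surfaces of the wing at an acute angle.  Locally the wing
is flat, so the local surface altitude z0 can be estimated by averaging
neighbouring hair-root altitudes inside a cylinder (radius 2 x the inter-hair
distance, ~25 um); the signed root altitude z_s = z - z0 and the signed angle
phi of the hair direction to the x-y plane then both change sign at the
surface: top hairs have both positive, bottom hairs both negative, and
mixed signs mark segmentation errors that are discarded.

A hair is called *mwh* when its nearest same-side neighbour root lies closer
than 5 um -- well below the 12.5 +/- 2.5 um wild-type spacing.  Mutant hairs
are grouped into cells (single linkage at the same 5 um threshold) and cells
into spots (single linkage at 2 x the inter-hair distance), the classical
counting units of the wing-spot test.

All operations take and return the hair table (one row per hair, physical
units) produced by :func:`wingspot.segmentation.hairs_to_frame`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ClassificationParams",
    "MwhGrouping",
    "estimate_surface",
    "assign_side",
    "filter_orientation_outliers",
    "filter_shape_outliers",
    "filter_surface_outliers",
    "call_mwh",
    "group_cells_and_spots",
    "classify_hairs",
]


@dataclass
class ClassificationParams:
    surface_radius_um: float = 25.0      # cylinder radius, 2 x inter-hair distance
    mwh_threshold_um: float = 5.0
    inter_hair_mean_um: float = 12.5
    inter_hair_sd_um: float = 2.5
    angle_ambiguity_fraction: float = 0.10
    altitude_outlier_sd: float = 2.0
    shape_outlier_k: float = 3.5         # robust MAD-equivalent bound multiplier
    spot_threshold_um: float = 25.0      # cell adjacency, 2 x inter-hair distance
    mwh_distance_3d: bool = True         # 3D Euclidean (planar if False)

    def validate(self) -> None:
        if not self.mwh_threshold_um < self.inter_hair_mean_um - 2 * self.inter_hair_sd_um:
            raise ValueError(
                "mwh threshold must stay below inter-hair mean - 2 SD "
                f"({self.mwh_threshold_um} vs "
                f"{self.inter_hair_mean_um - 2 * self.inter_hair_sd_um})"
            )


@dataclass
class MwhGrouping:
    """Per-wing-stack mutant bookkeeping: hairs -> cells -> spots."""

    n_mwh_hairs: int
    n_cells: int
    n_spots: int


def _active(df: pd.DataFrame) -> np.ndarray:
    return (~df["discarded"].to_numpy(dtype=bool))


def estimate_surface(df: pd.DataFrame, params: ClassificationParams | None = None) -> pd.DataFrame:
    """Local surface altitude per hair, from roots in a planar cylinder.

    Adds columns ``z0_um`` (mean neighbouring root altitude, both sides,
    including the hair itself), ``z_s_um`` (= z - z0), ``phi_rad`` (signed
    angle of the direction to the x-y plane), ``n_surface_neighbors`` and
    ``surface_low_confidence``.  A hair with no other root inside the
    cylinder takes z0 from its nearest neighbour and is flagged.
    """
    p = params or ClassificationParams()
    if len(df) < 2:
        raise ValueError("surface estimation needs at least 2 hairs")
    xy = df[["root_x_um", "root_y_um"]].to_numpy()
    z = df["root_z_um"].to_numpy()
    active = _active(df)
    if not active.any():
        # nothing reliable to anchor the surface; fall back to all roots
        active = np.ones(len(df), dtype=bool)
    src_idx = np.flatnonzero(active)
    tree = cKDTree(xy[src_idx])
    z0 = np.empty(len(df))
    n_nb = np.zeros(len(df), dtype=int)
    lowconf = np.zeros(len(df), dtype=bool)
    neighbor_lists = tree.query_ball_point(xy, r=p.surface_radius_um)
    for i, nbrs in enumerate(neighbor_lists):
        ids = src_idx[nbrs]
        others = ids[ids != i]
        if others.size == 0:
            # fall back to the single nearest (other) root
            kq = min(2, len(src_idx))
            dist, j = tree.query(xy[i], k=kq)
            cand = src_idx[np.atleast_1d(j)]
            cand = cand[cand != i]
            z0[i] = z[cand[0]] if cand.size else z[i]
            n_nb[i] = 1
            lowconf[i] = True
        else:
            z0[i] = z[np.append(others, i)].mean() if active[i] else z[others].mean()
            n_nb[i] = others.size + (1 if active[i] else 0)
    df["z0_um"] = z0
    df["z_s_um"] = z - z0
    dirs = df[["dir_x", "dir_y", "dir_z"]].to_numpy()
    norms = np.linalg.norm(dirs, axis=1)
    norms[norms == 0] = 1.0
    df["phi_rad"] = np.arcsin(np.clip(dirs[:, 2] / norms, -1, 1))
    df["n_surface_neighbors"] = n_nb
    df["surface_low_confidence"] = lowconf
    return df


def assign_side(df: pd.DataFrame) -> pd.DataFrame:
    """Top iff phi > 0 and z_s > 0; bottom iff both negative; else discard."""
    phi = df["phi_rad"].to_numpy()
    zs = df["z_s_um"].to_numpy()
    side = np.where((phi > 0) & (zs > 0), "top", np.where((phi < 0) & (zs < 0), "bottom", ""))
    df["side"] = side
    bad = (side == "") & _active(df)
    df.loc[bad, "discarded"] = True
    df.loc[bad, "discard_reason"] = "side-inconsistent"
    return df


def filter_orientation_outliers(
    df: pd.DataFrame, params: ClassificationParams | None = None
) -> pd.DataFrame:
    """Discard hairs anti-parallel to their average neighbour direction.

    The scalar product of each hair's direction with the mean direction of
    its (non-discarded) neighbours inside the surface cylinder must be
    non-negative.  Hairs without neighbours are left alone (insufficient
    evidence).
    """
    p = params or ClassificationParams()
    active = _active(df)
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return df
    xy = df[["root_x_um", "root_y_um"]].to_numpy()[idx]
    dirs = df[["dir_x", "dir_y", "dir_z"]].to_numpy()
    tree = cKDTree(xy)
    flag = np.zeros(len(df), dtype=bool)
    neighbor_lists = tree.query_ball_point(xy, r=p.surface_radius_um)
    for k, nbrs in enumerate(neighbor_lists):
        i = idx[k]
        others = [idx[m] for m in nbrs if idx[m] != i]
        if not others:
            continue
        mean_dir = dirs[others].mean(axis=0)
        if float(dirs[i] @ mean_dir) < 0:
            flag[i] = True
    df.loc[flag, "discarded"] = True
    df.loc[flag, "discard_reason"] = "orientation"
    return df


def filter_shape_outliers(
    df: pd.DataFrame, params: ClassificationParams | None = None, min_hairs: int = 30
) -> pd.DataFrame:
    """Discard hairs with abnormal shape descriptors (robust bounds).

    Descriptors: length, voxel count, anisotropy, with robust bounds at
    median + k * 1.4826 * MAD (upper side for size and length: the filter
    exists to catch under-segmented, i.e. merged and hence oversized,
    objects -- mwh hairs are legitimately short).  Anisotropy uses an
    absolute blob floor instead of a population bound: cluster hairs have
    legitimately reduced anisotropy, so a bound relative to the wild-type
    field would flag real mutant hairs.  With fewer than ``min_hairs``
    active hairs no distribution can be estimated and nothing is flagged.
    """
    p = params or ClassificationParams()
    active = _active(df)
    if active.sum() < min_hairs:
        warnings.warn(
            f"only {int(active.sum())} hairs; shape-outlier filter skipped",
            stacklevel=2,
        )
        return df
    flag = np.zeros(len(df), dtype=bool)
    # relative floor keeps the bounds meaningful on very homogeneous fields,
    # where the raw MAD collapses and natural tails would be flagged
    for col, floor in (("length_um", 0.35), ("n_voxels", 0.50)):
        vals = df[col].to_numpy(dtype=float)
        ref = vals[active]
        med = np.median(ref)
        mad = np.median(np.abs(ref - med))
        half = max(p.shape_outlier_k * 1.4826 * mad, floor * abs(med))
        flag |= active & (vals > med + half)
    flag |= active & (df["anisotropy"].to_numpy(dtype=float) < 1.5)
    df.loc[flag, "discarded"] = True
    df.loc[flag, "discard_reason"] = "shape"
    return df


def filter_surface_outliers(
    df: pd.DataFrame, params: ClassificationParams | None = None
) -> pd.DataFrame:
    """Discard hairs abnormally placed or angled relative to the surface.

    Per wing side: (1) |z_s| above the side's mean + k SD (default k = 2);
    (2) ambiguous angle, |phi| below 10% of the side's mean |phi|.
    """
    p = params or ClassificationParams()
    flag_alt = np.zeros(len(df), dtype=bool)
    flag_ang = np.zeros(len(df), dtype=bool)
    active = _active(df)
    for side in ("top", "bottom"):
        sel = active & (df["side"].to_numpy() == side)
        if sel.sum() < 2:
            continue
        zs = np.abs(df["z_s_um"].to_numpy())
        phi = np.abs(df["phi_rad"].to_numpy())
        bound = zs[sel].mean() + p.altitude_outlier_sd * zs[sel].std()
        flag_alt |= sel & (zs > bound)
        flag_ang |= sel & (phi < p.angle_ambiguity_fraction * phi[sel].mean())
    df.loc[flag_alt, "discarded"] = True
    df.loc[flag_alt, "discard_reason"] = "surface-altitude"
    df.loc[flag_ang & ~flag_alt, "discarded"] = True
    df.loc[flag_ang & ~flag_alt, "discard_reason"] = "surface-angle"
    return df


def call_mwh(df: pd.DataFrame, params: ClassificationParams | None = None) -> pd.DataFrame:
    """Call the *mwh* phenotype from nearest same-side neighbour distance.

    Discarded hairs neither receive a phenotype nor serve as neighbours.
    The call is symmetric: both members of a close pair become *mwh*.
    """
    p = params or ClassificationParams()
    p.validate()
    phen = np.full(len(df), "", dtype=object)
    active = _active(df)
    cols = ["root_x_um", "root_y_um", "root_z_um"] if p.mwh_distance_3d else [
        "root_x_um", "root_y_um"
    ]
    for side in ("top", "bottom"):
        sel = np.flatnonzero(active & (df["side"].to_numpy() == side))
        if sel.size == 0:
            continue
        phen[sel] = "wt"
        if sel.size == 1:
            continue
        pos = df.iloc[sel][cols].to_numpy()
        tree = cKDTree(pos)
        dist, _ = tree.query(pos, k=2)
        near = dist[:, 1] < p.mwh_threshold_um
        phen[sel[near]] = "mwh"
    df["phenotype"] = phen
    return df


def _single_linkage_components(pos: np.ndarray, threshold: float) -> np.ndarray:
    """Connected components of the < threshold proximity graph (union-find)."""
    n = pos.shape[0]
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(pos)
    for i, j in tree.query_pairs(r=threshold):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def group_cells_and_spots(
    df: pd.DataFrame, params: ClassificationParams | None = None
) -> tuple[pd.DataFrame, MwhGrouping]:
    """Group *mwh* hairs into cells and cells into spots (single linkage).

    Cells cluster at the mwh threshold (5 um), spots at the cell-adjacency
    threshold (25 um); both per wing side, deterministically.  Adds
    ``cell_id`` and ``spot_id`` columns (-1 for non-mwh hairs).
    """
    p = params or ClassificationParams()
    cell_ids = np.full(len(df), -1, dtype=int)
    spot_ids = np.full(len(df), -1, dtype=int)
    cell_off = 0
    spot_off = 0
    cols = ["root_x_um", "root_y_um", "root_z_um"] if p.mwh_distance_3d else [
        "root_x_um", "root_y_um"
    ]
    for side in ("top", "bottom"):
        sel = np.flatnonzero(
            (df.get("phenotype", pd.Series([""] * len(df))).to_numpy() == "mwh")
            & (df["side"].to_numpy() == side)
        )
        if sel.size == 0:
            continue
        pos = df.iloc[sel][cols].to_numpy()
        cells = _single_linkage_components(pos, p.mwh_threshold_um)
        cell_ids[sel] = cells + cell_off
        # spots: single linkage over hairs at the spot threshold merges cells
        spots_hair = _single_linkage_components(pos, p.spot_threshold_um)
        spot_ids[sel] = spots_hair + spot_off
        cell_off += cells.max() + 1
        spot_off += spots_hair.max() + 1
    df["cell_id"] = cell_ids
    df["spot_id"] = spot_ids
    n_mwh = int((cell_ids >= 0).sum())
    n_cells = int(np.unique(cell_ids[cell_ids >= 0]).size)
    n_spots = int(np.unique(spot_ids[spot_ids >= 0]).size)
    return df, MwhGrouping(n_mwh_hairs=n_mwh, n_cells=n_cells, n_spots=n_spots)


def classify_hairs(
    df: pd.DataFrame, params: ClassificationParams | None = None
) -> tuple[pd.DataFrame, MwhGrouping]:
    """Run the full classification chain on a hair table.

    Surface estimation, side assignment, the three consistency filters,
    phenotype calling, and cell/spot grouping, in that order.
    """
    p = params or ClassificationParams()
    df = estimate_surface(df, p)
    df = assign_side(df)
    df = filter_orientation_outliers(df, p)
    df = filter_shape_outliers(df, p)
    df = filter_surface_outliers(df, p)
    df = call_mwh(df, p)
    return group_cells_and_spots(df, p)
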