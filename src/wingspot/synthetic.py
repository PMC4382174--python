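"""Synthetic wing data with known ground truth.

Three generators cover the three kinds of input the automated wing-spot
(SMART) readout consumes:

* :func:`generate_wing_stack` -- a bright-field focus stack holding two
  hair-covered wing surfaces, with per-hair ground truth;
* :func:`generate_slide_image` -- a low-resolution grayscale slide scan with
  dark wing-shaped blobs and known outlines;
* :func:`generate_dose_scores` -- per-wing genotoxicity score tables whose
  per-dose means follow a known sigmoid dose-response curve.

Every generator takes an explicit seed; there is no global random state.

The stack generator emulates the statistics that drive the analysis: local
hair regularity (inter-hair distance 12.5 +/- 2.5 um by default), *mwh*
mutant cells bearing 2--4 close-set hairs (< 5 um apart), vein stripes of
elevated structure density, an optional hair-free off-wing margin, and
additive Gaussian acquisition noise.  It does not attempt optical realism
(no PSF, no refraction through the wing membrane).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack import FocusStack

__all__ = [
    "StackParams",
    "GroundTruth",
    "SlideParams",
    "WingOutline",
    "SigmoidParams",
    "generate_wing_stack",
    "generate_slide_image",
    "generate_dose_scores",
]


# --------------------------------------------------------------------------
# focus stacks
# --------------------------------------------------------------------------

@dataclass
class StackParams:
    """Parameters of the synthetic focus-stack generator.

    Defaults define the package's standard synthetic study conditions: a
    200 x 200 um field sampled at 0.64 um/px planar and 1 um axial, two hair
    layers 16 um apart, wild-type hairs on a jittered hexagonal lattice with
    mean nearest-neighbour spacing ``hair_spacing_um``.
    """

    field_size_um: tuple[float, float] = (200.0, 200.0)  # (y, x)
    z_depth_um: float = 44.0
    voxel_xy_um: float = 0.64
    voxel_z_um: float = 1.0

    hair_spacing_um: float = 12.5
    hair_spacing_sd_um: float = 2.5
    hair_length_um: float = 10.0
    hair_width_um: float = 2.0
    hair_tilt_deg: float = 30.0
    prevailing_angle_deg: float = 20.0   # planar hair direction
    angle_noise_deg: float = 6.0

    surface_mid_um: float = 20.0
    surface_separation_um: float = 16.0
    undulation_amp_um: float = 1.0
    undulation_period_um: float = 80.0

    n_mwh_clones: int = 0
    clone_size_cells: int = 3
    hairs_per_cell: int | tuple[int, int] = (2, 4)
    mwh_ring_radius_um: float = 2.2      # cell hairs sit on this ring (< 5 um pairwise)

    vein_stripes: tuple[tuple[float, float], ...] = ()  # (center_x_um, width_um)
    vein_hair_spacing_um: float = 4.0
    vein_band_intensity: float = 40.0
    margin_um: float = 0.0               # hair-free off-wing margin on the +x edge

    place_hairs: bool = True             # False: empty field (no-signal case)

    background: float = 50.0
    noise_sd: float = 3.0   # cooled-CCD acquisition noise, ~2% of hair peak
    hair_peak: float = 150.0
    tip_intensity_fraction: float = 0.4  # linear taper root -> tip

    seed: int = 0

    def validate(self) -> None:
        if self.voxel_xy_um <= 0 or self.voxel_z_um <= 0:
            raise ValueError("voxel sizes must be > 0")
        if not self.hair_width_um < self.hair_spacing_um:
            raise ValueError("hair width must be smaller than the inter-hair distance")
        # widest intra-cell distance occurs for the 4-hair ring (opposite
        # hairs at 2 x 1.09 x radius)
        intra = 2.18 * self.mwh_ring_radius_um
        lo = self.hair_spacing_um - 2.0 * self.hair_spacing_sd_um
        if not (intra < 5.0 < lo):
            raise ValueError(
                "mwh intra-cell spacing must stay below 5 um and 5 um below "
                f"spacing - 2 SD (got intra={intra:.2f}, spacing-2sd={lo:.2f})"
            )


@dataclass
class GroundTruth:
    """Ground truth for one synthetic stack.

    ``hairs`` has one row per rendered hair: root position (um), direction
    unit vector, length, side, phenotype, cell/spot ids (-1 for wild type),
    an ``on_vein`` flag for hairs rendered inside vein stripes (excluded
    from the regular-lattice spacing guarantees), and ``in_field`` (False
    for hairs rooted in the lattice overhang just outside the acquisition
    field, rendered only so the field boundary looks like a continuing
    wing).  ``region_mask`` is True on x-y pixels belonging to veins or the
    off-wing margin.
    """

    hairs: pd.DataFrame
    region_mask: np.ndarray
    analyzed_area_um2: float
    params: StackParams


def _hex_lattice(rng, size_y, size_x, spacing, jitter_sd, min_dist, pad=0.0):
    """Jittered hexagonal point pattern with a hard minimum distance.

    The lattice constant carries a small upward correction so that the
    *measured* mean nearest-neighbour distance matches ``spacing``: taking
    the minimum over ~6 jittered neighbours biases it low by roughly one
    jitter SD.
    """
    a = spacing + 1.1 * jitter_sd
    dy = a * math.sqrt(3.0) / 2.0
    max_jit = max(0.0, 0.5 * (a - min_dist) - 0.05)
    pts = []
    y0 = rng.uniform(0, dy) - pad
    x0 = rng.uniform(0, a) - pad
    n_rows = int((size_y + 2 * pad) / dy) + 2
    n_cols = int((size_x + 2 * pad) / a) + 2
    for i in range(n_rows):
        y = y0 + i * dy
        for j in range(n_cols):
            x = x0 + j * a + (i % 2) * a / 2.0
            jit = rng.normal(0.0, jitter_sd / math.sqrt(2.0), size=2)
            r = math.hypot(*jit)
            if r > max_jit:
                jit *= max_jit / r
            px, py = x + jit[0], y + jit[1]
            if -pad <= px < size_x + pad and -pad <= py < size_y + pad:
                pts.append((px, py, i, j))
    return a, pts


def _surface_altitude(p: StackParams, x, y, side):
    und = p.undulation_amp_um * np.sin(2 * np.pi * x / p.undulation_period_um) * np.cos(
        2 * np.pi * y / p.undulation_period_um
    )
    off = p.surface_separation_um / 2.0
    return p.surface_mid_um + (off if side == "top" else -off) + und


def _hair_direction(rng, p: StackParams, side, angle_noise=True):
    psi = math.radians(p.prevailing_angle_deg)
    if angle_noise:
        psi += rng.normal(0.0, math.radians(p.angle_noise_deg))
    tilt = math.radians(p.hair_tilt_deg)
    sz = math.sin(tilt) if side == "top" else -math.sin(tilt)
    c = math.cos(tilt)
    return np.array([c * math.cos(psi), c * math.sin(psi), sz])


def _render_rod(vol, p: StackParams, root, direction, length, peak):
    """Draw one tilted tapered rod (max-combined) into ``vol`` (z, y, x)."""
    vz, vxy = p.voxel_z_um, p.voxel_xy_um
    tipf = p.tip_intensity_fraction
    # thinner at the root than the tip, but not so thin that the root's
    # observed (blur-attenuated) intensity stops being the region maximum
    r_root, r_tip = 0.3 * p.hair_width_um, 0.5 * p.hair_width_um
    tip = root + length * direction
    pad = 3.0 * max(r_tip, 0.9 * 1.6)
    lo = np.minimum(root, tip) - pad
    hi = np.maximum(root, tip) + pad
    nz, ny, nx = vol.shape
    iz0 = max(int(lo[2] / vz), 0); iz1 = min(int(hi[2] / vz) + 2, nz)
    iy0 = max(int(lo[1] / vxy), 0); iy1 = min(int(hi[1] / vxy) + 2, ny)
    ix0 = max(int(lo[0] / vxy), 0); ix1 = min(int(hi[0] / vxy) + 2, nx)
    if iz0 >= iz1 or iy0 >= iy1 or ix0 >= ix1:
        return
    zc = (np.arange(iz0, iz1) * vz)[:, None, None]
    yc = (np.arange(iy0, iy1) * vxy)[None, :, None]
    xc = (np.arange(ix0, ix1) * vxy)[None, None, :]
    relx = xc - root[0]
    rely = yc - root[1]
    relz = zc - root[2]
    s = relx * direction[0] + rely * direction[1] + relz * direction[2]
    s = np.clip(s, 0.0, length)
    dx = relx - s * direction[0]
    dy = rely - s * direction[1]
    dz = relz - s * direction[2]
    frac = s / length
    radius = r_root + (r_tip - r_root) * frac
    sigma = radius / 1.6
    # bright-field depth of field elongates structures axially; without it a
    # thin rod would fall between 1-um z samples and fragment
    sigma_z = np.maximum(sigma, 1.1)
    rho2 = (dx * dx + dy * dy) / sigma**2 + dz * dz / sigma_z**2
    val = peak * (1.0 - (1.0 - tipf) * frac) * np.exp(-rho2 / 2.0)
    # bright socket at the root: keeps the observed intensity maximum at the
    # root despite the blur's reduced support at the rod end
    knob2 = (relx * relx + rely * rely) / 0.8**2 + relz * relz / 1.1**2
    np.maximum(val, peak * np.exp(-knob2 / 2.0), out=val)
    box = vol[iz0:iz1, iy0:iy1, ix0:ix1]
    np.maximum(box, val, out=box)


def generate_wing_stack(params: StackParams) -> tuple[FocusStack, GroundTruth]:
    """Render a synthetic two-surface wing focus stack with ground truth.

    Raises
    ------
    ValueError
        If parameters violate their invariants, or the field is too small to
        place a single hair at the requested spacing.
    """
    p = params
    p.validate()
    size_y, size_x = p.field_size_um
    hair_x_max = size_x - p.margin_um
    if hair_x_max < p.hair_spacing_um or size_y < p.hair_spacing_um:
        raise ValueError(
            f"field {p.field_size_um} um (margin {p.margin_um}) too small to "
            f"place any hair at spacing {p.hair_spacing_um} um"
        )
    rng = np.random.default_rng(p.seed)

    records = []  # root_x/y/z, dir, side, phenotype, cell, spot, on_vein

    def in_vein(x):
        return any(abs(x - cx) <= w / 2.0 for cx, w in p.vein_stripes)

    lattices = {}
    # the wing blade extends past the acquisition field: hairs rooted just
    # outside still reach into the volume, so the lattice overhangs the
    # field by roughly one hair length
    pad = 1.2 * p.hair_length_um
    for side in ("top", "bottom") if p.place_hairs else ():
        a, pts = _hex_lattice(
            rng, size_y, hair_x_max, p.hair_spacing_um, p.hair_spacing_sd_um, 5.0,
            pad=pad,
        )
        if p.margin_um > 0:
            # the margin edge is the actual wing border: nothing overhangs it
            pts = [q for q in pts if q[0] < hair_x_max]
        lattices[side] = (a, pts)

    # --- mwh clones: contiguous runs of lattice sites on one side ----------
    n_hairs_per_cell = p.hairs_per_cell
    clone_sites: dict[str, dict[int, tuple[int, int]]] = {"top": {}, "bottom": {}}
    cell_counter = 0
    if not p.place_hairs and p.n_mwh_clones > 0:
        raise ValueError("cannot place mwh clones with place_hairs=False")
    guard = 1.5 * p.hair_spacing_um
    # keep clones clear of veins: the discard mask is deliberately wider
    # than the vein stripe itself
    vein_guard = max(guard, 30.0)
    for spot_id in range(p.n_mwh_clones):
        side = "top" if rng.random() < 0.5 else "bottom"
        a, pts = lattices[side]
        interior = [
            k for k, (x, y, _i, _j) in enumerate(pts)
            if guard <= x <= hair_x_max - guard and guard <= y <= size_y - guard
            and not any(abs(x - cx) <= w / 2.0 + vein_guard for cx, w in p.vein_stripes)
            and k not in clone_sites[side]
        ]
        if not interior:
            raise ValueError("no room left to place an mwh clone")
        seed_k = int(rng.choice(interior))
        # BFS over nearest lattice sites to grow a contiguous clone
        chosen = [seed_k]
        coords = np.array([(pts[k][0], pts[k][1]) for k in interior])
        while len(chosen) < p.clone_size_cells:
            best, bestd = None, np.inf
            for k, (x, y) in zip(interior, coords):
                if k in chosen:
                    continue
                d = min(
                    math.hypot(x - pts[c][0], y - pts[c][1]) for c in chosen
                )
                if d < bestd:
                    best, bestd = k, d
            if best is None:
                break
            chosen.append(best)
        for k in chosen:
            clone_sites[side][k] = (cell_counter, spot_id)
            cell_counter += 1

    # --- wild-type field + clone cells -------------------------------------
    for side in ("top", "bottom") if p.place_hairs else ():
        a, pts = lattices[side]
        for k, (x, y, _i, _j) in enumerate(pts):
            if in_vein(x):
                continue  # vein hairs rendered separately below
            z0 = float(_surface_altitude(p, x, y, side))
            if k in clone_sites[side]:
                cell_id, spot_id = clone_sites[side][k]
                if isinstance(n_hairs_per_cell, tuple):
                    k_hairs = int(rng.integers(n_hairs_per_cell[0], n_hairs_per_cell[1] + 1))
                else:
                    k_hairs = int(n_hairs_per_cell)
                phase = rng.uniform(0, 2 * np.pi)
                # ring radius scales with hair count: pairwise root distances
                # stay in ~3.4-4.8 um, below the 5 um call threshold with
                # margin for localization error
                ring = p.mwh_ring_radius_um * {2: 0.86, 3: 1.0, 4: 1.09}.get(k_hairs, 1.0)
                for m in range(k_hairs):
                    ang = phase + 2 * np.pi * m / k_hairs
                    hx = x + ring * math.cos(ang)
                    hy = y + ring * math.sin(ang)
                    hz = float(_surface_altitude(p, hx, hy, side))
                    # cell hairs fan outward from the cell centre and vary in
                    # length, as real mwh hairs do
                    d = _hair_direction(rng, p, side)
                    splay = np.array([math.cos(ang), math.sin(ang), 0.0])
                    d = d + 0.7 * splay
                    d /= np.linalg.norm(d)
                    hair_len = p.hair_length_um * rng.uniform(0.7, 1.0)
                    records.append((hx, hy, hz, *d, hair_len, side, "mwh", cell_id, spot_id, False))
            else:
                d = _hair_direction(rng, p, side)
                records.append((x, y, z0, *d, p.hair_length_um, side, "wt", -1, -1, False))

    # --- vein hairs: dense, shorter, same morphology ------------------------
    for cx, w in p.vein_stripes if p.place_hairs else ():
        for side in ("top", "bottom"):
            _, vpts = _hex_lattice(
                rng, size_y, w, p.vein_hair_spacing_um, 0.6, 2.0
            )
            for x, y, _i, _j in vpts:
                hx = cx - w / 2.0 + x
                if not (0 <= hx < size_x):
                    continue
                hz = float(_surface_altitude(p, hx, y, side))
                d = _hair_direction(rng, p, side)
                records.append((hx, y, hz, *d, 0.6 * p.hair_length_um, side, "wt", -1, -1, True))

    cols = [
        "root_x_um", "root_y_um", "root_z_um", "dir_x", "dir_y", "dir_z",
        "length_um", "side", "phenotype", "cell_id", "spot_id", "on_vein",
    ]
    hairs = pd.DataFrame(records, columns=cols)
    hairs["in_field"] = (
        (hairs["root_x_um"] >= 0) & (hairs["root_x_um"] < hair_x_max)
        & (hairs["root_y_um"] >= 0) & (hairs["root_y_um"] < size_y)
    )

    # --- rasterize ----------------------------------------------------------
    nz = int(round(p.z_depth_um / p.voxel_z_um))
    ny = int(round(size_y / p.voxel_xy_um))
    nx = int(round(size_x / p.voxel_xy_um))
    vol = np.zeros((nz, ny, nx), dtype=np.float32)
    for rec in hairs.itertuples(index=False):
        root = np.array([rec.root_x_um, rec.root_y_um, rec.root_z_um])
        direction = np.array([rec.dir_x, rec.dir_y, rec.dir_z])
        _render_rod(vol, p, root, direction, rec.length_um, p.hair_peak)

    # vein stripes carry a bright structural band on each surface
    if p.vein_stripes:
        xs = np.arange(nx) * p.voxel_xy_um
        zs = np.arange(nz) * p.voxel_z_um
        for cx, w in p.vein_stripes:
            stripe = (np.abs(xs - cx) <= w / 2.0)
            for side in ("top", "bottom"):
                zc = _surface_altitude(p, cx, size_y / 2.0, side)
                prof = p.vein_band_intensity * np.exp(-((zs - zc) ** 2) / (2 * 2.0**2))
                band = prof[:, None, None] * stripe[None, None, :]
                vol[:, :, :] = np.maximum(vol, band.astype(np.float32))

    vol += p.background
    if p.noise_sd > 0:
        vol += rng.normal(0.0, p.noise_sd, size=vol.shape).astype(np.float32)
    np.clip(vol, 0, None, out=vol)

    # --- masks and bookkeeping ----------------------------------------------
    region_mask = np.zeros((ny, nx), dtype=bool)
    xs = np.arange(nx) * p.voxel_xy_um
    for cx, w in p.vein_stripes:
        region_mask[:, np.abs(xs - cx) <= w / 2.0] = True
    if p.margin_um > 0:
        region_mask[:, xs >= hair_x_max] = True
    analyzed_area = float((~region_mask).sum()) * p.voxel_xy_um**2

    stack = FocusStack(data=vol, voxel_size_um=(p.voxel_z_um, p.voxel_xy_um, p.voxel_xy_um))
    truth = GroundTruth(
        hairs=hairs, region_mask=region_mask,
        analyzed_area_um2=analyzed_area, params=p,
    )
    return stack, truth


# --------------------------------------------------------------------------
# slide scans
# --------------------------------------------------------------------------

@dataclass
class WingOutline:
    """True outline of one synthetic wing: an ellipse plus its hinge point."""

    center_xy: tuple[float, float]
    semi_axes: tuple[float, float]   # (major, minor), px
    angle_deg: float                 # major-axis angle from +x
    origin_xy: tuple[float, float]   # bright hinge point

    def contains(self, x, y, pad=1.0):
        th = math.radians(self.angle_deg)
        dx, dy = x - self.center_xy[0], y - self.center_xy[1]
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        a, b = self.semi_axes
        return (u / (a * pad)) ** 2 + (v / (b * pad)) ** 2 <= 1.0


@dataclass
class SlideParams:
    """Layout of the synthetic slide scan (emulates a 300 dpi 8-bit scan)."""

    width_px: int = 900
    height_px: int = 300
    dpi: float = 300.0
    background: int = 230
    wing_intensity: int = 120
    origin_intensity: int = 205
    wing_semi_axes_px: tuple[float, float] = (14.0, 6.5)
    noise_sd: float = 3.0
    angles_deg: tuple[float, float] = (-40.0, 40.0)
    max_tries: int = 2000

    @property
    def pixel_pitch_um(self) -> float:
        return 25400.0 / self.dpi


def generate_slide_image(
    n_wings: int,
    params: SlideParams | None = None,
    seed: int = 0,
    angles_deg: list[float] | None = None,
) -> tuple[np.ndarray, list[WingOutline]]:
    """Draw ``n_wings`` dark elliptical wings on a bright slide.

    Each wing carries a small bright blob at one end of its major axis
    (the hinge, used as the acquisition origin).  Wings never overlap; if
    they cannot be packed, a ``ValueError`` is raised.

    Returns the 8-bit image and the list of true outlines.
    """
    if n_wings < 0:
        raise ValueError("n_wings must be >= 0")
    p = params or SlideParams()
    rng = np.random.default_rng(seed)
    img = np.full((p.height_px, p.width_px), float(p.background))
    a, b = p.wing_semi_axes_px
    outlines: list[WingOutline] = []
    margin = a + 4
    tries = 0
    while len(outlines) < n_wings:
        tries += 1
        if tries > p.max_tries:
            raise ValueError(
                f"could not pack {n_wings} wings on a "
                f"{p.width_px}x{p.height_px} slide (placed {len(outlines)})"
            )
        cx = rng.uniform(margin, p.width_px - margin)
        cy = rng.uniform(margin, p.height_px - margin)
        if angles_deg is not None and len(outlines) < len(angles_deg):
            ang = angles_deg[len(outlines)]
        else:
            ang = rng.uniform(*p.angles_deg)
        if any(
            math.hypot(cx - o.center_xy[0], cy - o.center_xy[1]) < 2.2 * a
            for o in outlines
        ):
            continue
        th = math.radians(ang)
        ox = cx - 0.8 * a * math.cos(th)
        oy = cy - 0.8 * a * math.sin(th)
        outlines.append(WingOutline((cx, cy), (a, b), ang, (ox, oy)))

    yy, xx = np.mgrid[0 : p.height_px, 0 : p.width_px]
    for o in outlines:
        th = math.radians(o.angle_deg)
        dx, dy = xx - o.center_xy[0], yy - o.center_xy[1]
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        inside = (u / o.semi_axes[0]) ** 2 + (v / o.semi_axes[1]) ** 2 <= 1.0
        img[inside] = p.wing_intensity
        # bright hinge blob
        d2 = (xx - o.origin_xy[0]) ** 2 + (yy - o.origin_xy[1]) ** 2
        blob = inside & (d2 <= 2.0**2)
        img[blob] = p.origin_intensity
    if p.noise_sd > 0:
        img += rng.normal(0, p.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), outlines


# --------------------------------------------------------------------------
# dose-response score tables
# --------------------------------------------------------------------------

@dataclass
class SigmoidParams:
    """Hill-form dose-response curve: bottom + range / (1 + (ec50/c)^slope)."""

    bottom: float = 1.2
    top: float = 12.0
    ec50_mM: float = 2.5
    slope: float = 1.2

    @property
    def range(self) -> float:
        return self.top - self.bottom

    def mean_at(self, dose):
        dose = np.asarray(dose, dtype=float)
        out = np.full(dose.shape, self.bottom, dtype=float)
        nz = dose > 0
        out[nz] = self.bottom + self.range / (1.0 + (self.ec50_mM / dose[nz]) ** self.slope)
        return out


def generate_dose_scores(
    curve: SigmoidParams,
    doses_mM,
    n_wings: int = 60,
    noise: str = "nb",
    nb_size: float = 6.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-wing scores whose per-dose means follow ``curve``.

    ``noise`` is one of ``"nb"`` (negative binomial, dispersion ``nb_size``;
    variance mu + mu^2/size), ``"poisson"``, or ``"none"`` (every wing gets
    the exact per-dose mean).  Returns a DataFrame with columns
    ``wing_id, dose_mM, score``.
    """
    if curve.range < 0:
        raise ValueError("sigmoid range (top - bottom) must be >= 0")
    doses = np.asarray(list(doses_mM), dtype=float)
    if (doses < 0).any():
        raise ValueError("doses must be >= 0")
    if n_wings < 1:
        raise ValueError("n_wings must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    wid = 0
    for dose in doses:
        mu = float(curve.mean_at(np.array([dose]))[0])
        if noise == "none":
            scores = np.full(n_wings, mu)
        elif noise == "poisson":
            scores = rng.poisson(mu, size=n_wings).astype(float)
        elif noise == "nb":
            # NB with mean mu, size theta: p = theta / (theta + mu)
            if mu <= 0:
                scores = np.zeros(n_wings)
            else:
                p_nb = nb_size / (nb_size + mu)
                scores = rng.negative_binomial(nb_size, p_nb, size=n_wings).astype(float)
        else:
            raise ValueError(f"unknown noise model {noise!r}")
        for s in scores:
            rows.append((wid, dose, float(s)))
            wid += 1
    return pd.DataFrame(rows, columns=["wing_id", "dose_mM", "score"])
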