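# Methods

This note documents the models and procedures implemented in `wingspot`,
the parameter choices that matter, what the synthetic benchmarks emulate,
and the numerical decisions taken where the design was genuinely open.

## The assay

The wing-spot test exposes *Drosophila* larvae carrying one copy of the
recessive *mwh* marker to a compound. A genotoxic lesion that removes the
wild-type allele (mutation, recombination, deletion) makes a wing cell
homozygous for *mwh*; that cell, and its clonal descendants, grow 2–4
close-set hairs instead of the normal single trichome. The readout is the
count of mutant cells (or hairs, or clonal spots) per wing as a function of
dose. Wild-type hairs tile both wing surfaces quasi-regularly at
12.5 ± 2.5 µm nearest-neighbour spacing; *mwh* tufts sit well below that,
so a 5 µm nearest-neighbour threshold separates the phenotypes cleanly.

## Acquisition planning (slide_prep)

A desktop scan (300 dpi, 8-bit; 84.7 µm/px) shows wings as dark elongated
blobs. Processing steps and their parameters:

* Threshold at 15% of the inverted image's intensity range; contour
  regularization by morphological opening + closing with a 2 px disk (the
  published procedure names a filter but not which; any contour smoother
  works). Slides whose intensity range stays below 48 grey levels contain
  no dark object, only scanner noise, and yield no regions — a fixed
  fraction of a noise-level range would be meaningless.
* Candidate filtering by aspect ratio λ₁/λ₂ of the pixel-position
  covariance, area, and centroid position, each against an allowed
  interval (mean ± 2 SD of reference wings); degenerate (collinear)
  regions are always dropped. Every discard records the failing criteria.
* The wing origin (hinge) is the intensity maximum after a masked Gaussian
  blur (σ = 3 px) restricted to the region, so the bright slide background
  cannot attract the maximum; ties break to the lowest row, then column.
  The wing axis runs from the origin to the centre of mass.
* Pixels closer than 400 µm to the origin (≈20% of a wing length) or on
  the negative axis side are trimmed; the hinge region carries no
  analyzable blade.
* k-means (10 restarts, fixed seed) partitions the remaining pixels;
  k = round(max_fields · area / reference_area) clamped to [1, max_fields]
  with max_fields = 6, reference_area = the median kept-wing area on the
  slide. Class means are the acquisition positions; being means of mask
  pixels they always lie inside the wing's convex hull.
* Stage mapping X′ = r·R_ϑ(X − X_c) with r the microscope/scan sampling
  ratio. The estimator of X_c and ϑ from the scan's dark border is a
  simple reconstruction (centre of mass + dominant axis of the dark mask);
  a calibrated transform should be preferred when available. Manual
  correction of bad segmentations is supported by CSV overrides rather
  than an interactive editor.

## Hair detection (stack_segmentation)

Focus stacks are (z, y, x) volumes with physical voxel sizes carried
through every computation; orientation and distances are always evaluated
in micrometres so the planar/axial anisotropy (0.64 vs 1 µm in the default
synthetic conditions) cannot bias them.

* **Filtering.** White top-hat per z-slice (disk radius 3 µm > the 2 µm
  hair width, so hairs survive the opening) removes the slowly varying
  out-of-focus background; top-hat is 2-D per slice because that
  background varies with focus depth. A 3-D Gaussian (σ = 0.8 µm, a
  fraction of the hair width) then suppresses acquisition noise.
* **Background.** The histogram mode locates the background level even
  when half the volume is signal; sigma-clipped statistics around the mode
  give the background mean and SD. The watershed stop level is
  mean + 2 SD.
* **Seeds.** h-maxima: the regional maxima of the grayscale reconstruction
  of (filtered − h) under filtered. A maximum survives iff its topographic
  prominence exceeds h; near-equal maxima joined by a saddle shallower
  than h merge into one seed, which is what prevents over-segmentation of
  a single hair with several local peaks. h is a fraction (10%) of the
  average structure-maximum height; because maxima heights are bimodal
  (noise bumps just above the stop level vs hair peaks), the average is
  taken over the upper class of an Otsu split — otherwise thousands of
  noise maxima drag h to the noise floor. The implementation is checked
  against an exhaustive superlevel-set oracle for exact agreement.
* **Watershed.** Seeded flooding in decreasing intensity order, masked at
  the stop level, 26-connected, deterministic tie-breaks. Every labeled
  region contains one seed and no sub-stop voxel.
* **Hair vectors.** Root = brightest voxel (hair sockets image brightly);
  direction = first eigenvector of the intensity-weighted position
  covariance, sign-fixed toward the centroid; length = √λ₁. Intensity
  weighting anchors the orientation to the bright hair core rather than
  the dim watershed halo — this matters inside *mwh* tufts, where
  neighbouring watershed cells share halo; the unweighted (plain
  position-covariance) form is available via a flag. Near-isotropic
  regions (λ₁/λ₂ < 1.5) are flagged ambiguous.

## Region and hair discards

The discard mask is built from the **raw** stack's maximum-intensity
projection — the top-hat would flatten exactly the wide bright structures
(vein bands) the mask must find. The projection is thresholded at its own
background + 2 SD (the projection of many noise slices has a lifted floor,
so its background statistics are estimated on the projection itself); the
binary structure mask is smoothed with a Gaussian of σ = 25 µm (2× the
inter-hair distance), giving a local coverage fraction in [0, 1]. Pixels
with coverage below 0.15 (off-wing background), above 0.55 (veins), or
with a smoothed locally min–max-normalized projection above 0.6 (extended
bright structures) are discarded; the three thresholds were calibrated on
the synthetic fixtures and are exposed in `DiscardParams`. Any hair whose
region footprint touches the mask by one pixel is discarded — growing the
mask can only add discards, never remove them.

Three per-hair consistency filters follow: (1) orientation — a hair whose
direction has negative scalar product with its average neighbour's is
discarded; (2) shape — robust upper bounds (median + max(3.5·1.4826·MAD,
a relative floor) per descriptor) on length and voxel count catch
under-segmented merged objects, which are oversized; the bounds are
one-sided because *mwh* hairs are legitimately short, and anisotropy uses
an absolute blob floor (1.5) instead of a population bound because tuft
hairs have legitimately reduced anisotropy; (3) surface placement —
per-side bounds |z_s| ≤ mean + 2 SD and |φ| ≥ 10% of the mean angle.

## Side assignment and phenotype

Locally the wing is flat, so the surface altitude z₀ at a root is the
mean root altitude of all hairs (both sides) within a 25 µm planar
cylinder; a hair with no neighbour in the cylinder takes its nearest
root's altitude and is flagged low-confidence. z_s = z − z₀ and
φ = arcsin(direction_z) both change sign at the surface: top iff both
positive, bottom iff both negative, disagreement ⇒ discard. A hair is
*mwh* iff its nearest same-side, non-discarded neighbour root lies within
5 µm (3-D Euclidean by default; a planar switch exists — roots of one
cell share the surface, so the difference is negligible). Cells are
single-linkage clusters of same-side mwh hairs at the same 5 µm
threshold; spots cluster cells at 25 µm (2× inter-hair). Both thresholds
are configurable and echoed in output metadata.

## Genotoxicity statistics

Per-wing scores: mwh hairs per mm² of analyzed area, mwh cell count
(headline score), mwh spot count, and the dichotomous >2-hairs indicator.
The dose-response curve is the per-dose mean score. Dose dependency: OLS
of mean score on dose with a one-sided t-test of slope ≤ 0; P < 0.05 calls
the compound genotoxic. Toxic doses must be excluded before testing. The
per-dose two-sample test against control is Welch's t by default (a
rank-sum alternative is provided); multiple doses are reported unadjusted
with an additional Holm column available.

The constrained sigmoid score(c) = bottom + (top − bottom)/(1 + (EC50/c)^slope)
is fit to per-dose means with the saturation enforced (default: the
maximum mean × 1.1, overridable), because toxicity at high doses keeps the
data from reaching the plateau. Internally EC50 and slope are fit on a log
scale for conditioning, with a small multi-start over log-spaced EC50
initializations (shallow slopes put the optimum on a long flat ridge);
Wald 95% CIs use the Jacobian covariance with a t quantile (df = n − 3),
mapped back to natural parameters by the delta method, and the confidence
envelope propagates the same covariance pointwise. The control dose
contributes the baseline exactly (score(0) = bottom) rather than through a
small dose offset; an offset distorts shallow-slope profiles by a few
percent of range at c = 0. EC50 estimates beyond 10³× the largest dose are
flagged extrapolated. Bottom and range absorb any affine transform of the
score axis, so EC50 and slope are invariant to it — this is what makes
automated and manual protocols comparable after scaling.

## Synthetic data: what it emulates, and what it does not

The generator's defaults define the package's standard study conditions:
a 200 × 200 µm field at 0.64 µm/px planar (half the published
instrument's 0.32 µm — the hair width remains ~3 px, so every detection
scale holds at a quarter of the voxel count) and 1 µm axial; two hair
layers 16 µm apart on gently undulating surfaces (1 µm amplitude, 80 µm
period — flat at the 25 µm scale); wild-type roots on a jittered
hexagonal lattice tuned so the measured nearest-neighbour mean is
12.5 µm with a hard 5 µm minimum; hairs as tilted (30°), tapered rods,
thinner at the root than the tip, intensity tapering linearly to 40% at
the tip, with a bright socket at the root (without it, the blur's reduced
support at the rod end moves the observed maximum into the shaft) and a
mild axial elongation standing in for bright-field depth of field; *mwh*
cells as 2–4 hairs on small rings (pairwise 3.4–4.8 µm) that fan outward
and vary in length, as real tufts do; vein stripes as dense short hairs
(4 µm spacing) under a bright band; an optional hair-free off-wing
margin; background 50 with Gaussian noise SD 3 (≈2% of the 150 hair peak,
consistent with a cooled CCD); and an explicit seed everywhere — no
global random state. The lattice overhangs the field by about one hair
length so the boundary looks like a continuing wing; overhang hairs are
marked `in_field = False` and excluded from benchmarks.

Score tables draw per-wing counts as negative binomial around the sigmoid
mean (size θ = 6, ≈2× overdispersion at mid scores; Poisson and noiseless
modes available), 60 wings per dose by default, doses on the
0.3–10 mM-style grid with a zero control.

What passing the synthetic benchmarks does **not** show: robustness to
real optics (PSF, refraction through the membrane, uneven illumination),
to folded or torn wings, to true vein anatomy, or to the actual error
rates of real slides — the published image-derived aggregates (specificity
and coverage of acquisition, hairs per wing, false positives per wing,
discard percentages) cannot be reproduced without the original slides.
The synthetic analogs test the same mechanisms (detection recall, side
separation, vein false-call suppression, dose-independence of false
calls) under controlled conditions. Likewise the reference-profile fits
regenerate surrogate dose tables from the published EC50/slope values and
check the fitting machinery round-trip; they are not a reanalysis of the
original measurements.

## Benchmark problem sizes

The standard validation run uses 20 fixture stacks (three single-cell
clones and one vein stripe each), 100 random volumes up to 32³ for the
seed oracle, 1000 null simulations for the dose-dependency test size
(with one independent confirmation batch if the first falls outside the
binomial band — a calibrated test lands outside a 95% band in 5% of seed
draws by construction), 200 dose-response replicates for EC50 recovery
and CI coverage, and 50 slide fixtures for acquisition geometry.

## Known limitations

* The slide-frame (stage transform) estimator is a rough reconstruction;
  calibrate the transform on the instrument instead where possible.
* Under-segmentation of very dense tufts is mitigated but not eliminated;
  recall degrades on large multi-cell clusters (and is asserted only to
  degrade monotonically).
* The *flr* (flare) marker of the classical two-marker assay is out of
  scope; only *mwh* is detected, so twin-spot analysis is unavailable.
* Analyzed area counts the projected (single-surface) field area minus
  the discard mask; it does not model true 3-D wing surface area.
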