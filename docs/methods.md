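# Methods

This note documents the models, conventions and numerical choices behind
`tps3d`, in the spirit of a package vignette: what each stage assumes, which
parameters matter, and what the synthetic validation does and does not show.

## Coordinate and indexing conventions

Arrays are `(channel, z, y, x)`; voxel indices are 0-based and all intervals
are half-open.  The physical coordinate of voxel `i` along an axis with
voxel size `v` is `i * v` μm (a voxel-centre grid anchored at 0).  Depth 0 is
the first acquired plane.  All public quantities are in micrometres and
percent.

## The phantom generator

The generator emulates a cleared, thick (default 150 μm) tissue section
imaged by spinning-disk confocal in three channels: nuclear dye, membranous
PD-L1 marker, lipophilic counterstain.  Defaults describe the study
condition used throughout the tests: a 512 μm square lateral field at
1 μm/voxel — a scaled-down stand-in for an 8 mm × 8 mm region of interest —
150 μm deep, with ~3,000 cells.

**Cells.**  Cells are spheres with uniform-intensity nuclei
(radius ~ N(4, 0.5²) μm, truncated at ±2 s.d.) and, for PD-L1-positive tumor
cells, a uniform annular membrane shell (thickness 1.5 μm) in the marker
channel; all cells contribute a dimmer cytoplasmic ball to the lipid
channel.  Uniform (rather than tapered) nuclear intensity is a deliberate
choice: on a noise-free two-level image any threshold between background and
signal recovers the exact rasterized cross-section, which makes geometric
ground-truth recovery well-posed and testable; realism is carried by the
noise model instead.  Placement is dart-throwing with a minimum
centre-to-centre distance (default `2 × max radius + 1` μm, so cells never
overlap and — provably — neither do their planar cross-sections), with a
placement margin of `radius + membrane + 1` μm from every face.  Requesting
more cells than the field can hold at the minimum spacing raises an explicit
packing error.  An optional lateral tumor box places tumor cells inside and
non-tumor cells outside, giving the tumor region spatial structure for
masker evaluation.

**Positivity.**  Each tumor cell draws its PD-L1 status from a
depth-dependent probability evaluated at its centroid depth: constant,
linear (top → bottom) or piecewise profiles, all constrained to [0, 1].

**Noise.**  Clean signal plus a constant background (default 50), Poisson
shot noise and Gaussian read noise (σ = 2).  The per-channel `snr` is the
peak signal amplitude divided by the background noise s.d.
(`sqrt(background + read_noise²)` ≈ 7.35); the default `snr = 10` puts
nuclei ~10σ above background, consistent with the strong stain-over-
autofluorescence contrast of cleared-tissue imaging.  `snr=None` produces a
noise-free, zero-background volume for exact-recovery tests.

**What the phantom does not emulate.**  Optical PSF blur and depth-dependent
attenuation, autofluorescence structure, irregular nuclear shapes,
overlapping/crowded nuclei and tissue texture.  Real tissue is also far
denser per plane than the 3-D non-overlap constraint allows; masker tests
therefore use thin-slab phantoms where per-plane nuclear coverage (~10–30 %)
matches tissue.  Passing the synthetic gates shows the chain is correctly
assembled and unbiased under the stated imaging model — not that it matches
trained-model accuracy on patient images.

## Nuclear segmentation

Per plane, on the nucleus channel: Li minimum-cross-entropy threshold →
binary hole filling → connected components (rough labels) → Euclidean
distance transform; its local maxima (minimum separation = expected nucleus
radius, default 4 μm) seed a watershed on the negated distance transform
within the foreground.  The watershed can only split rough components, never
merge them; components that received no seed keep their rough label.
Objects smaller than 25 % of the expected nucleus cross-section are removed.
Segmentation is strictly 2-D — planes are processed independently, so one
physical cell contributes a detection to every plane its nucleus crosses;
per-plane TPS is defined over exactly these detections.

**Threshold guard.**  On nearly-empty planes Li's fixed point can sit inside
the background noise and flag half the plane as foreground.  The
implementation therefore requires the foreground/background class means to
be separated by at least `min_contrast` (default 5) background standard
deviations; until they are, Li is re-applied to the above-threshold tail
(classical iterative tail thresholding, ≤ 12 rounds), and if separation is
never achieved the plane is declared background-only.  `min_contrast` must
be comfortably below the image SNR.  An optional Gaussian pre-filter
(default off) is available for low-SNR material.

**Count-error metric.**  Per image, `|predicted − true| / true`; the summary
is the mean and the n−1 standard deviation across images (0.0 reported for a
single image).  True counts of zero are rejected — the relative error is
undefined — so phantom evaluations restrict to planes whose geometric truth
count is positive.  The geometric truth for a plane is the number of truth
spheres whose rasterized cross-section (voxel centres inside the sphere)
meets the same 25 %-area cutoff the segmentation applies; it is computed
from coordinates alone, with no image processing.

## Tumor masking

The masker contract is `predict(plane) -> boolean mask`, deterministic given
parameters, so a trained segmentation network can replace the baseline.  The
shipped baseline thresholds nuclear foreground (same contrast-guarded Li) and
smooths it with a wide Gaussian (default σ = 20 μm) into a local
nuclear-coverage map, masking where coverage exceeds `min_density`
(default 0.05, i.e. ≥ 5 % of local area covered by nuclei), then closes with
a 10 μm disk.  It is a density heuristic, documented as a baseline, not a
reproduction of a learned model.  Tumor membership of a nucleus is
centroid-in-mask — unambiguous for partial overlaps.

Cell-instance accuracy is precision-style (the fraction of predicted-tumor
cells confirmed tumor in truth), reported with the symmetric overall
accuracy alongside; it is undefined (explicit error) when nothing is
predicted tumor.

## Membranous classification

The annulus of a nucleus is its label's dilation by `annulus_width_um`
(default 1.5 μm, nearest-label tie-break so annuli never overlap) minus the
nucleus.  Features: annulus mean, annulus 90th percentile, annulus-to-
nucleus-interior mean ratio (the explicit membranous-versus-cytoplasmic
discriminator a CNN would learn implicitly), and ring coverage — the
fraction of annulus pixels above a per-plane background reference, the Li
threshold of the marker plane, which keeps the module self-calibrating.
The default rule is positive iff coverage ≥ 0.3 **and** ratio ≥ 1.2, both
comparisons inclusive; the low thresholds encode "any membranous staining".
These two cut-offs are a stated convention, not an inferred operating point;
they are monotone (raising either can only turn positives negative) and
config-exposed.  Cells whose annulus is empty (fully squeezed off the image)
are flagged unreliable and excluded from both numerator and denominator of
the TPS, with the exclusion counted in the QC report.

The consensus protocol for building labeled sets marks a cell positive only
if all four annotations (two readers × two rounds) are positive.

## TPS, depth profile, heterogeneity

TPS is `100 × positives / tumor cells`, undefined for zero tumor cells.
Categories partition [0, 100] as [0, 1) / [1, 50) / [50, 100]; "1–49 %" is
read as [1, 50) so no score falls between categories.  The depth profile
bins detections by nucleus-centroid depth into half-open 5 μm windows
anchored at depth 0 (a detection exactly at the full depth joins the last
bin) and aggregates all planes within each window.  Bins with no tumor cells
are undefined and excluded from max/min/average — zero-filling would bias
the max–min spread.  The headline "3-D average" is the mean of defined
per-bin scores (matching per-depth plotting); the cell-pooled alternative is
always computed and reports name which is shown.  A profile crosses a
clinical boundary when its defined bin scores straddle 1 % or 50 %; the
cohort summary reports the mean max–min spread, the count above 10
percentage points, and the category-crossing breakdown per boundary.

## Pseudo-needle biopsy

The track is axis-aligned (length along x by default), default
8 mm × 1 mm × full depth, centred on the intensity-weighted centre of mass
of the nucleus channel (a tissue-density proxy; channel selectable).  A
track that would exceed the lateral bounds is shifted inward to fit —
necessary because the full-length track spans the entire field, where any
off-centre centre of mass would otherwise always fail — and a track longer
than the volume clamps to the full extent with a warning.  Cropping returns
the subvolume plus the physical offset mapping crop coordinates back to the
parent frame; cropping the ground truth with the same half-open box yields
the consistent cell subset.

## Concordance statistics

Weighted kappa uses disagreement weights `|i−j|/(K−1)` (linear, default) or
its square (quadratic) over the ordered categories, with
`κ = 1 − Σw·O / Σw·E`; the choice of weights is a mandatory, logged
parameter.  Bands: > 0.8 excellent, > 0.6 good, else below good.  A table
with all mass in a single cell for both raters has `Σw·E = 0` and raises an
explicit degenerate-table error.  Percent concordance is `100 × trace / n`.

## Validation design and statistical conventions

The synthetic gates (in `tests/test_acceptance.py` and
`scripts/acceptance.py`) use these conventions:

* **Per-bin recovery.**  For a constant-positivity phantom, the binomial
  experiment of bin *k* is the set of truth tumor cells whose centroid lies
  in the 5 μm slab (the same assignment the truth profile uses), so
  `SE_k = 100·sqrt(p(1−p)/n_k)`.  The measured bin additionally borrows
  detections from neighbouring-slab cells, which only lowers its variance,
  so this SE is a (mildly conservative) upper bound.  Edge bins with no
  truth centroids (axial placement margins) cannot form an SE and are
  skipped.  The average-TPS check uses `SE = 100·sqrt(p(1−p)/N)` with `N`
  all truth tumor cells.
* **Problem sizes.**  Full-scale recovery runs use 512 × 512 × 150 voxels
  with ~3,000 cells; segmentation and needle checks use 256 μm fields
  (400 and 160 cells), chosen to keep a complete run at desk scale while
  leaving ≥ 25 informative depth bins.
* **Needle equivalence.**  Exact profile equality between "crop, then
  score" and "score, then restrict to the crop box" holds when no cell
  straddles the crop boundary; the check therefore renders a corridor
  phantom (cells within reach of the boundary removed from a sampled truth)
  in noise-free mode, where thresholds are content-independent.
* **Synthetic cohort.**  The 33-case heterogeneity summary draws per-case
  base positivity from a mixture (35 % below 1 %, 50 % uniform 1–30 %, 15 %
  uniform 50–80 %) with mild linear depth gradients (slope ~ N(0, 3 %)),
  1,200 cells per case, and profiles computed from truth labels.  With
  ~45 tumor cells per bin, bin-level sampling noise contributes several
  percentage points to the max–min spread, so the cohort's spread statistics
  are dominated by counting statistics at this scale — they exercise the
  summary machinery rather than estimate tissue heterogeneity.

## Known limitations

* Segmentation is 2-D by design; no 3-D linking or per-cell deduplication
  across planes is attempted, so "cells" in all outputs are per-plane
  detections.
* The baseline masker cannot separate tumor from non-tumor tissue of equal
  nuclear density; that distinction is the job of a plugged-in trained
  model.
* The classifier thresholds assume marker background is stable within a
  plane; strong spatially varying background would call for a local
  reference.
* `min_contrast` ties detection to image SNR; very low-contrast material
  (SNR ≲ 6) needs the knob lowered and the Gaussian pre-filter enabled.
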