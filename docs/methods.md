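# Methods

This note documents the models behind `cytoquant`, the parameters that
matter, the numerical conventions, and what the synthetic data do and do not
establish.  The library under `src/cytoquant/` holds all computation; the
numbered scripts under `analysis/` and `scripts/acceptance.py` are thin
drivers over it and constitute the command-line surface of the package.

## Synthetic epithelium (`cytoquant.synthetic`)

The generator emulates the surface view of a non-proliferative, curved
epithelial monolayer of large polygonal cells (a stage-10 follicular
epithelium) as seen in a two-channel confocal stack.

**Geometry.**  Cell outlines are the Voronoi tessellation of jittered-grid
seed points (epithelia are near-hexagonal; no generative model of the real
tissue is attempted).  The tissue surface is an elliptic paraboloid dome;
`curvature_sag_um` is the peak-to-corner z offset (a paraboloid cannot be
constant along a rectangular field edge, so "edge" is taken at the corners).
The dome is centered inside the stack, and generation refuses specs whose
stack cannot contain the sag plus one plane of margin on each side.

**Multinucleation.**  A multinucleated cell is rendered by merging `k`
adjacent seed cells (`nuclei_per_multi_cell`, default 2): the shared
interface carries no membrane signal and each constituent seed contributes
one nucleus at its region centroid.  Partners are chosen along the longest
shared interface — a binucleated cell arises from a failed division whose
daughters share a full division plane — never across a corner sliver, where
point-spread tails from the flanking junctions would re-draw a spurious
boundary.  Exactly `round(fraction · n_cells)` cells are multinucleated,
which makes the planted truth exact rather than binomial.

**Rendering and noise.**  The membrane channel is the boundary skeleton
(dilated to `membrane_width_px`) placed on every plane within ±1 plane of
the local surface z; the nuclear channel is one 3D Gaussian blob per nucleus
(σ = `nucleus_radius_um`/2, isotropic in physical units) sitting on the
surface.  Both channels receive a lateral Gaussian PSF blur
(`psf_sigma_px`), then Poisson shot noise (`poisson_scale` counts per
intensity unit) and additive Gaussian read noise (`gaussian_sd`) — the
standard fluorescence camera model.  All randomness flows through one
`numpy` generator seeded from the spec; identical specs reproduce stacks
bit-for-bit.

**Study conditions.**  Defaults: 384×384 px at 0.4 µm/px (~150 µm field),
12 planes 1 µm apart, 390 cells (≈8 µm across), sag 4 µm,
`poisson_scale` 0.1, `gaussian_sd` 8.  Cell size and intensity
distributions are calibrated only so that automated segmentation is
feasible, not to match real egg chambers.  The field is deliberately large
relative to a cell: excluding border-touching cells disfavors the larger
multinucleated cells, and this size bias scales with the cell-to-ROI size
ratio (at these conditions it depresses the recovered ratio by < 0.01 at a
planted fraction of 0.2).

**Not emulated:** photorealistic optics, stage drift, photobleaching,
time-lapse mitosis, cell-size heterogeneity beyond grid jitter, nuclear
texture, and segmentation-hostile artifacts (debris, fusing membranes).
Passing recovery tests therefore demonstrates correctness of the
measurement chain, not robustness to every real-world acquisition defect —
on real data the pipeline retains the manual-correction hook below.

## Projection (`cytoquant.projection`)

Nuclei are detected in 3D by Otsu thresholding of the nuclear channel,
discarding components under `min_volume_vox` (default 30 ≈ half a nucleus at
default sampling) and taking intensity-weighted centroids.  Components are
numbered in raster order of their first voxel, which makes the nearest-anchor
tie-break deterministic.

For every pixel the anchoring nucleus is the nearest by Euclidean xy
distance; the projected window contains all planes whose centers lie within
`thickness_um`/2 (default 1 µm, inclusive) of the anchor's z, falling back
to the single nearest plane if that interval is empty.  The default reducer
is `max` (surface views are maximum-intensity projections elsewhere in this
workflow); `mean` and `sum` are available.  Axis order is (z, y, x),
0-based, pixel-center convention; physical units come from the sidecar
metadata.  `mid_stack_projection` provides the fixed-plane baseline the
local projection is judged against.

## Multinucleation scoring (`cytoquant.multinucleation`)

The central ROI is a rectangle shrunk by `margin_fraction` per side
(default 0.2 in the function signature; the analysis uses 0.10, which still
excludes the rim where projection could miss membrane/nuclei while keeping
~200 scoreable cells per chamber).  An `adaptive` mode erodes the Otsu
tissue foreground by a fraction of its equivalent radius for tissues that do
not fill the frame.

Cells: Gaussian smoothing (σ = 1.2 px) of the membrane channel, seeds from
h-minima (h = 0.25 of the smoothed intensity range — deep enough to ignore
noise pits, shallow enough to keep one seed per true cell), seeded watershed
within the ROI, regions < 80 px dropped.  A featureless membrane channel
degenerates to a single region filling the ROI.  Border handling: regions
touching the ROI border are **kept in the label map but flagged**; the
ratio/frequency statistics exclude them.  (Discarding them outright would
contradict recording a `touches_border` flag per cell, and QC needs to see
them.)  Nuclei: Otsu → hole filling → distance-transform watershed with
peaks ≥ 5 px apart → objects < 25 px dropped.

Counting assigns each nucleus to the cell label under its centroid;
centroids on background are tallied separately (`n_unassigned`).  Statistics
run over *qualifying* cells (≥ 1 nucleus, interior): ratio = total nuclei /
cells (hence always ≥ 1), frequency = % with ≥ 2 nuclei.  Zero-nucleus cells
indicate segmentation errors and are reported as a QC count — the automated
analogue of the manual validation step this workflow assumes.  Label maps
round-trip through 16-bit TIFF so a hand-corrected map can replace the
automatic one.

The Δ ratio subtracts the mean control ratio of the *same replicate*;
`assemble_screen` enforces the pairing through a `replicate` column and
refuses records without same-replicate controls.

## Constriction kinetics (`cytoquant.constriction`)

Traces must be ≥ 6 frames, uniformly sampled within 1 %.  Onset: t₀ is the
frame before the first frame whose diameter has dropped below
(1 − `delta_rel`)·d[0] (default 5 %) with the trace non-increasing — within
a tolerance of half that drop — over the next `persist` = 3 frames.  Both
knobs are exposed; the persistence test is what makes a noisy plateau not
trigger.

Rate: among all windows of 4 consecutive post-onset frames whose normalized
diameters lie in [0.40, 0.80] (endpoints inclusive), each gets an OLS fit of
absolute diameter on time; windows with R² ≤ 0.95 are rejected, the max-R²
window wins, ties go to the earliest.  R² is 1 − SSres/SStot on the 4
points; a flat window (SStot = 0) has undefined R² and is skipped.  Traces
with no in-band window or no window passing R² raise — they are excluded,
mirroring how such traces are flagged rather than force-fitted.

A consequence worth stating: at 2 % measurement noise the R² gate itself
excludes roughly 5–10 % of genuinely constant-rate traces (four points give
the fit only two residual degrees of freedom), independent of implementation.
The exclusion rate shrinks with noise; the rate estimate on accepted windows
is unbiased to within ~1 %.  Trace defaults (d₀ = 8 µm — the ring of an
≈8 µm cell — sampled every 1 min for 20 min, onset at 2 min, tail plateau at
0.25·d₀) were chosen once as realistic movie conditions under which the
4-point window spans a third of the constant phase.

`mean_trace_with_sd` aligns normalized traces at t₀ and reports pointwise
mean and sample SD (missing where < 2 traces overlap), the input for
mean ± SD cohort plots and fixed-timepoint group comparisons.

## Intensity and failure scoring (`cytoquant.intensity`)

ROI semantics follow interactive line-ROI conventions: a circular ROI of
width w is the annular band within w/2 of the circle path, a segmented line
of width w is the band within w/2 of the polyline (with round end caps), a
disk ROI is a filled circle; membership is by pixel-center distance.
Background correction subtracts the mean of a 10 px cytoplasmic disk from
the ROI mean measured on a 2-plane z-sum projection, making the corrected
value invariant to any global additive offset.

Event scoring drops cells above `max_area_px` (prior-failure suspects; no
universal value exists, so it is a required parameter — `default_area_cap`
offers 2× the median pre-division area of the same dataset) and completed,
non-regressing divisions observed < 20 min.  Events that neither completed
constriction nor regressed are censored (movie ended mid-furrowing) and
excluded with a QC count; the three categories — success, regression before
constriction completed, regression after — partition everything that
remains.  Both filters are row predicates, so their order is irrelevant.

## Statistics (`cytoquant.stats`)

Group comparisons use the unpaired two-sided Mann–Whitney U test, computed
by `scipy.stats.mannwhitneyu`: exact enumeration when the combined sample is
≤ 12 without ties, otherwise the normal approximation with tie and
continuity corrections (the switch point is exposed as a module constant).
Tests validate the exact path against full labeling enumeration.

Screen calls: enhancer if p < α and median Δ > 0, suppressor if p < α and
median Δ < 0, else no effect (α = 0.05 by default; the numeric rule is
stated explicitly here because no field-wide convention fixes one).  P-values
are uncorrected across targets, matching the per-experiment control design;
a Benjamini–Hochberg column is available but off by default.  Under a
simulated null the call rate matches α to within binomial error.

## Problem sizes

The test suite and acceptance script run the recovery grid at 4 fractions ×
10 stacks (~200 scored cells each), one domed noise-free stack for the
projection comparison, 100-trace constriction cohorts, 1000-replicate null
calibration, 1000-window least-squares checks, and 200-event logs — sizes at
which every Monte-Carlo bound in the tests has comfortable margin on a
single CPU.

## Known limitations

* Segmentation parameters (smoothing σ, h-minima depth, minimum areas) are
  tuned to the synthetic rendering scale; real acquisitions will need the
  config knobs and possibly the manual-correction TIFF round-trip.
* The centroid-containment rule for nucleus assignment can misassign a
  nucleus whose centroid falls on a membrane pixel of a neighboring cell in
  heavily blurred data.
* Onset detection assumes a plateau precedes constriction; movies starting
  mid-constriction raise instead of guessing.
* The border-exclusion size bias (large cells excluded more often) is
  inherent to per-cell border filtering; it is kept small by field geometry
  here but should be remembered when comparing tissues with very different
  cell sizes.
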