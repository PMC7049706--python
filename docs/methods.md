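# Methods

`speckquant` quantifies single-molecule RNA FISH (smFISH) images of adherent
cells: it segments nuclei from DAPI, approximates whole-cell territories,
detects RNA speckles in 3D, counts them per nuclear and cytoplasmic
compartment, and compares the per-cell cytoplasmic ratio between cell
populations. Because such experiments rarely deposit raw image stacks, the
package ships a synthetic-field generator with exact ground truth so that
every stage is validated end-to-end against known answers.

## The measurement model

A field is a multi-channel 3D stack `(z, y, x)`: one DAPI channel and one or
two FISH channels (e.g. *Malat1*, *Neat1*). The default acquisition geometry
is 0.25 um optical sections covering ~10 um of depth (41 slices) with
0.26 um in-plane pixels, so voxels are anisotropic (z coarser than xy) and
3D connectivity is always exercised under anisotropy.

### Nucleus segmentation (2D)

Nuclei are segmented from the z-projection of the DAPI stack (maximum
projection by default — it preserves the brightness of condensed mitotic
chromatin; mean projection is available). The chain is: Gaussian smoothing
(sigma 1.2 px), Otsu foreground threshold, Euclidean distance transform,
h-maxima seeding (h = 2 px), marker-controlled watershed. Objects smaller
than `min_area_px` (150 px) are kept only as micronucleus candidates;
objects touching the field border are flagged and excluded from statistics
because their territory is truncated. The smoothing sigma is deliberately
light: DAPI SNR is high, and heavier smoothing dims micronuclei (~0.8 um
radius, a few pixels across) below the foreground threshold.

Because every threshold is data-relative (Otsu), segmentation is exactly
invariant to adding a constant intensity offset.

### Interphase / mitotic classification

Each nucleus gets two features: mean projected DAPI intensity within its
mask, and a texture score — the standard deviation of the locally
mean-subtracted intensity (5 px window) within the mask, the simplest
statistic that separates coarse condensed chromatin from smooth interphase
chromatin. A nucleus is called mitotic iff both features reach their
thresholds. Thresholds can be configured; by default they are
auto-calibrated per field as the Otsu two-class split of each feature,
floored at a minimum fold over the field median (1.4x for intensity, 1.6x
for texture). The floor matters: an unguarded two-class split forces a
boundary even on a homogeneous all-interphase field and would fabricate
mitotic calls; with the floor, a mitotic-free field produces none, while
genuinely mitotic nuclei (about twice as bright, several-fold coarser) clear
it easily.

### Micronuclei

Sub-minimum-area DAPI objects are micronuclei if their area is strictly
below 20% of the field's median main-nucleus area and their centroid lies
within 3 median-equivalent-radii of a main nucleus; each is assigned to the
nearest one. The area bound is exclusive: an object exactly at the cutoff is
not a micronucleus. Candidates with no main nucleus in reach are logged and
left unassigned.

### Cell territories and cytoplasm

Without a membrane marker, the whole-cell region of each nucleus is the set
of pixels whose nearest nucleus pixel (Euclidean, isotropic in y, x) belongs
to it — a generalized Voronoi tessellation of the nucleus masks. Equidistant
pixels tie-break to the lower nucleus label; this deterministic rule is the
one place where relabeling nuclei does not commute with the tessellation.
The implementation computes one exact distance transform per nucleus label
and takes the argmin, which realizes the rule exactly (a watershed on the
joint distance transform is equivalent away from ties but its queue order
does not guarantee the tie-break). An optional reach cap (in um) leaves
far-field pixels unassigned; the default is uncapped, matching confluent
cultures. The cytoplasm map is the exact per-pixel set difference
cell minus nucleus, so nucleus ∪ cytoplasm = cell holds pixel-for-pixel by
construction and is asserted, not approximated.

### 3D speckle detection

Per FISH channel: light isotropic Gaussian denoising (0.7 px, below the
speckle scale), then per-slice local background correction by white top-hat
with a disk (radius 8 px, ~4x the expected speckle radius; per-slice because
widefield background varies along z), then a single Otsu threshold per
channel per field computed on a 256-bin histogram of the full 3D corrected
stack (ties toward the lower threshold; a per-slice mode exists behind a
flag for sensitivity analysis). Binarized voxels are grouped into
26-connected components (face, edge and corner adjacency); objects smaller
than 3 voxels are discarded as noise. The denoising step exists because the
top-hat of pure shot noise is heavy-tailed enough to capture the Otsu
threshold inside the noise floor; after denoising the threshold lands
between background and puncta across the whole SNR range simulated.

Each object reports voxel count (and um^3 via the voxel size), unweighted
centroid, and mean intensity measured on the *original* volume — background
correction affects detection only, never measurement. Compartment assignment
uses the rounded (y, x) of the centroid against the nucleus and cytoplasm
maps (the compartments exist only in projection space); a speckle is never
split across compartments, and speckles outside any territory or in an
excluded border cell are dropped from per-cell statistics with a log entry.
By construction, nuclear + cytoplasmic = total assigned, exactly, per cell
and channel.

### Statistics

Per cell and channel: nuclear, cytoplasmic and total counts; the cytoplasmic
ratio x = n_cyto / n_total (undefined and excluded from ratio tests when
n_total = 0, but kept in proportion tests with has_cytoplasmic = false); and
the transformed ratio x^(1/5). Group comparisons:

- **Mann–Whitney U** (two-sided) on transformed ratios: exact enumeration
  when the combined sample is at most 20 without ties, otherwise the normal
  approximation with tie-corrected variance and no continuity correction.
- **Kolmogorov–Smirnov** two-sample, asymptotic p.
- **Pearson chi-squared** (no continuity correction) on the
  cells-with-cytoplasmic-speckles contingency table, with a warning when any
  expected count is below 5.
- **Speckle sizes**: MW plus median/quartile summaries (linear-interpolation
  quartiles), at per-speckle or per-cell-mean granularity.

The x^(1/5) transform is monotone, so it cannot change the MW result and
changes the KS p only through the asymptotic approximation; both transformed
and raw results are emitted rather than guessing the intent of transforming
before rank-based tests. No multiple-testing correction is applied to the
primary p-values; a Bonferroni column is emitted alongside for transparency.
`length_fold` rounds a length ratio half-away-from-zero for report
annotations of deleted-region sizes (1655 bp / 148 bp -> 11).

## The synthetic-data generator

`generate_field(params, seed)` renders one field plus exact truth tables and
label volumes; identical inputs give bit-identical outputs (a single
`numpy` PCG64 stream). What it emulates:

- **Nuclei** as non-overlapping soft-edged ellipsoids (sigmoid falloff,
  edge softness 8% of radius), interphase radius 3.6 um, mitotic 2.2 um
  (mitotic nuclei are smaller), each with ±8% radius jitter, placed by
  rejection sampling with a 0.8 um separation margin. Overcrowded requests
  warn and report the count actually placed.
- **Mitotic chromatin** as a 2x DAPI gain times a band-limited
  multiplicative texture (Gaussian-filtered noise at 0.5 um scale, relative
  amplitude 0.4) — the features the classifier uses (intensity, texture,
  size), nothing more.
- **Micronuclei** (Poisson rate per cell, default 0.1) as ~0.8 um bodies
  placed just outside the parent nucleus.
- **Speckles** as anisotropic Gaussians, sigma (0.4, 0.25, 0.25) um, peak
  150 intensity units, per-cell counts from a gamma-Poisson law
  (mean 8, dispersion 0.15 — over-dispersed, as real per-cell FISH counts
  are) and a per-channel cytoplasmic placement probability (default 0.05,
  WT-like; an elevated-export condition uses 0.30). Nuclear speckles are
  uniform in the (shrunken) nucleus ellipsoid; cytoplasmic speckles uniform
  over the cell's truth territory within 4 um of the nucleus boundary.
- **Background and noise**: flat offset 20 plus a linear shading gradient
  (amplitude 8), Poisson shot noise and Gaussian read noise (sigma 2),
  giving SNR ~ 10 at speckle peaks. Both noise sources can be disabled for
  noiseless truth-consistency checks.

Two structural choices deserve emphasis. First, truth speckles within a cell
are kept at least one *resolution ellipsoid* apart — (2.2, 1.7, 1.7) um in
(z, y, x). Two diffraction-limited puncta closer than the optical resolution
are a single object to any threshold-and-label detector, so truth entities
below that separation would measure the placement law, not the detector;
spots that cannot be placed in a crowded (typically mitotic) nucleus are
dropped and never enter the truth tables. Second, the truth territory map is
built from the true nucleus masks with the same exact nearest-nucleus rule
the pipeline uses, while the pipeline's map comes from its *own*
segmentation — so compartment agreement genuinely tests the detection path.

What the generator does **not** emulate: real PSFs (no convolution beyond
the Gaussian approximation), photobleaching, chromatic shift, nuclear
sub-structure, cell-to-cell intensity variation, or touching/overlapping
nuclei in dense monolayers. Passing tests therefore demonstrate the
algorithm's correctness and its behavior under shot noise, shading,
anisotropy and over-dispersed counts — not robustness to every artifact of
real microscopy.

## Problem sizes and numerical choices

Validation runs use fields of 41 x 256 x 256 voxels with 10 cells
(mitotic fraction 0.15), which a laptop CPU processes in ~2 s per field:

- ground-truth recovery: 10 fields (~100 nuclei, ~800 speckles);
- cohort comparison: 20 fields per group, ~200 cells per group, cytoplasmic
  fractions 0.05 vs 0.30;
- null calibration: 200 replicate cohort pairs of 200 cells drawn directly
  from the generator's count law (gamma-Poisson totals, binomial
  nuclear/cytoplasmic split) — the statistics stage consumes per-cell
  counts, so calibrating its type-I error does not require rendering
  40,000 images' worth of pixels.

Degenerate inputs are defined, not exceptional: a constant projection or a
constant FISH volume yields empty tables; a constant volume given to the
Otsu threshold raises a degenerate-input error that the detection chain
catches as "speckle-free field". Ties: Otsu ties break toward the lower
threshold (first argmax); tessellation ties to the lower label; watershed
seeds are labeled in scan order. All coordinates are 0-based (z, y, x).

## Known limitations

- Cell territories are a geometric approximation; against membrane-marker
  segmentation the cytoplasmic assignment of peripheral speckles would be
  less certain than the synthetic benchmarks suggest.
- The phase classifier is a two-threshold rule on two features; it cannot
  distinguish mitotic sub-stages and will mislabel, e.g., apoptotic bright
  nuclei as mitotic.
- Speckle counts in crowded nuclei are resolution-limited by design; the
  detector reports merged objects as one speckle, which is the correct
  behavior for the data it would see but undercounts true molecule numbers.
- The exact Mann–Whitney branch is used only for tie-free combined samples
  of at most 20; with ties it falls to the tie-corrected normal
  approximation regardless of size.
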