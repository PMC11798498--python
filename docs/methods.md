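# Methods

This note documents the models, conventions and numerical choices behind
`mpmorph`, and what the synthetic-data tests do and do not demonstrate
about real micrographs and load logs.

## Imaging model and calibration

A micrograph is an H×W×3 array of intensities normalised to [0, 1] by the
container maximum of the source bit depth (255 or 65535). Normalisation by
the container maximum — not by the per-image maximum — is deliberate: the
global binarisation threshold of 0.5 is only meaningful on a fixed scale.
Grayscale sources are broadcast to three identical channels; alpha is
dropped. Images smaller than 3×3 are rejected because the Sobel operator
needs a full 3×3 neighbourhood.

The μm-per-pixel calibration is a **required** user input with no default.
The pixel pitch of a microscope acquisition cannot be recovered from pixel
data, and silently guessing one would corrupt every μm-denominated number
downstream. Builtin reference tables of already-calibrated particle
dimensions for three commercial aligners (Essix Ace, 8 particles; Ghost
Aligner, 6; Invisalign, 3) are shipped as packaged CSVs; one Ghost row has
a known area but unresolvable axes, kept as first-class missing values
(NaN) rather than dropped at load time — each consumer declares drop-or-fail
behaviour.

## Segmentation: k-means and Partition Entropy

The image is flattened to n = H·W RGB points in raster order (a lossless,
invertible map). Lloyd's algorithm runs with:

* **Initialisation**: k distinct data points drawn uniformly without
  replacement under the caller's seed. One restart by default; a
  `restarts` option keeps the lowest within-cluster sum of squares.
* **Stopping**: early exit when centroids are unchanged between successive
  iterations, otherwise a cap of 100 iterations; a `converged` flag
  records which occurred. (On noisy natural backgrounds with large k the
  assignment can cycle near a fixed point; the cap bounds the cost and the
  flag makes it observable.)
* **Empty clusters**: re-seeded from the point farthest from its current
  centroid.
* **Determinism**: identical seed ⇒ bit-identical labels and centroids.

Each partition is scored with the Partition Entropy over cluster
occupancies, PE(k) = Σ P_i ln P_i (natural log), a non-positive quantity
bounded below by −ln k, equal to 0 only when one cluster holds everything.
The optimal k maximises PE; ties break toward the smaller k (parsimony).
A reference score table measured on a saliva-only micrograph
(−0.6856, −0.8455, −0.7965, −0.9378, −0.9218 for k = 2…6) selects k = 2 —
note the near-balanced two-way split sits close to the closed form −ln 2 =
−0.6931.

Two sensitivity variants score the within-cluster distribution of the
256-level quantised BT.601 gray value instead of the occupancy
(`gray_literal` and its sign-flip). A per-point crisp-membership entropy
of within-image value frequencies is non-negative by construction and
essentially independent of the partition, so it cannot rank candidate k
the way the occupancy form does; the variants exist for robustness
checks, not selection, and the occupancy convention is the default
everywhere.

## Morphometry pipeline

Stages, in order: extract the target cluster (all other pixels set to
black), BT.601 weighted grayscale (weights 0.2989/0.5870/0.1140,
normalised to sum to exactly 1 so achromatic pixels are fixed points),
global threshold 0.5 with dark-particle polarity (foreground = gray <
0.5; a flag inverts), optional hole filling, 8-connected component
labelling with a `min_pixels` noise floor (default 5 px), per-region
measurement. The Sobel gradient magnitude (standard 3×3 kernels, edge
replication at the border, rescaled by the max when it exceeds 1) of the
extracted grayscale is emitted as a boundary overlay artifact;
measurements are taken on the filled regions, because an area is a pixel
count of a region and edge chains alone do not define one.

One composition detail matters: after extraction the non-target pixels are
black (gray 0), which the dark-polarity threshold would classify as
foreground. The pipeline therefore intersects the binarised mask with the
target-cluster membership mask. This preserves both primitive operations
exactly as specified while making their composition mean what the
procedure intends: foreground = pixels of the particle cluster that are
dark at the 0.5 level.

The AUTO cluster choice picks the cluster whose mean gray level differs
most from that of the modal (largest) cluster — on a bright-background
micrograph, the particle cluster. It is logged on every run.

**Equivalent-ellipse axes.** For a region's pixel coordinates, the 2×2
second central moment matrix gets +1/12 added to each diagonal entry (the
variance of a unit interval: each pixel is treated as a unit square, the
convention of the classic regionprops implementations). Axis lengths are
4√λ of the eigenvalues, scaled to μm; a single pixel measures
4√(1/12) ≈ 1.1547 px on both axes. Orientation is the principal
eigenvector's angle, counter-clockwise from the +col axis, in (−π/2, π/2].
These measurements are exactly invariant under translation and 90°
rotation, and invariant under arbitrary rotation to within rasterization
error (~3% at the sizes tested).

## Ingestion-risk classes

A monotone step function of the chosen dimension (default: major axis,
i.e. the particle's largest extent; minor-axis and √area modes exist):
size < 1 μm → passive membrane crossing; 1 ≤ size < 5 → passive transit;
5 ≤ size ≤ 20 (both ends inclusive) → endocytosis / paracellular
diffusion; size > 20 → excreted. The 1–5 μm region is assigned to passive
transit on the physiological reading that small MPs pass the digestive
tract passively. Classification follows the recorded numbers, not prose
summaries of them: one builtin Invisalign mean major length of 20.89 μm
classifies as excreted even though the source text describes all
Invisalign particles as sub-20 μm. Each class carries a human-readable
rule note so reports are self-documenting.

## Mechanics

Logs are segmented by fixed 4 s periods anchored at the first timestamp
(the machine runs a programmed cycle); a force-trigger mode splitting at
upward crossings of 5% of peak force exists for drifting clocks. A
trailing partial cycle is discarded with a warning; slice lengths plus the
discard equal the input length.

Per-cycle energy is the absolute shoelace area of the closed
(displacement, force) polygon — equivalent, for a closed cycle, to
integrating the load branch minus the unload branch, and invariant under
cyclic rotation of sample order. Compression is positive; energies are
reported as positive N·mm.

Damage detection: non-overlapping windows (default 250 cycles) provide
means and sample variances; a drop event is recorded at the onset cycle
where energy falls below (1 − drop_ratio)·median of the preceding
up-to-window cycles while the previous cycle did not trigger — so one
sustained step-down is reported once, at its onset. The defaults (window
250, drop_ratio 0.3) flag a 6.6 → 2.7 N·mm failure-type drop while
ignoring ±0.5 N·mm operational fluctuation; both are configurable.

## One-way ANOVA

Implemented from first principles: between/within sums of squares,
F = MS_between/MS_within, and the upper tail via the regularized
incomplete beta I_{d2/(d2+d1·x)}(d2/2, d1/2) evaluated with the modified
Lentz continued fraction (symmetry-switched into its convergent region;
absolute error < 1e-10, cross-checked in tests against an independent
quadrature of the F density and against scipy). All-identical data gives
F = 0, p = 1; zero residual degrees of freedom is an error.

Group construction for the builtin tables follows how the values were
recorded: a printed mean summarising several fragments enters as a single
observation, and the Ghost row with unresolved axes is dropped from
axis-length comparisons (its area still counts in area comparisons). Under
that convention the Essix-vs-Ghost comparisons give p = 0.844 / 0.242 /
0.482 (area / major / minor) and Invisalign-vs-pooled gives p = 0.119 for
area. The corresponding published major- and minor-axis p-values for the
Invisalign comparison (0.04, 0.02) are **not** reproduced by any grouping
of the printed rows we could construct (nearest reconstructions ≈ 0.023
and 0.052); those two cells are treated as unverifiable from the published
numbers and are excluded from the reproduction targets. No
multiple-testing correction is applied: raw per-dimension p-values are
the reporting convention here.

## Synthetic generators

**Micrographs.** Background = bright low-saturation base colour
(0.85, 0.83, 0.80) with a linear gradient (amplitude 0.05) along a seeded
direction plus Gaussian noise (σ = 0.02 default) — the regime in which a
global 0.5 threshold is meaningful. Particles are dark (0.35, 0.30, 0.28)
ellipses, or blobs: ellipses whose radius is modulated by a seeded radial
Fourier perturbation (harmonics 2–6, total amplitude ≤ 20%), mimicking
irregular fracture fragments. Particles that overlap, touch
(8-adjacency), or cross the border are rejected so the ground truth —
pixel-count area and moment axes of each clean rasterized mask — stays
unambiguous. `random_scene` draws 1–5 such particles (major axis 14–44 μm
by default) by rejection sampling with clearance.

**Load logs.** Force follows the four-step profile exactly. Displacement
is the elastic line (compliance 0.002 mm/N → 0.1 mm at 50 N) plus a
creep-and-recovery offset: it advances by Δ = area/peak during the high
hold and returns during the zero hold, making each closed loop a
parallelogram of exactly the requested area. Because every loop vertex is
a straight-segment endpoint, any `samples_per_cycle` divisible by 4
samples all vertices and the discretised shoelace energy matches the
requested one to rounding error; the ≥20-samples/cycle closure tolerance
of 1% is met with enormous margin. Optional linear drift and Gaussian
displacement noise (defaults 0) perturb the loop without moving its
nominal area.

**What passing closure tests shows — and does not.** The generators make
particles that are strictly darker than the background, never touching,
with noise far from the threshold, and loops whose vertices are sampled
exactly. Perfect recovery under these conditions validates the measurement
chain (segmentation → threshold → labelling → moments; segmentation →
shoelace), not robustness to real-world pathologies: overlapping or
out-of-focus particles, illumination gradients crossing the 0.5 level,
sub-resolution fragments, load-cell drift within a cycle. Those remain the
user's responsibility to judge per dataset.

## Problem sizes and numerics

Default test/closure sizes: 128×128 px scenes (1 μm/px), 50 scenes in the
acceptance battery; 120–200 cycle load logs at 20–80 samples/cycle;
10,000-replicate null calibration of the ANOVA (group sizes 8 and 6,
matching the builtin area comparison). These sizes make every property
cheap to recompute while leaving the tolerances meaningful. Ties in
component renumbering break by raster order; k-means distance ties resolve
to the lowest cluster index (argmin); all seeds derive from caller-visible
integers and are recorded in logs and reports.

## Known limitations

* No touching-particle splitting (no watershed) and no shape taxonomy
  (fibre/fragment/sphere) — particles merged in the mask measure as one.
* No resolution-limit rule: fragments near one pixel are simply pruned by
  `min_pixels`, not flagged as indistinguishable.
* The absolute PE values of a real acquisition depend on its colour
  statistics; only the selection behaviour (argmax over k, ties to small
  k) is reproducible without the original images.
* Energy analysis assumes the programmed cycle period; severe clock drift
  requires the trigger segmentation mode.
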