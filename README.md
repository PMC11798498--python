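# mpmorph

Quantitative analysis of microplastic (MP) particles shed by orthodontic
clear aligners under simulated swallowing loads — and of the cyclic
compression tests that shed them.

Thermoformed and 3D-printed clear aligners experience roughly 1,500
occlusal contacts (~50 N each) per day; over a two-week wear period this
fatigue-like loading nucleates cracks and detaches polymer fragments that
the patient may ingest. Characterising those fragments means answering two
questions from light micrographs of residual saliva: *how many particles,
and how large?* — and, from the test machine's force–displacement log,
*when did the aligner start to fail?* `mpmorph` is a library + CLI for
orthodontic-materials and microplastics researchers that does both.

## What it computes

**Particle morphometry.** A micrograph is flattened to its cloud of
per-pixel RGB triples and partitioned with Lloyd's k-means for candidate
cluster counts k. Each partition is scored with the Partition Entropy (PE)
validity index over the cluster occupancy fractions P_i = n_i/n,

    PE(k) = Σ_i P_i ln P_i,        −ln k ≤ PE ≤ 0,

and the k with maximal PE wins (ties to the smaller k). The particle
cluster is extracted, converted to grayscale by the BT.601 weighted sum,
binarised at the global threshold 0.5, and labelled into 8-connected
regions; a Sobel gradient map is emitted as the boundary diagnostic. Each
region yields a pixel-count area and equivalent-ellipse axis lengths
(second central moments with the +1/12 pixel-as-unit-square correction,
axes = 4√λ), all calibrated to micrometres by a user-supplied μm/pixel
scale.

**Ingestion risk.** Each particle is placed in a size-based
gastrointestinal-fate class: `< 1 μm` passive membrane crossing, `1–5 μm`
passive transit, `5–20 μm` uptake only by endocytosis / paracellular
diffusion, `> 20 μm` likely excreted.

**Hysteresis energy.** Cyclic-compression logs (20 Hz, programmed 4 s
cycles: 1 s ramp to 50 N, 1 s hold, 1 s ramp down, 1 s hold) are segmented
into cycles; the energy absorbed per cycle is the shoelace area of the
closed force–displacement loop (N·mm). Windowed statistics plus an
onset detector flag sudden energy drops — the signature of crack growth.

**Group statistics.** One-way ANOVA, implemented from first principles
(sums of squares, and the F upper tail through a continued-fraction
regularized incomplete beta), compares particle dimensions between aligner
brands. Mean dimension tables for three commercial aligners (Essix Ace,
Ghost Aligner, Invisalign) ship as builtin fixtures.

**Synthetic data.** Seeded generators produce micrographs with exact
rasterized ground truth (dark elliptical/irregular particles on a bright
graded noisy background) and load logs whose per-cycle loop areas are
exact by construction — so every stage is testable end to end.

## Worked example

Simulate a micrograph with one 80 × 40 μm ellipse, then measure it:

```bash
mp-morph simulate image --spec scene.json --out scene.png --truth truth.csv
mp-morph measure scene.png --scale 1.0 --seed 1 --out meas.csv
```

where `scene.json` is

```json
{"shape": [128, 128], "seed": 7,
 "particles": [{"shape": "ellipse", "center_um": [64, 64],
                "major_um": 80, "minor_um": 40, "orientation_rad": 0.5}]}
```

The measurement CSV contains one row:

```
source_id  particle_id  area_um2  major_um  minor_um  pixel_count
scene.png            1    2503.0      79.9     39.91         2503
```

i.e. the analyser re-found the particle, its pixel-count area (2,503 μm²
at 1 μm/px, vs the continuous ellipse area π·40·20 ≈ 2,513 μm²) and axis
lengths within a fraction of a percent of the rasterized ground truth —
`truth.csv` prints the identical 2503.0 / 79.9 / 39.91. The log line
`selected k=2, target cluster 1` records the PE-selected cluster count and
the auto-chosen particle cluster.

Compare two builtin dimension tables:

```bash
$ mp-morph anova essix_ace ghost --column area_um2
{"column": "area_um2", "F": 0.0402, "df": [1, 12], "p": 0.8445, "group_ns": [8, 6]}
```

p = 0.84 ≫ 0.05: the areas of the MPs shed by the two thermoformed
aligners are statistically indistinguishable. And classify a table:

```bash
$ mp-morph risk invisalign --dimension major
                          count  fraction
ENDOCYTOSIS_PARACELLULAR      2  0.666667
EXCRETED                      1  0.333333
```

Two of the three Invisalign particle means fall in the 5–20 μm
endocytosis/paracellular window; one (20.89 μm) sits just above the 20 μm
excretion boundary.

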