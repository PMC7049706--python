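# speckquant

Quantification of single-molecule RNA FISH (smFISH) images: nucleus
segmentation with interphase/mitotic classification, micronuclei counting,
cell-territory tessellation, 3D speckle detection, and per-cell
nuclear/cytoplasmic localization statistics.

## What it computes

smFISH renders individual transcripts or transcript clusters (e.g. *Malat1*
at nuclear speckles, *Neat1* at paraspeckles) as fluorescent puncta in a 3D
z-stack, with DAPI marking nuclei. The scientific question this package
serves is *where* a transcript lives: per cell, what fraction of its
speckles are cytoplasmic rather than nuclear, and how that distribution
shifts between cell populations (for instance wild-type cells versus cells
carrying a deletion that increases cytoplasmic export).

The pipeline, stage by stage:

1. **Nuclei** — watershed segmentation of the z-projected DAPI image;
   nuclei classified as interphase or mitotic from DAPI intensity and
   texture (condensed mitotic chromatin is smaller, brighter, coarser);
   small DAPI bodies near a nucleus flagged as micronuclei.
2. **Cell territories** — each pixel assigned to its nearest nucleus
   (Voronoi tessellation of the nuclear compartment); cytoplasm = cell
   minus nucleus, exactly.
3. **Speckles** — per FISH channel: local background correction (per-slice
   white top-hat), one Otsu threshold per channel per field, 26-connected
   3D component labeling, size filter; each speckle gets a voxel count,
   mean intensity, centroid, owning cell and compartment.
4. **Statistics** — per cell, the cytoplasmic ratio
   `x = n_cyto / n_total` and its normalizing transform `x^(1/5)`; groups
   compared with two-sided Mann–Whitney *U* and two-sample
   Kolmogorov–Smirnov tests on the transformed ratios (stratified by
   interphase / mitotic / all), Pearson's chi-squared on the proportion of
   cells with any cytoplasmic speckle, and Mann–Whitney plus quartiles for
   speckle-size comparisons.

Raw imaging data for this kind of experiment is rarely deposited, so the
package includes a first-class synthetic-field generator
(`speckquant.simulate`) that renders DAPI + FISH stacks with exact ground
truth (nucleus table, speckle table, truth label maps) and controllable
cytoplasmic fraction, mitotic fraction, micronucleus rate, speckle size and
noise. Every pipeline stage is validated against that truth; see
`docs/methods.md` for the model and its limits.

## Worked example

```python
import dataclasses
import speckquant as sq

# a WT-like field: 10 cells, 5% of speckles cytoplasmic
params = sq.FieldParams()
stack, truth = sq.generate_field(params, seed=17)
result = sq.process_field(stack)

print(result.cell_summary[["cell_id", "phase", "n_nuclear",
                           "n_cytoplasmic", "cytoplasmic_ratio"]].head(4))
```

```
   cell_id       phase  n_nuclear  n_cytoplasmic  cytoplasmic_ratio
0        1  interphase         13              1           0.071429
1        2  interphase         10              0           0.000000
2        3  interphase         12              0           0.000000
3        4     mitotic          5              1           0.166667
```

Each row is one cell: cell 1 is an interphase cell in which 1 of 14
detected *Malat1* speckles lies in the cytoplasmic compartment (ratio
0.07); the mitotic cell 4 has 1 of 6 cytoplasmic. Comparing a WT-like cohort
(cytoplasmic fraction 0.05) against an elevated-export cohort (0.30),
~200 cells per group:

```python
params_hi = dataclasses.replace(params, cytoplasmic_fraction={"malat1": 0.30})
group_a, group_b = sq.generate_cohort(params, params_hi, n_fields=20, seed=42)
```

the Mann–Whitney and KS tests on transformed ratios both reject with
p below 1e-39, and the mean per-cell ratio recovers the generating
fractions (0.077 vs 0.311 for seed 1).

The same stages run from the shell:

```bash
speckquant simulate --seed 17 --n-fields 6 --out sim/
speckquant run-all --config config.yaml
speckquant compare --groups wt/cells_all.csv mut/cells_all.csv --out comparison.csv
```

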