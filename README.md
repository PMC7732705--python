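# wearbench

Quantification of 3D surface wear from sequential dental scans, with a
synthetic scan generator providing exact ground truth so every stage of the
pipeline — rigid alignment, wear metrics, paired statistics — is testable
without clinical data.

The package implements a two-factor factorial bench comparing

* **capture models**: laboratory profilometry (single-valued 50 µm raster
  with 2.6 µm repeatability noise; blind to undercuts) vs. intraoral-style
  scanning (coarser remeshing + Laplacian smoothing + vertex noise; captures
  undercuts), and
* **alignment strategies**: untrimmed two-stage best-fit ICP on the
  buccal/lingual reference surfaces (1000 → 5000 sampled points, occlusal
  region deleted) vs. feature-initialized trimmed ICP (curvature keypoints +
  RANSAC coarse alignment, then a 25 µm correspondence inlier band).

Wear outcomes per surface: signed volume change (mm³, loss negative),
maximum point loss (µm), mean profile loss (µm), plus a per-surface
positive-truncation secondary analysis. Statistics: median/IQR, paired
Wilcoxon signed-rank with Bonferroni correction (default family of 6),
two-way absolute-agreement single-measures ICC with 95% CI, and an a-priori
power inversion for detecting a correlation.

## Layout

| module | role |
|---|---|
| `wearbench.mesh_core` | labeled triangle meshes, raster grids, PLY/OBJ/STL I/O, exact closest-point and ray queries |
| `wearbench.synthetic_data` | crown generator, lesion depth fields with closed-form volumes, capture models, pose perturbation, cohorts |
| `wearbench.registration` | point sampling, ICP (point-to-plane / point-to-point, optional trimming), feature-based coarse alignment, the two full strategies |
| `wearbench.wear_metrics` | perpendicular signed distance maps and the three outcome metrics |
| `wearbench.stats` | median/IQR, Wilcoxon (exact ≤ 25 / normal approx), Bonferroni, ICC(A,1), correlation power |
| `wearbench.experiment` | factorial driver, ground-truth audit, report rendering |

## CLI

```bash
# synthetic cohort: PLY scans + ground_truth.csv
wearbench simulate --config examples/cohort.yaml --out out/

# align a follow-up scan to its baseline
wearbench align --strategy feature_trimmed \
    --baseline base.ply --followup follow.ply \
    --out aligned.ply --report report.json

# wear metrics between a baseline and an aligned follow-up
wearbench measure --baseline base.ply --followup-aligned aligned.ply --out result.json

# paired tests + ICC over a long-form results table
wearbench stats --in results_long.csv --out stats.json

# the full factorial experiment
wearbench run --config examples/factorial.yaml --out results/ --seed 1
```

PLY is the canonical format (a `uchar region` vertex property carries the
occlusal/buccal/lingual/other labels); STL/OBJ use a `vertex_index,region`
sidecar CSV.

## Notes on conventions

* All coordinates are mm; metrics are reported in µm/mm³ at the reporting
  layer only.
* A face belongs to a region iff all three of its vertices carry the label.
* Quartiles use linear interpolation; the Wilcoxon statistic is
  W = min(W⁺, W⁻) with zero differences dropped by default; the ICC model is
  two-way, absolute agreement, single measures.
* Missing raster cells are dropped, never interpolated — interpolation is
  exactly the intraoral-scanner artifact under study.
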