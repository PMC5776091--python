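# polefocus

Quantification of polar protein-cluster dynamics in bacterial time-lapse
microscopy, bundled with a ground-truthed synthetic image generator so that
every stage of the measurement pipeline can be validated by parameter
recovery.

The motivating system is the general PTS protein Enzyme I (EI) in
*Escherichia coli*: a metabolic enzyme that partitions between a diffuse,
active cytoplasmic pool and a compact, largely inactive cluster at the cell
pole. Cells in a population differ in whether they carry a cluster, how
mobile it is, and when it assembles or disperses — a spatial layer of
phenotypic heterogeneity in sugar metabolism. The package is for
microbiologists and image-analysis developers who want a reproducible,
scriptable version of the measurements this kind of study rests on:

- **Segmentation** of rod-shaped cells from a phase-contrast-like channel
  (Otsu threshold, connected components, principal-axis geometry).
- **Cluster detection** inside each cell: white top-hat homogenization, a
  within-cell `mean + k·SD` threshold, and measurement of area, intensity
  and sub-pixel centroid on the original image.
- **Per-cell intensity statistics**: the mean intensity MI (a proxy for
  protein amount) and the standard-deviation intensity SDI (a proxy for
  cluster presence and size; for a fixed budget, moving signal from the
  diffuse pool into a spot raises the SDI monotonically).
- **Tracking** of cluster centroids and average speed (path length over
  elapsed time), for speed-versus-size analyses.
- **Pattern classification** of each cell into the four canonical dynamic
  localization classes: non-Dyn (static cluster), Dyn-1P (mobile within one
  pole zone), Dyn-OP (excursions to the other pole or midcell), and UC (no
  detectable cluster).
- **Event detection**: cluster formation (SDI jump of a configurable factor
  over a trailing baseline) and gradual dispersal (a monotone SDI decline
  accumulating a relative drop), plus quiescence-exit sub-population
  classification and sister-cell inheritance scoring across division.
- **FRAP**: pole-region recovery curves with double normalization,
  recovery(t) = (F̂(t) − F̂(0⁺)) / (F̂_pre − F̂(0⁺)) × 100 on
  ratio-corrected intensities, and single-exponential `A·(1 − e^(−kt))`
  fits.
- **Statistics**: Pearson/Spearman correlation, ordinary one-way ANOVA, and
  bootstrap confidence bands.

The synthetic generator (`polefocus.simulate`) renders two- or
three-channel OME-TIFF stacks of growing, dividing rod cells whose
fluorophore budget is split exactly between a uniform diffuse pool and a
Gaussian polar spot, with: power-law speed–size motion
`v = v0·(A_ref/A)^α`, exponential (cell-cycle-independent) cluster
nucleation, linear dispersal after quiescence exit, asymmetric cluster
inheritance at division, photobleaching with exchange-driven recovery, and
a reporter channel rank-correlated with clustering through a Gaussian
copula. Every run returns a `GroundTruth` object with per-cell, per-frame
truth tables.

## Worked example

Simulate a 1000-cell population with the canonical pattern mixture
(9% non-Dyn, 43% Dyn-1P, 11% Dyn-OP, 37% UC), analyze it, and read back the
classifier's population fractions:

```python
from polefocus import SimulationConfig, simulate_population
from polefocus.pipeline import run_analysis

cfg = SimulationConfig(n_cells=1000, n_frames=11, frame_interval=60.0,
                       nucleation_rate=0.0, seed=11)
stack, truth = simulate_population(cfg)
result = run_analysis(stack)
print(result.fractions)
```

```
non-Dyn       0.090
Dyn-1P        0.430
Dyn-OP        0.110
UC            0.370
detectable    0.630
dtype: float64
```

The classifier recovers the generating mixture exactly here: 43% of cells
have a cluster that stays mobile within one pole zone, 37% show only
diffuse signal, and 63% of cells carry a detectable cluster.

The same recipes are available from the shell, e.g. a photobleaching
experiment pair (untreated vs. translation-inhibited):

```bash
$ polefocus figures --which fig3 --out out/ --seed 1
{
  "untreated_600s": 6.022137476884732,
  "chloramphenicol_600s": 3.9854269143040515
}
```

i.e. about 6% of the bleached polar signal is recovered after 600 s with
protein synthesis intact, and about 4% when the synthesis contribution is
removed — the difference being the de novo synthesized third of the
recovered material.

Other entry points: `polefocus simulate` (write a ground-truthed OME-TIFF
plus truth CSVs), `polefocus analyze` (full pipeline on a stack),
`polefocus frap`, `polefocus figures --which fig1|fig2|fig3|fig4b|fig5a|fig5cd`,
and `polefocus report`.

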