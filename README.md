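# histoscape

Landscape-ecology and spatial-statistics analysis of classified histological
images.

## The scientific problem

Modern digital pathology pipelines can classify every pixel of a whole-slide
image into tissue categories (scar, parenchyma, inflammation, …) and annotate
discrete features (follicles, portal tracts, central veins, nuclei) as
points. What those pipelines usually lack is a principled, quantitative
vocabulary for the *spatial arrangement* of those classes and features — how
fragmented the scar is, whether follicles cluster or repel, how large the
functional tissue unit is, whether a lesion is organised along an axis.

Geoscience and ecology solved the analogous problem decades ago: a
classified map is a *categorical landscape*, and a set of annotated features
is a *spatial point pattern*. `histoscape` ports that toolbox to histology:

* **Landscape metrics** — a classified label raster is decomposed into
  patches (maximal connected same-class regions) and summarised at patch,
  class and landscape level: percentage of landscape (PLAND), patch count
  and density, largest-patch index, total edge and edge density, mean patch
  area, the aggregation index AI = 100·g_ii/max g_ii, Shannon/Simpson
  diversity and evenness, and contagion. A complementary
  information-theoretic layer treats the 4-neighbour class co-occurrence
  distribution as a joint distribution and reports its marginal, conditional
  and joint entropies and mutual information (bits).
* **Point-pattern statistics** — intensity and nearest-neighbour summaries,
  the Clark–Evans index (observed mean NN distance over its CSR expectation
  1/(2√λ); < 1 clustered, > 1 dispersed, with the Donnelly edge-corrected
  expectation available), the Hopkins–Skellam index (Σd²_event/Σd²_sample;
  1 under CSR, < 1 clustered), edge-corrected Ripley K and Besag L
  functions (translation, isotropic, border corrections), the empty-space F,
  nearest-neighbour G and J = (1−G)/(1−F) functions, pointwise and global
  Monte-Carlo CSR envelopes, a studentized permutation test for grouped
  patterns, and Voronoi/Stienen geometry.
* **Microarchitectural models** — the hepatic lobule idealised as a regular
  hexagon (portal tracts at the vertices, central vein at the centre): the
  mean distance r from a central vein to its 6 nearest portal tracts gives
  the modelled lobule area (3√3/2)·r². And a scar-axis analysis: cells
  around a vein are summarised by distance-to-ring and polar angle, the
  peak of the wrapped-kernel angular density defines the scar axis, fields
  are rotated so the peak sits at 90°, and a free least-squares sine fit to
  the aligned density tests for axial (180°-periodic, bipolar) organisation.
* **Diagnostic classification** — per-case landscape-metric feature tables
  feed a leakage-free pipeline (case-level splits, near-zero-variance
  removal, rank-based inverse-normal transform and correlation filtering
  fitted on the training split only) into a bagged random forest with full
  per-tree introspection: out-of-bag permutation importance, impurity
  decrease, mean minimal depth, node/root counts with binomial p-values,
  ROC/AUC and F1-by-threshold, plus k-means case clustering.
* **Synthetic generators** — clumpiness-controlled categorical rasters,
  Poisson/Matérn-cluster/inhibition point processes, jittered hexagonal
  lobular lattices and bipolar scar fields, all seed-deterministic with
  known ground truth, so every analysis can be calibrated without tissue
  data.

## Worked example

```python
import numpy as np
from histoscape import (all_metrics, clark_evans, hopkins_skellam, l_function,
                        lobule_areas, align_to_peak, angular_density,
                        fit_axial_sine)
from histoscape.points import Window
from histoscape.synthetic import (gen_clumpy_raster, gen_point_process,
                                  gen_lobular_lattice, gen_scar_field)

# 1. landscape metrics on a synthetic classified image
raster = gen_clumpy_raster((128, 128), n_classes=3, clumpiness=0.6, seed=1)
tabs = all_metrics(raster)
land = tabs["landscape"].table.iloc[0]
print(f"SHDI={land['shdi']:.3f}  SHEI={land['shei']:.3f}  "
      f"AI={land['ai']:.1f}  CONTAG={land['contag']:.1f}")
print(f"mutual information={tabs['complexity'].mutual_information:.3f} bits")

# 2. point-pattern statistics on a clustered pattern
window = Window(0, 1, 0, 1)
pp = gen_point_process("matern_cluster", window,
                       {"kappa": 25, "mu": 8, "radius": 0.05}, seed=2)
print(f"n={pp.n}  CE={clark_evans(pp, 'donnelly'):.3f}  "
      f"HS={hopkins_skellam(pp, rng_seed=99):.3f}")
est = l_function(pp, r=np.linspace(0, 0.1, 11), centred=True)
print("L(r)-r at r=0.05:", round(est.value[5], 4))

# 3. lobule hexagon model on a jittered lattice
lat = gen_lobular_lattice(Window(0, 60, 0, 60), lobule_spacing=6.0,
                          jitter_sd=0.15, seed=3)
areas = [e.area for e in lobule_areas(lat["centrals"], lat["portals"])]
print(f"{len(areas)} lobules, mean area {np.mean(areas):.2f} "
      f"(lattice truth {lat['true_area']:.2f})")

# 4. scar-axis analysis on a synthetic bipolar field
scar = gen_scar_field(n_cells=500, vein_radius=5, axis_deg=30,
                      bipolar_concentration=8, radial_decay=8, seed=4)
aligned = align_to_peak(scar["field"])
grid, dens, _ = angular_density(aligned.phi)
fit = fit_axial_sine(grid, dens)
print(f"raw peak {scar['field'].phi_peak:.0f} deg -> aligned "
      f"{aligned.phi_peak:.0f} deg; fitted period {fit.period:.1f} deg")
```

Output:

```
SHDI=1.099  SHEI=1.000  AI=91.5  CONTAG=35.1
mutual information=1.112 bits
n=185  CE=0.462  HS=0.052
L(r)-r at r=0.05: 0.0531
99 lobules, mean area 31.26 (lattice truth 31.18)
raw peak 30 deg -> aligned 90 deg; fitted period 177.6 deg
```

The clustered Matérn pattern is flagged by every statistic (CE and HS well
below 1, L(r) − r above 0); the jittered lattice recovers the constructed
lobule area to a fraction of a percent; the planted 30° bipolar scar axis is
found, rotated to 90°, and its aligned density fits a sine with period
≈ 180°, the signature of axial organisation.

## Command-line interface

Every analysis is also exposed as a `histoscape` subcommand operating on
standard formats (integer TIFF/PNG label images with a JSON sidecar, CSV
point tables, ImageJ `.roi`/`.zip` annotations):

```bash
histoscape simulate raster --seed 1 --out sim/
histoscape landscape --input sim/raster.tif --out metrics.csv
histoscape pointpattern --input points.csv --window 0,1,0,1 \
    --fn L --envelope pointwise --out L.csv
histoscape lobule --centrals cv.csv --portals pt.csv --out areas.csv
histoscape scar --cells mfb.csv --ring ring.csv --out scar.csv
histoscape classify --features features.csv --trees 500 --out clf/
histoscape centroids --input labels.tif --class-code 2 --out follicles.csv
histoscape run --config pipeline.json      # batch runner with manifest
```

## Documentation

`docs/methods.md` describes the statistical models, estimator conventions,
edge corrections, parameter defaults and numerical safeguards in detail.
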