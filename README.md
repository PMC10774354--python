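# grasshh

Grassland height-heterogeneity analysis from photogrammetric point
clouds — a tested, reusable implementation of the height variation
hypothesis (HVH) workflow for pollinator habitats.

The HVH states that the more vertically heterogeneous the vegetation of a
site, the more niches it offers and the more species it hosts. For
grasslands surveyed by low-altitude UAV photogrammetry the workflow is:

1. derive a **canopy height model** (CHM = DSM − DTM) from the dense
   point cloud, rasterizing both surfaces through a Delaunay TIN — the
   DSM from per-cell highest points, the DTM from the lowest point per
   0.5 m filter cell — at 10, 25 and 50 cm resolution;
2. compute **height-heterogeneity (HH) indices** over each 150 m × 1 m
   field transect: Rao's Q (Σ d_ij p_i p_j with p_i = 1/N and
   d_ij = |x_i − x_j|), the coefficient of variation (100·SD/x̄),
   Berger–Parker dominance (n_max/N) and Simpson's D (Σ p_i²), the
   latter two on 1 cm height bins;
3. **regress** ground-surveyed flower richness, bee richness and bee
   abundance on HH with ordinary least squares, producing the
   4 indices × 3 resolutions × 3 responses result grid, and validate
   raster pairs by seeded random point sampling.

Because field and UAV campaigns of this kind are rarely released, the
package ships a synthetic generator: correlated random height fields
sampled as photogrammetry-like point clouds (700 pts/m², partial ground
visibility) and transect surveys stochastically coupled to the planted
heterogeneity. The whole chain runs — and is tested — without any
external data. See `docs/methods.md` for the model details.

## Worked example

Run the full simulated study (30 short transects, all four indices,
three resolutions) and inspect the result grid:

```sh
grasshh run --preset fast --seed 1 --out-dir results/demo
```

or in Python:

```python
from grasshh.pipeline import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(preset="fast", seed=1, out_dir="results/demo"))
```

`results/demo/result_grid.csv` then contains one OLS fit per
(index, resolution, response) cell; the Rao's Q rows of that exact run:

```
index  resolution        response      slope  r_squared      p_value  significant
rao_q        0.10 flower_richness 105.617091   0.668959 3.413595e-08         True
rao_q        0.10    bee_richness 121.143939   0.492030 1.571492e-05         True
rao_q        0.10   bee_abundance 771.021814   0.444108 5.807452e-05         True
rao_q        0.25 flower_richness  95.631438   0.682565 1.879660e-08         True
rao_q        0.25    bee_richness 111.998712   0.523390 6.266007e-06         True
rao_q        0.25   bee_abundance 683.018654   0.433742 7.599625e-05         True
rao_q        0.50 flower_richness  98.223762   0.694064 1.112859e-08         True
rao_q        0.50    bee_richness 114.598222   0.528177 5.418356e-06         True
rao_q        0.50   bee_abundance 705.391232   0.445913 5.539126e-05         True
```

Reading this: with the generator's default (positive) effect sizes, every
Rao's Q cell shows a positive, significant slope — more height
heterogeneity, more flowers and bees — and the R² of each response barely
moves across the three raster resolutions (e.g. 0.67–0.69 for flower
richness), i.e. the inference is robust to CHM resolution. Rao's Q
attains the highest R² of the four indices in this run; Simpson's D and
Berger–Parker, being dominance measures, carry negative slopes. The run
also writes `hh_measures.csv` (the long HH table), `surveys.csv`,
`true_parameters.csv` (the planted gradient) and a `manifest.json` with
SHA-256 checksums; rerunning with the same seed reproduces every table
byte for byte.

The other subcommands expose the stages individually: `simulate` (write
LAS/XYZ clouds + survey tables), `chm` (point cloud → DSM/DTM/CHM
GeoTIFFs), `heterogeneity` (CHM + transect table → HH table), `validate`
(raster pair → fit report) and `regress` (HH + survey tables → result
grid).

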