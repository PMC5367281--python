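# vegmorph

Morphometric analysis of self-organized vegetation patterns in dryland
ecosystems.

Dryland vegetation frequently organizes into striking spatial patterns —
isolated **spots**, reticulate **labyrinths**, and **gaps** of bare ground in
otherwise continuous canopy — arranged along a gradient of water stress.
Because spotted patterns are thought to precede collapse to bare ground,
quantifying pattern *morphology* (rather than naming it by eye) matters for
anticipating regime shifts. `vegmorph` provides that quantification for
ecologists and Earth-system modellers working with either simulated biomass
fields or satellite imagery.

## Method

1. **Segmentation.** A raster (model biomass grid in g m⁻², or a grayscale
   satellite chip) is converted to a binary pattern: vegetation = foreground,
   bare ground = background. Model grids are thresholded at 5 g m⁻², rescaled
   (×0.17, bilinear) and cropped to a 50×50 window; satellite chips are
   cropped (350×350), downscaled to 50×50 and intensity-thresholded (Otsu by
   default, dark pixels read as dry-season vegetation).
2. **Pixel graph.** The pixels of one polarity become vertices; two vertices
   are joined when they lie in each other's 3×3 neighbourhood
   (8-connectivity — the king-move lattice). Simulated patterns are analysed
   through foreground pixels, satellite patterns through background pixels.
3. **Subgraph centrality.** Each vertex *v* is ranked by

   SC(*v*) = Σ<sub>ℓ≥0</sub> μ<sub>ℓ</sub>(*v*)/ℓ! = [e<sup>A</sup>]<sub>*vv*</sub> = Σ<sub>j</sub> u<sub>j</sub>(*v*)² e<sup>λ<sub>j</sub></sup>,

   where μ<sub>ℓ</sub>(*v*) counts closed walks of length ℓ from *v* and
   (λ<sub>j</sub>, u<sub>j</sub>) is the eigensystem of the adjacency matrix A.
4. **Euler-characteristic filtration.** Vertices are admitted in descending
   SC rank in 5% increments; at each of the 20 levels the Euler
   characteristic χ = V − E of the induced subgraph is recorded, giving a
   20-dimensional feature vector per image.
5. **Morphospace.** Feature vectors from an image collection are embedded
   with covariance PCA; the first principal component captures essentially
   all variance and separates pattern classes into disjoint score intervals.
6. **Patch statistics.** Vegetation patch sizes (8-connected components, in
   pixels) are summarized per image; their mean jumps by an order of
   magnitude when individual patches coalesce into a spanning labyrinth — a
   percolation-like transition.

A seeded synthetic-pattern generator (thresholded smoothed Gaussian random
fields, disk lattices, deterministic fixtures) reproduces the
spot/labyrinth/gap sequence so the whole pipeline is testable without
external data.

## Worked example

```python
from vegmorph import morphospace_study

study = morphospace_study(base_seed=0)
print(f"PC1 explains {100 * study.pc1_variance:.2f}% of the variance")
print(study.separation[["label_a", "label_b", "disjoint", "gap"]].to_string(index=False))
```

prints

```
PC1 explains 99.95% of the variance
   label_a    label_b  disjoint          gap
     spots labyrinths      True  6477.932050
     spots       gaps      True 12675.329197
labyrinths       gaps      True  5392.472068
```

Thirty synthetic patterns (10 spots at 15% cover, 10 labyrinths at 50%, 10
gaps at 85%) were featurized through their background pixels and embedded
with PCA. PC1 alone carries 99.95% of the variance, and the three
morphologies occupy disjoint PC1 intervals separated by the listed gaps — a
single coordinate classifies the pattern type. The `examples/` directory has
one short script per capability (feature vectors, morphospace, patch-size
sweep, model-grid segmentation).

A thin CLI wraps the same functions:

```bash
vegmorph synth --family smoothed-field --cover 0.15 --seed 7 --out spots.csv
vegmorph featurize spots.csv --kind mask --polarity background --out features.csv
```

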