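# Methods

This note records the models, conventions and numerical choices behind
`vegmorph`, and what the synthetic experiments do and do not demonstrate.

## Binary patterns and polarity

All analysis operates on 2-D boolean rasters with a fixed convention:
`True` = vegetation (foreground), `False` = bare ground (background). Shapes
are distinguished by their complements, so every operation can run on either
polarity. The default polarity differs by source: simulated biomass fields
are characterized through their **foreground** (vegetated) pixels, while
satellite-derived patterns are characterized through their **background**
(bare-ground) pixels — real-world vegetation patches are small and
irregular-edged, and the continuous bare-ground matrix carries the cleaner
morphological signal. The CLI's `--polarity auto` encodes this default; it
is a convention, not a rule, and is always overridable.

## Segmentation

**Model recipe** (biomass grid → 50×50 mask): threshold at 5 g m⁻²
(inclusive: a cell exactly at threshold is vegetated, which keeps an
all-equal grid deterministic), nearest-neighbour upsample ×4, bilinear
rescale ×0.17, centered 50×50 crop, re-binarize at 0.5 on the interpolated
values. The upsample step exists because a 100×100 grid shrunk by ×0.17
could not contain a 50×50 window; ×4 makes the rescaled raster 68×68, and
the implied ~0.6 cells/pixel matches a ~161 m footprint for the final window
at 2 m cells. Both factor and crop are configurable.

**Satellite recipe** (grayscale chip → 50×50 mask): centered 350×350 crop,
anti-aliased bilinear downscale to 50×50, intensity threshold. The strong
(7×) reduction needs the smoothing prefilter; without it the sparse bilinear
sampling aliases fine patch structure and the foreground area fraction is
not preserved. The threshold defaults to Otsu with dark-is-vegetation
(dry-season canopies are darker than bare soil); a fixed threshold in (0, 1)
can be supplied per image. RGB inputs are converted by BT.709 luminance.
Thresholding uses `bright = intensity > t` with the dark mask as its exact
complement, so flipping the polarity hint complements the mask bit-for-bit,
and re-thresholding an already-binary image at 0.5 is the identity.

Windows are 0-based, row-major, half-open throughout.

## Pixel graphs and subgraph centrality

The "3×3 neighbourhood" rule is 8-connectivity: vertices are pixels of the
chosen polarity in raster order; an edge joins two vertices at Chebyshev
distance exactly 1 (self excluded). A full m×n raster therefore yields the
king graph with m(n−1) + n(m−1) + 2(m−1)(n−1) edges — 9702 for 50×50.

Subgraph centrality SC(v) = Σ μ_ℓ(v)/ℓ! is computed spectrally as
Σ_j u_j(v)² e^{λ_j} via a dense symmetric eigendecomposition
(`scipy.linalg.eigh`). Graphs here have ≤ 2500 vertices, where the dense
route is exact, fast and free of Krylov convergence concerns. Disconnected
graphs need no special-casing (block-diagonal adjacency). SC(v) ≥ 1 always
(the length-0 walk), and Σ_v SC(v) = Σ_j e^{λ_j}, which the tests use as a
conservation check. A truncated walk-count oracle (repeated matrix powers,
L = 30, graphs ≤ 200 vertices) provides an independent route for testing
only; at L = 30 the truncation error is below 1e-9 because the spectral
radius of these graphs is at most 8.

Ranking is by descending SC with ties broken by raster order (stable sort).
Ties are measure-zero in realistic data but arise in symmetric fixtures
(all-equal masks), and the deterministic tie-break makes every downstream
artifact byte-reproducible. SC values are used raw — no normalization or
truncation before ranking.

## Euler-characteristic filtration

Level k of the filtration (k = 1…20) admits the top ceil(k·V/20) ranked
vertices. Ceiling rounding guarantees a non-empty first level and a complete
final level for any V; for the full 50×50 mask V = 2500 is divisible by 20
and the rounding never engages. χ of a vertex subset is V − E of the induced
subgraph (faces are not defined for these graphs); the empty subset has
χ = 0 by convention, though the ceiling rule makes it unreachable. χ equals
components minus independent cycles, so forests have χ = component count and
densely connected blobs drive χ strongly negative.

The per-level edge counts are computed in one O(E) pass: an edge enters the
filtration at the level that admits the lower-ranked of its endpoints, so a
sorted array of entry levels plus `searchsorted` yields all 20 counts. Tests
cross-check the whole vector against a brute-force reimplementation
(explicit subsets, pairwise adjacency scan, networkx centrality) on ≤ 12×12
masks, and the identity χ[last] = V − E against an independent edge count.

## Morphospace

PCA is performed on the column-centered feature matrix without per-feature
standardization: all 20 features are χ counts in identical units, and
standardizing would inflate the nearly constant early levels. The
implementation is a direct SVD of the centered matrix, keeping the full
explained-variance spectrum (ratios sum to 1 to 1e-10) with component signs
fixed so each loading vector's largest-magnitude entry is positive —
`sklearn.decomposition.PCA` serves as an independent cross-check in the
tests. Class separation is reported as pairwise PC1 interval disjointness
with a signed gap, since in practice PC1 carries > 99% of the variance and
higher components are noise. Model-derived and satellite-derived sets should
be embedded separately (their polarity conventions differ); the library does
not pool them.

## Patch statistics

Patches are 8-connected foreground components (`scipy.ndimage.label`),
matching the graph convention; connectivity 4 is available. Per image the
summary reports every patch size, their count and arithmetic mean; an empty
image has *absent* (None), not zero, mean size. No minimum-patch-size filter
is applied by default. Patch count equals the component count of the
foreground pixel graph — a cross-module identity the tests enforce — and
patch sizes always partition the foreground pixel count.

## Synthetic patterns

The generator stands in for an ecohydrological pattern-forming model: seeded
white noise is smoothed with a periodic Gaussian filter (sigma =
`correlation_length_px`) and thresholded at the exact empirical quantile
1 − cover, so the realized cover equals the request to within one pixel.
Low cover yields spots, ~0.5 labyrinths, high cover gaps — the canonical
morphology sequence. Defaults: 50×50 rasters and correlation length 3 px,
which on a 50×50 domain produces a handful of patches of realistic relative
scale, comparable to the patch counts seen in segmented dryland imagery.
Disk lattices give an idealized spotted pattern with an analytic patch count
k²; the spacing precondition is ≥ 2r + 2 because at 2r + 1 neighbouring
disks sit at Chebyshev distance 1 and would merge under 8-connectivity,
breaking the analytic count. All generators are pure functions of
(parameters, seed).

What the generator does *not* emulate: the regular wavelength selection of
reaction–diffusion patterning (Gaussian random fields have a broad spectrum,
real banded patterns a narrow one), anisotropy from slopes, and the steeply
nonlinear rainfall→cover response of real and simulated drylands. Passing
tests on these fields therefore demonstrate that the morphometric machinery
separates morphology classes and detects coalescence — not that any
particular ecohydrological model is reproduced.

## The coalescence (percolation-like) experiment

`percolation_sweep` sweeps cover 0.10→0.90 in 0.05 steps, 5 replicates per
step, at correlation length 1.5 px — small enough relative to the 50×50
domain for a clean separation between patch scale and system size. Mean
patch size rises smoothly (~1.4× per step) while patterns remain collections
of individual patches, then regime-shifts to a single spanning labyrinth.
The transition window is operationalized without free parameters:

* **lower bracket** — the last step at which *no* replicate contains a
  lattice-spanning patch (largest patch touching all four edges): patterns
  are still made of separate individual patches;
* **upper bracket** — the first later step at which *most* replicates
  consist of exactly one patch: a continuous labyrinth.

Between these brackets (typically cover ≈ 0.45 → ≈ 0.80) the mean patch
size jumps by well over an order of magnitude (×15–×40 across seeds),
whereas comparable spans away from the transition change it far less in
regime terms. Note that for a cover-controlled generator no *pair of
adjacent* sweep steps shows a tenfold jump — the mean-over-patches statistic
has no point singularity, and rainfall-driven models only compress the
transition into one driver step because their cover response is steeply
nonlinear near it. The regime-bracket definition above is therefore the
faithful analogue of comparing the last multi-patch rainfall level with the
first single-labyrinth level.

## Problem sizes and determinism

The bundled experiments use 50×50 rasters: 30 patterns for the morphospace
study (30 dense eigendecompositions of ≤ 2500×2500 symmetric matrices,
≈ 30 s total) and 85 masks for the cover sweep (labeling only, ≈ 2 s).
Every stochastic routine takes an explicit seed; replicate seeds are derived
as documented offsets from a single base seed, so whole studies are
reproducible bit-for-bit.

## Known limitations

* Satellite segmentation quality depends on an intensity threshold; Otsu
  assumes a bimodal histogram and can fail on hazy or low-contrast chips.
* The χ feature vector is not rotation- or scale-normalized beyond the fixed
  50×50 window; images must be segmented to a common footprint before
  comparison.
* PC1 interval disjointness is a descriptive report, not a significance
  test; no classifier is fitted.
* The manual crop placement of the original workflows is replaced by a
  centered (or user-specified) crop.
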