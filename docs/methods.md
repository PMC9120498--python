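# Methods

This note documents the models and procedures `specdiv` implements, the
design choices made where more than one reasonable convention exists, and
the limits of what the synthetic experiments can show.

## Synthetic scenes

The generator produces everything an imaging-spectroscopy biodiversity
study consumes, with full ground truth.

**Phylogeny.** A coalescent-style process: lineages merge pairwise with
exponential waiting times at rate k(k−1)/2 for k active lineages, giving a
rooted ultrametric tree whose depth is rescaled to 1 (so the phylogenetic
covariance has a unit diagonal). Trees are deterministic under their seed.

**Endmembers.** Each species' reflectance is a smooth vegetation template —
green-peak bump, chlorophyll red trough, logistic red edge to an NIR
plateau, water-absorption dips at ~1200/1450/1940 nm, declining SWIR —
whose five shape parameters evolve by Brownian motion along the tree
(reflected into biophysical bounds, reflectance clamped to [0, 1]). Closely
related species are therefore spectrally similar *in expectation*; the
package makes no claim that the templates match any particular flora, only
that they are maskable, mixable and phylogenetically structured. A fixed
bare-soil endmember (brightening monotonically into the SWIR, NDVI ≈ 0.06)
is bundled so greenness masking has something to reject.

**Communities.** Plots sit at evenly spaced positions on a 1-D
environmental gradient. Species have Gaussian niches with random optima and
widths (0.15–0.4 gradient units); expected abundance at position g is
`exp(−s·(g−opt)²/(2w²))` times a lognormal base abundance and lognormal
noise (σ = 0.35). `gradient_strength s = 0` makes the niche factor
identically 1, so communities are exchangeable. Abundances are rescaled to
a per-plot total cover drawn uniformly from 35–95 % (a scalar total can be
passed instead), which makes canopy density — and hence LAI — vary across
plots.

**Rendering.** Tree-species cover is realized as circular crowns: stems
uniform in the plot, crown diameter and height drawn from the species'
ranges, crowns placed until their cumulative disc area reaches the species'
intended cover (overlap allowed; placement never fails). Each 1 m pixel is
assigned a single class — the tallest crown covering its center, otherwise
an understory species or bare soil drawn from the plot's remaining cover —
and receives that class's endmember spectrum. This one-component-per-pixel
rendering was chosen over sub-pixel mixing so that the per-pixel ground
truth (dominant species, soil flag, shade flag) is exact and mask-recovery
tests are unambiguous; at 1 m pixels under ~2–6 m crowns it is a mild
idealization. The soil probability on open pixels is scaled by the open
fraction so that the *overall* soil share of the plot matches the
configured bare-soil fraction in expectation. A random pixel subset
(default 8 %) is shaded by multiplying the full spectrum by 0.1 — strong
enough that the NIR shade index separates cleanly, and scale-only, so NDVI
(a ratio) is unaffected, exactly as with real cast shadow to first order.
Gaussian noise (default σ = 0.005 reflectance) is added and the result
clipped to [0, 1]. LAI is mapped linearly from combined cover onto the
0.13–3.80 range observed across the sites this design emulates
(`LAI = 0.13 + 3.67 · cover_fraction · (1 − soil_fraction) + N(0, 0.05)`,
clipped).

**What the scenes do not emulate:** radiative transfer (no PROSAIL),
atmospheric and BRDF effects, topographic illumination, sensor PSF and
mixed pixels, spatial autocorrelation of communities beyond the 1-D
gradient, and within-species spectral variation. Passing tests therefore
demonstrate the *correctness of the computations* and the recoverability of
a known compositional signal under idealized imaging — not performance on
real airborne data.

## Preprocessing

Band exclusion removes wavelengths ≤400 nm, ≥2400 nm, and the closed water
windows [1340, 1445] and [1790, 1955] nm. NDVI uses band-window means (red
650–680 nm, NIR 780–800 nm — the exact windows are a convention on a 5 nm
grid and are configurable); the shade index is the arithmetic mean over
752–1048 nm. Both screens are evaluated on the original (pre-band-drop)
reflectance — their windows survive the band drop, so the order only
matters in principle — and applied inclusively (≥ threshold), with
site-level NDVI thresholds (default 0.5 for the synthetic vegetation;
sparse real sites would use ~0.2, dense forest ~0.8) and vegetation-type
shade thresholds (forest 0.18, shrubland 0.20, grassland 0.22). A pixel
belongs to a plot if its center lies inside the plot polygon (half-open
cells, so edges never double-count); a plot is retained iff at least 50 %
(inclusive) of its pixels pass both screens. Brightness normalization
divides each retained spectrum by its Euclidean norm; it is idempotent,
scale-invariant (a shaded copy of a spectrum normalizes to the same vector)
and drops zero-norm rows with a warning.

## Spectral diversity

One PCA is fitted per site on all retained plots' normalized pixels pooled,
so plot scores and distances live in a single space. Type-I scaling is
operationalized as: center columns on the pooled mean, never standardize,
score rows by projection on unit-norm eigenvectors — the distance-biplot
convention under which full-rank scores preserve Euclidean distances among
centered spectra. The eigendecomposition runs on the band-space covariance
when pixels ≥ bands and on the pixel-space Gram matrix otherwise; both
routes agree to numerical tolerance (tested). The retained dimension k is
the smallest k whose cumulative variance fraction exceeds the target
(default 0.95).

`SD_α` is the per-plot mean squared deviation of pixel scores from the plot
centroid summed over retained components — the biased total variance, zero
iff all pixels coincide, invariant under rotation of the retained basis,
and equal to centered band-space variance when the variance target is 1.
The within/among decomposition holds exactly:
`SD(pooled) = Σ_p (n_p/N)·SD_α(p) + (1/N) Σ_p n_p‖centroid_p − grand‖²`.

Plot mean spectra are computed in normalized band space (whether one should
average before or after normalization, or in PC space, is a convention;
this one keeps β-distances in the same space as the PCA input, and the
choice is recorded here). Spectral β-diversity is the full symmetric
Euclidean distance matrix among those means.

## Plant diversity

Visible crown cover solves the occlusion problem by sub-grid rasterization
(default 0.1 m; tests run 0.05 m): every cell belongs to the tallest disc
covering its center, ties broken by record order (later rows win —
documented, since only the height ranking is principled). Crowns are
clipped to the plot by construction. Rasterization converges to the exact
polygon-clipping solution as resolution → 0; at 0.05 m agreement is within
2 % relative error for species fractions ≥0.5 % of plot area (thinner
occlusion slivers are below the sub-grid's resolving power and are checked
on an absolute scale).

Understory cover is treated as percent of plot area, rescaled to 100 if a
row exceeds it (with a warning), multiplied by the open fraction (1 − crown
fraction) and added to tree-visible cover; a species in both layers
accumulates.

Richness counts positive-cover species. Shannon uses natural logarithms.
PSE follows the abundance-weighted evenness formula given in the README; it
is 1 on a star phylogeny, reduces to PSV under equal abundances (both
verified symbolically and numerically), and decreases monotonically as
abundance concentrates on one clade. Averaging PSE over replicate simulated
phylogenies (the `n_trees` option) emulates studies that integrate over
phylogenetic uncertainty; the default is a single tree. The Hellinger
transform takes square roots of relative covers (unit-norm rows), and
taxonomic β-diversity is Euclidean distance on transformed rows, hence
bounded by √2 and invariant to row totals.

## Statistics

Distance regressions are ordinary least squares of spectral on taxonomic
distance with each unordered pair used once (or per-plot mean distances),
reporting slope, intercept, r², t and the two-sided p from the standard
slope test. These naive p-values ignore the dependence among pairs sharing
a plot and are reported for fidelity with common practice; the Mantel
permutation test (plot labels of one matrix permuted, two-sided on the
pairwise Pearson correlation) is the calibrated alternative and is what the
package's own calibration tests rely on. A zero-variance regressor yields a
missing fit rather than an error.

Co-inertia analysis centers both tables with uniform row weights and takes
the SVD of the cross-covariance YᵀX/n; eigenvalues are squared singular
values, total co-inertia their sum, and RV = total / √(‖XᵀX/n‖²_F ·
‖YᵀY/n‖²_F) ∈ [0, 1]. The Monte-Carlo test permutes rows of Y (999 by
default) and uses p = (1 + #{permuted ≥ observed}) / (n_perm + 1); inside
the loop total co-inertia is computed as the squared Frobenius norm of the
cross-covariance (the identity Σσ² = ‖·‖²_F avoids 999 SVDs). The test is
exact under row exchangeability, which the calibration experiment (spectra
and inventories simulated independently) verifies at the nominal 5 % level.

"Variance explained" — how much of the plant table's variation the spectra
capture — has no canonical definition in a co-inertia framework; the
implementation provides a redundancy-style statistic (fraction of Y's total
variance captured by regression on X's co-inertia scores), which is 1 for
Y = X with all axes, 0 for orthogonal tables, and non-decreasing in the
number of axes. Because it saturates trivially whenever plots ≤ features,
the pipeline reports it on the first two axes (the plane an ordination plot
shows). It is flagged as one plausible operationalization, not a standard.

Per-LAI-class regressions fit each plant metric on SD_α within four LAI
classes ([0.13, 0.634], (0.634, 1.183], (1.183, 1.84], (1.84, 3.80] —
left-closed only for the first class); classes with fewer than 3 plots are
skipped with a warning.

## Pipeline and problem sizes

`run_all` derives per-stage seeds from one root seed, writes every stage
output plus a SHA-256 manifest (identical config + seed ⇒ identical
manifest), and labels any failure with its stage. The reference study the
acceptance script runs uses one site of 25 plots (20 m, 1 m pixels, the
full 426-band grid), 12 species, gradient strength 12 for the turnover
study and 0 with an independently drawn inventory for the null study —
sizes chosen so a single desk-scale run exercises every stage while the
replicate-based tests (100–500 replicates) use a coarser 10–20 nm band grid
and smaller plots. Mantel and co-inertia tests use 999 permutations in
single runs and 199 in the 100-replicate recovery experiment (the p = 0.005
floor is far below the 0.05 decision level).

## Known limitations

Crown placement targets expected disc area without accounting for overlap
or edge clipping, so realized visible cover is systematically a little
below the intended percent for dense canopies. The per-pixel rendering
(no sub-pixel mixing) makes mask recovery exact by construction; real
mixed pixels would blur both masks. Naive distance-regression inference is
anticonservative by design (see above). The co-inertia row weights are
uniform; site-stratified or abundance weights are not implemented.
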