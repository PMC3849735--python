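# Methods

This note records the models, conventions and design choices behind
`histohet`, in the spirit of a statistical appendix: what is computed,
under which assumptions, and what the synthetic validation does and does
not demonstrate.

## Coordinate and unit conventions

All geometry above raw pixel access is in micrometres, origin at the
top-left corner of the frame, x rightward, y downward. Pixel (row i,
col j) at resolution r µm/px has its centre at ((j+0.5)·r, (i+0.5)·r).
Areas are µm² (mm² only where stated, e.g. intensities per mm² and the
mitotic-index reference area). Sample variance (n−1 denominator) is
used everywhere a variance is reported.

## Imaging chain

**Wavelet decimation.** The working image is produced by keeping the
approximation band of an orthonormal Daubechies-2 wavelet transform per
RGB channel, once per level, each level halving both dimensions and
doubling the pixel size; three levels map a 0.5 µm/px scan to 4 µm/px,
where one pixel is on the order of a cell. The periodized transform is
used rather than symmetric extension: with a length-4 filter, symmetric
extension yields ⌈(n+3)/2⌉ coefficients per level and the image size
drifts away from exact halving, while periodization gives exactly
⌈n/2⌉ and preserves the ÷8 size contract. Approximation coefficients
are rescaled by 1/2 per level (the 2-D orthonormal DC gain) so a
constant image maps to the same constant. Consequences: the output
mean matches a block-average to well under 1%, and output variance
never exceeds input variance on natural textures.

**Nucleus detection.** Brown-stain optical density is obtained by color
deconvolution with the Ruifrok–Johnston H/E/DAB stain matrix
(scikit-image's implementation); the DAB channel is thresholded (Otsu
on the in-ROI OD histogram unless a fixed threshold is configured),
8-connected components are extracted and filtered to an area window
(defaults 10–400 µm², bracketing a mitotic nucleus of radius ≈ 2–6 µm).
Touching nuclei closer than one pixel merge into a single detection —
a stated limitation of connectivity-based segmentation; the defaults
are calibrated on the synthetic renderer only, and real-slide use
should re-tune threshold and area window. Detection count is monotone
non-increasing in the threshold by construction.

**Mitotic index.** Count × 1.7 / ROI-area(mm²), i.e. mitoses per
1.7 mm² (≈ 10 high-power fields), computed over the whole ROI rather
than a selected hot spot.

## Spatial heterogeneity features

**Voronoï pavements.** Each detected nucleus's zone of influence is its
Voronoï cell clipped to the ROI polygon. Cells are bounded by
mirroring the generators across the four sides of the ROI bounding box
before triangulating, so the clipped cells partition the ROI exactly
(conservation is asserted to 0.1%, observed at machine precision). The
feature is the sample variance of cell areas, optionally divided by
the squared mean area (dimensionless). Cell adjacency is taken from
the Delaunay ridges of the generators.

**Hot spots.** Cells with area strictly below the p-th percentile
(default 10) are flagged; adjacent flagged cells are merged and groups
of ≥ min_cluster (default 5) cells are reported. This output is
exploratory: under complete spatial randomness, chains of ≥5 small
adjacent cells occur in roughly a third of 200-point patterns, so the
default min_cluster does not control false positives; ≥7 cells brings
the spurious rate to a few percent (measured property, documented in
the tests).

**Quadrat indices.** An axis-aligned grid of square quadrats (default
side 200 µm ≈ 50 px at the working resolution) tiles the ROI bounding
box; quadrats with less than 50% ROI overlap are discarded, which
avoids boundary-inflated variance, and densities use the actual
overlap area. Fisher's index is the variance-to-mean ratio of the
retained counts: ≈1 under complete spatial randomness (calibration
verified: mean over 200 CSR patterns ∈ [0.9, 1.1] at ≥20 expected
counts per quadrat), →0 for regular patterns, increasing with cluster
tightness. The normalized density variance is the squared coefficient
of variation of quadrat densities — intensity-free by construction.
Note that with unequal quadrat overlap areas the raw count VMR is
inflated even under CSR (unequal Poisson means); calibration
statements therefore refer to grids that tile the ROI exactly.

## Texture features

The gray-level co-occurrence matrix is computed on the Rec.601
luminance of the decimated working image, linearly quantized to G=16
levels between the in-ROI min and max, at the four distance-1 offsets
(0°, 45°, 90°, 135°), symmetrized and averaged — the common Haralick
convention. Pairs with either pixel outside the ROI are dropped; no
padding. Energy is Σp², in (0,1], equal to 1 for a constant image;
correlation uses the GLCM marginal means/SDs, lies in [−1,1], and is
defined as 0 when a marginal SD vanishes (single occupied level).
Additional descriptors (contrast, dissimilarity, homogeneity, entropy,
maximum probability) are available but not part of the validated
surface. The choice of luminance over the stain-OD channel is a
convention; the quantization makes energy invariant to level
relabeling and correlation invariant to level shifts.

## Composite scores

Features are standardized (sample SD), pruned of redundancy by greedy
elimination — while any pair has |Pearson r| > r_max (default 0.8),
drop the member of the worst pair with the larger mean |r| to the
other survivors, ties to the later column — and projected onto the
top-3 eigenvectors of the correlation matrix. The correlation (not
covariance) matrix is used because the features have incommensurable
units. Component signs are fixed by requiring a positive loading on a
reference dispersion feature (Fisher's index by default, falling back
to another surviving dispersion feature if it was pruned), so a higher
composite score always reads as "more heterogeneous". CP2 is defined
positionally as the second principal component. The upper-tercile
flag uses the linear-interpolation (type-7) empirical 2/3 quantile
with a strict > at the cut, so ties at the cutpoint are not flagged
and the flagged count is ⌊n/3⌋ or ⌈n/3⌉ (123 of 368 distinct values).

## Survival analysis

Disease-free survival is the end point: the event is metastasis and/or
local recurrence; deaths without recurrence are censored (a documented
assumption). Kaplan–Meier estimation, log-rank tests and Cox fitting
are delegated to lifelines; the Cox solution is then refined by Newton
iteration on the Efron-tie log partial likelihood (own gradient and
observed information) because the package guarantees a score residual
‖∂logPL/∂β‖∞ < 10⁻⁶ at the reported β̂ and lifelines' stopping rule
alone leaves ~10⁻⁵ at n=2000; standard errors and Wald p-values come
from the observed information at the refined optimum (they agree with
lifelines to ~4 decimals). Covariates are standardized internally for
conditioning and the coefficients mapped back — the partial likelihood
is equivariant under affine covariate maps. Only Efron tie handling is
offered. Collinear covariates and event-free tables are rejected.

Univariate screening uses log-rank for features with ≤5 distinct
values (categorical) and a univariate Cox Wald test for continuous
features; constant features yield a row with p = NaN plus a warning.

The risk model counts three binary poor factors per patient — mitotic
index strictly greater than 10 per 1.7 mm², positive axillary nodes,
CP2 upper tercile — and groups patients 0 / 1–2 / 3. The boundary is
strict: an index of exactly 10 contributes no factor.

## Synthetic study conditions

The generators define the conditions under which the pipeline is
validated; they are deliberately simple and their defaults are fixed.

- **Point patterns.** Homogeneous Poisson (CSR) for spatially random
  proliferation; a Thomas process (Poisson parents, Poisson(µ)
  offspring per parent, isotropic Gaussian scatter σ) for hot-spot
  clustering — the simplest stationary cluster process with a
  closed-form intensity λ_parent·µ. Parents are simulated on the ROI
  dilated by 4σ so the retained pattern is stationary inside the ROI.
- **Slides.** Flat dark-brown discs (radius default 4 µm) on a pale
  background with additive Gaussian noise. No chromatin texture, no
  mitotic-figure morphology, no scanner artifacts: downstream detection
  is intensity-based, so shape realism adds nothing to the tests. This
  means the detection defaults are validated only for well-contrasted
  stains.
- **Cohorts.** Covariate marginals mirror a typical breast-carcinoma
  series: mitotic index ~ negative binomial with mean 10 per 1.7 mm²
  and size 2 (variance 60 — overdispersion is present but the size
  parameter is a modelling choice, not an observed value), node
  positivity Bernoulli(0.44), heterogeneity score standard normal.
  Event times are exponential with hazard h₀·exp(βᵀz), censoring an
  independent exponential; default true hazard ratios are 1.71, 2.20
  and 1.46 per standardized covariate — the clinically relevant effect
  sizes for mitotic index, nodal status and heterogeneity. The log-HR
  for mitotic index acts on the model-standardized index: per-count
  effects of that magnitude would be meaningless (exp(0.54·40)
  overflows any plausible hazard) and per-SD effects are the standard
  reporting scale.
- **Demo dataset.** Per patient, a latent heterogeneity h ~ U(0,1)
  controls Thomas-cluster tightness (offspring scatter 300 → 40 µm,
  cluster size 2 → 10 as h grows) at a gamma-mixed intensity whose
  implied mitotic index has mean 10; features are computed from the
  pattern and a 4 µm/px rendered thumbnail, and the hazard uses the
  standardized latent h in the CP2 slot. Because a single latent
  drives all spatial features, which principal component captures it
  is data-dependent; the pipeline reports all three.

Passing tests on these conditions show the machinery is correct and
calibrated; they do not show that the detection defaults, feature set
or effect sizes transfer to any particular clinical archive.

## Problem sizes

Monte-Carlo checks use 100–200 replicates for calibration statements,
20 seeds × n=2000 for Cox recovery (mean absolute log-HR error
≤ 0.15), 10⁴ probes for the nearest-generator oracle, and a demo
cohort of 368 patients with 8 rendered slides in the acceptance run;
the full validation completes in minutes on one core.

## Known limitations

- Voronoï-cell adjacency is taken before ROI clipping; a cell split in
  two by a non-convex ROI keeps its pre-clip neighbours.
- Quadrat-count calibration statements assume grids that tile the ROI
  exactly; ragged edges inflate the raw-count VMR under CSR (the
  density-based index is unaffected).
- The hot-spot default min_cluster=5 is exploratory, not
  false-positive-controlled (see above).
- No stain normalization across scanners, no mitotic-phase
  classification, no time-dependent covariates or competing risks.
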