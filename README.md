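# histohet

Spatial heterogeneity of tumor proliferation on virtual slides, and its
prognostic value for disease-free survival.

## The problem

Breast carcinomas with the same mitotic count can organize their
proliferation very differently: mitoses may be spread evenly through the
tumor or packed into "hot spots". `histohet` quantifies that spatial
heterogeneity from immunostained whole-slide images (mitosis-specific
stains such as anti-phosphohistone-H3 make mitotic nuclei an
intensity-detection problem) and asks whether it carries prognostic
information beyond the classical factors — mitotic index and lymph-node
status.

The pipeline is, end to end:

1. **Imaging** — read the scan (tiled/pyramidal TIFF or PNG), decimate it
   with a Daubechies-2 orthogonal wavelet (3 levels: 0.5 → 4 µm/px, where
   one pixel ≈ one cell), mask to a region of interest, detect
   brown-stained nuclei by color deconvolution + thresholding + connected
   components, and compute the mitotic index per 1.7 mm².
2. **Heterogeneity features** — on the nucleus positions: the variance of
   Voronoï pavement areas (each nucleus's zone of influence; small
   pavements = hot spots), Fisher's index of dispersion
   `I = s²/x̄` of quadrat counts (≈1 under complete spatial randomness,
   >1 under clustering), and the normalized density variance
   `s²(ρ)/ρ̄²`. On the decimated image: Haralick gray-level co-occurrence
   energy `Σᵢⱼ p(i,j)²` and correlation
   `Σᵢⱼ (i−µᵢ)(j−µⱼ)p(i,j)/(σᵢσⱼ)`.
3. **Composite scores** — prune redundant features (pairwise |r| > 0.8),
   standardize, and project onto the first three principal components:
   the per-patient scores CP1–CP3, oriented so higher = more
   heterogeneous.
4. **Survival** — Kaplan–Meier curves, log-rank screening, multivariate
   Cox proportional-hazards regression (Efron ties,
   `h(t|x) = h₀(t)·exp(βᵀx)`), and a three-poor-factor risk model:
   mitotic index > 10 per 1.7 mm², nodal involvement, upper tercile of
   CP2, grouping patients as 0 / 1–2 / 3 factors.

Because clinical slide archives are rarely shareable, the package ships a
first-class synthetic-data layer: homogeneous Poisson and Thomas-process
nucleus patterns with known clustering, a slide renderer (stained discs +
noise), and a proportional-hazards cohort simulator with known hazard
ratios — every stage is testable against ground truth.

## Worked example

`examples/04_survival_and_risk_groups.py` simulates a 2000-patient
disease-free-survival cohort with true hazard ratios 1.71 (per SD of
mitotic index), 2.20 (node-positive) and 1.46 (per SD of the
heterogeneity score), refits them, and stratifies by poor-factor count:

```
multivariate Cox fit (true RRs 1.71, 2.20, 1.46):
                     coef  hazard_ratio      se    p
mitotic_index_std  0.5278        1.6951  0.0275  0.0
node_pos           0.6834        1.9807  0.0602  0.0
cp2                0.3660        1.4419  0.0316  0.0
score-equation residual: 3.23e-13

risk groups: {'0 factor': 426, '1 or 2 factors': 1458, '3 factors': 116}
log-rank across the 3 groups: chi2=230.0, p=1.15e-50
  0 factor        S(12m)=0.98, S(60m)=0.84, S(120m)=0.70
  1 or 2 factors  S(12m)=0.89, S(60m)=0.59, S(120m)=0.37
  3 factors       S(12m)=0.70, S(60m)=0.26, S(120m)=0.09
```

The fitted hazard ratios recover the simulation truth, the partial-
likelihood score vanishes at the optimum, and survival decreases
monotonically with the number of poor factors.

The other examples walk through point-pattern statistics (`01`), the
slide-to-feature-row pipeline (`02`), composite-score construction
(`03`), and the full two-stage demo pipeline (`05`). The same stages are
available from the shell:

```bash
histohet demo   --out demo/ --seed 7
histohet slide  --image demo/slides/slide_000.png --roi demo/rois/slide_000_roi.png \
                --config demo/demo_config.json --out features.csv
histohet cohort --features demo/features.csv --cohort demo/cohort.csv \
                --config demo/demo_config.json --out results/
```

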