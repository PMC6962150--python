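# Methods

This note documents the models and conventions behind `radstab`: what the
synthetic cohort does and does not emulate, how the texture features and
agreement statistics are defined, which choices were genuinely open, and
what the package's passing tests do and do not establish about real data.

## 1. Synthetic cohort

### Lesion model

A lesion is the union of 1–5 ellipsoid lobes with random centers, semi-axes
and orientations. A scalar `complexity ∈ [0, 1]` controls both the lobe
count (`1 + round(4·complexity)`) and axis eccentricity, spanning the
"simple sphere" to "irregular multi-lobed" range seen in manual-contouring
studies. The ground-truth mask is the exact voxel-center membership set of
the scaled union; a single global scale factor is solved by bisection on a
precomputed quadratic-form field so the voxelized volume hits a target
drawn log-uniformly from the configured range (default 30–345 cm³ on a
128×128×64 grid at 3 mm isotropic voxels). Because membership is evaluated
analytically, a `complexity = 0` lesion is testable against the raw
ellipsoid equation.

The uptake map is: background (1.0 a.u.) + lesion contrast
(tumor-to-background ratio, default 4:1; drawn 3–7 per lesion in cohorts)
+ intra-lesion hot/cold Gaussian foci (count and amplitude drawn per
lesion) + white Gaussian voxel noise (σ = 0.25 a.u.), all smoothed with a
3D Gaussian of 5 mm FWHM and clipped at zero. The 5 mm post-filter is the
dominant determinant of local texture scale, which is why no scanner or
reconstruction physics is modeled: photon transport, sinogram formation
and iterative reconstruction are deliberately out of scope, and the noise
texture is therefore Gaussian-correlated rather than reconstruction-
correlated.

### Rater model

Each simulated rater perturbs the ground truth in signed-distance space:

    contour = { sd(x) + f(x) + b > 0 },

where `sd` is the Euclidean signed distance of the truth in voxel units
(shifted by half a voxel so the zero level lies between boundary and
background voxel centers — without this shift, sub-voxel perturbations
cannot move the discrete surface), `f` is a Gaussian random field smoothed
to the rater's correlation length (8–20 mm) and scaled to the rater's
perturbation amplitude (0.3–1.1 voxels across the default panel), and `b`
is a volume bias converted to a radial offset through the lesion's surface
area (clipped at ±2 voxels). The largest 26-connected component is kept.
This produces spatially coherent, surface-localized disagreement; i.i.d.
voxel flips would not resemble human contours.

Volume-error structure is deliberately placed at the *lesion* level: each
lesion draws a shared bias `N(0, 6 cm³)` (everyone over- or under-contours
an ambiguous lesion together) and a difficulty factor (0.7–1.3, driven by
complexity) that scales every rater's perturbation, while per-rater biases
are small (−1.5 to +3.5 cm³). This matches the empirical pattern that
contouring performance is lesion-dependent without strong systematic
rater trends. The per-rater bias list is centered slightly positive
because rethresholding a perturbed distance field around a convex body
carries a curvature-driven positive volume excess (~3 cm³ at these sizes);
the centering was calibrated once against the target accuracy
distributions and then frozen.

With the default panel and a fixed master seed the cohort lands at: ~90–96%
of contours with Dice > 0.800, median SMASD ≈ 0.40–0.47 voxels, mean
signed volume error ≈ +2.4 ± 3 cm³ (documented calibration band), and
per-lesion mean errors spanning roughly −15 to +25 cm³.

### Seeding

All randomness derives from one master seed via counter-based child seeds
`hash(master, lesion, stream, rater)` (NumPy `SeedSequence`), so adding a
rater or lesion never changes previously generated objects, and every
child seed stays below 2³¹.

### What the generator does **not** emulate

No anatomy (the "lung" is uniform background), no attenuation/scatter, no
reconstruction artifacts, no inter-rater tool differences, no
intra-rater (test–retest) variability. Consequently, passing calibration
tests show that the *statistical pipeline* behaves correctly under
realistic accuracy distributions — not that any particular feature would
be robust in clinical PET.

## 2. Discretization and texture features

Intensities inside the VOI are rescaled by fixed bin number:
`level = floor(G·(x − min)/(max − min))`, clipped to `G − 1`, min/max taken
inside the VOI per contour, `G ∈ {32, 64, 128, 256}`. A constant VOI maps
to level 0. This makes all features invariant to affine intensity shifts
(tested property).

* **GLCOM** — one symmetric matrix pooling all 13 displacement-1
  directions (both voxels in-mask); features on 0-based levels: Energy
  Σp², Contrast Σ(i−j)²p, Entropy −Σp·log₂p, Homogeneity Σp/(1+|i−j|),
  Dissimilarity Σ|i−j|p, Variance Σ(i−μ)²p, Correlation
  Σ(i−μ)(j−μ)p/σ² (0 when σ² = 0).
* **GLSZM** — zones are 26-connected components of equal level inside the
  mask; the thirteen standard size-zone statistics with levels shifted to
  1..G so inverse-gray weights are defined.
* **GLNDM** — Amadasun–King statistics over 3×3×3 neighborhoods; the
  neighborhood mean excludes the center and out-of-mask voxels, and voxels
  with no in-mask neighbor are excluded from the valid count. Coarseness
  and Strength use ε = 10⁻⁶ guards; Coarseness is capped at 10⁶ for
  homogeneous VOIs; Contrast and Busyness are 0 with a single present
  level.

Open conventions the literature does not pin down are explicit
configuration with these defaults: entropy base 2; homogeneity as inverse
difference (inverse difference squared behind a flag); pooled GLCOM
aggregation (per-direction feature averaging behind a flag); 1-based
shifts for GLSZM/GLNDM weights. The provenance block of every run echoes
all of them.

The optimized implementations are verified against naive triple-loop
references (written first, kept in the test suite) on hundreds of random
small VOIs to 10⁻¹⁰ relative tolerance, plus closed-form cases.

## 3. Contour metrics

Dice is `2|A∩B|/(|A|+|B|)`. SMASD uses 6-connectivity surface voxels
(out-of-grid counts as background) and voxel-center Euclidean distances in
voxel units (multiply by spacing for mm; a `physical` flag does this). The
symmetrization is the pooled mean over both surface sets; mean-of-two-means
is available as an option and coincides when the surfaces have equal size.
The distance-transform/KD-tree path is tested against an all-pairs brute
force.

## 4. Agreement statistics

* **Percent error**: `100·(f − f_gt)/|f_gt|`; contours whose ground-truth
  value is 0 are dropped pairwise and counted.
* **Spearman ρ** of percent error vs. Dice, pooled over all lesion–rater
  pairs per (feature, G); categories weak/moderate/relatively
  strong/strong at |ρ| = 0.4/0.6/0.8. No multiplicity correction; raw
  two-sided p-values are carried through.
* **ICC**: two-way random-effects, absolute-agreement, *single-measure*
  (each cell is one rater's measurement; single-measure is the form for
  which varying the rater count is meaningful). 95% bounds via the
  McGraw–Wong F-interval with Satterthwaite denominator df; validated
  against an explicit sums-of-squares oracle and `pingouin`, with
  simulated coverage in [93%, 97%] at n = 26, k = 10. Average-measures is
  available via the Spearman–Brown map. Degenerate inputs: identical
  columns → ICC = LB = UB = 1 (flagged); zero total variance → NaN
  (flagged, excluded from selection); negative estimates floored at −1.
* **Robust selection**: lower bound ≥ 0.950, inclusive.
* **Leave-p-out**: for p = 1..7 (k ≥ p + 2 required), the ICC lower bound
  is recomputed on every subset of k − p raters and averaged over all
  C(k, k−p) subsets; verified against exhaustive enumeration at k = 5.

## 5. Problem sizes and numerical choices

The default experiment (26 lesions × 10 raters × 4 schemes, 28,600 feature
rows, full leave-p-out) runs in a few minutes on one CPU. Tests use
reduced cohorts (3–8 lesions on 64×64×48 grids, 30–90 cm³) chosen so every
property is exercised at a scale where exhaustive oracles are feasible;
the rater-count trend check ranks features by ICC_LB instead of applying
the 0.950 cutoff because confidence bounds at 8 lesions are necessarily
wide. Volume-matching bisection uses 60 iterations on a precomputed field
(resolution ≪ one voxel); spacing comparisons use 10⁻³ relative
tolerance; CSV outputs are byte-reproducible given a config.

## 6. Known limitations

* Synthetic raters disagree more at the feature level than experienced
  physicians appear to: cohort mean ICCs land around 0.67–0.75, so only a
  handful of (feature, G) pairs clear ICC_LB ≥ 0.950, whereas human-rater
  panels on comparable phantoms report class-mean ICCs of ~0.89–0.97 with
  8–9 robust features per scheme. Conclusions about *which* features are
  robust therefore should not be read off the synthetic defaults.
* The ICC model assumes a complete lesion × rater grid; missing contours
  are an error, not an imputation case.
* GLSZM/GLNDM values depend on the 26-connectivity and in-mask
  neighborhood conventions; comparisons against implementations using
  other conventions (e.g. 6-connected zones, padded neighborhoods) will
  differ legitimately.
* Feature set is the 25 matrix-based textures only — no first-order,
  shape, or filtered-image features, and naming follows the package's own
  consistent scheme rather than any certification standard.
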