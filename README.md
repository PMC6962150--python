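# radstab

**How robust are PET radiomics texture features to lesion-contouring
variability?** `radstab` is a reusable pipeline for answering that question
in a setting with complete knowledge of the ground truth: it simulates
PET-like lung lesions with exact reference masks and a panel of imperfect
"raters", extracts 25 volumetric texture features under four gray-level
discretization schemes, and quantifies feature reliability with interrater
agreement statistics.

It is aimed at radiomics methodologists and medical-physics researchers who
need a controlled test bed for feature-stability questions — e.g. which
texture features survive realistic contouring noise, and how many raters a
study needs before its reliability estimates stabilize.

## What it computes

1. **Synthetic cohort** (`radstab.synthetic`) — lesions are unions of 1–5
   random ellipsoid lobes (30–345 cm³ by default) with heterogeneous uptake,
   voxel noise and 5 mm FWHM Gaussian smoothing; each simulated rater
   perturbs the signed distance transform of the truth with a smooth
   correlated random field plus a volume bias and rethresholds, giving
   spatially coherent contouring errors (most contours Dice > 0.8, sub-voxel
   surface distance).
2. **Contour agreement** (`radstab.metrics`) — Dice coefficient
   `DICE = 2|A∩B|/(|A|+|B|)` and the symmetric mean absolute surface
   distance in voxel units,
   `SMASD = [Σ_{x∈S_A} d(x,S_B) + Σ_{y∈S_B} d(y,S_A)] / (|S_A|+|S_B|)`.
3. **Texture features** (`radstab.features`) — the VOI is discretized to
   G ∈ {32, 64, 128, 256} levels by fixed bin number; 7 co-occurrence
   (GLCOM, displacement 1, 13 directions pooled), 13 size-zone (GLSZM,
   26-connected zones) and 5 neighborhood-difference (GLNDM, 3×3×3
   Amadasun–King) features are computed in 3D.
4. **Agreement statistics** (`radstab.stats`) — percent feature error vs.
   ground truth correlated with Dice (Spearman ρ, with the conventional
   weak/moderate/relatively strong/strong bands at 0.4/0.6/0.8); the
   two-way random-effects, absolute-agreement, single-measure ICC

       ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

   with McGraw–Wong 95% confidence bounds; robust-feature selection at
   ICC_LB ≥ 0.950; and leave-p-out rater resampling (mean ICC_LB over all
   C(k, k−p) rater subsets, p = 1…7).

## Worked example

```python
import radstab as rs

# one lesion + one imperfect rater
img, gt = rs.simulate_lesion(rs.LesionParams(), seed=42)
rater = rs.RaterProfile("r1", perturbation_scale=0.6, volume_bias_cm3=1.0)
mask = rs.simulate_rater_mask(gt, rater, seed=7)

print(f"volume {gt.volume_cm3:.1f} cm3, "
      f"dice {rs.dice(gt, mask):.3f}, smasd {rs.smasd(gt, mask):.3f} vox")

table = rs.extract_features(img, mask, schemes=(32,), source="r1")
print(table.df.head(3))
```

prints (exact numbers from this seed):

```
volume 198.6 cm3, dice 0.971, smasd 0.244 vox
  lesion_id source  gray_levels         feature     value
0    lesion     r1           32    GLCOM_Energy  0.021160
1    lesion     r1           32  GLCOM_Contrast  9.265327
2    lesion     r1           32   GLCOM_Entropy  7.043630
```

A Dice of 0.97 with quarter-voxel SMASD is a good manual contour on a large
lesion; the feature rows are the raw material for the reliability analysis.

The full experiment is one call (or `radstab run --out results --seed 1`
from the shell):

```python
cfg = rs.ExperimentConfig()          # 26 lesions × 10 raters, 4 schemes
report = rs.run_experiment(cfg, "results/")
print(report.robust_counts)          # features with ICC_LB ≥ 0.950 per G
```

which writes `scores.csv`, `features.csv`, `correlations.csv`, `icc.csv`,
`leavepout.csv` and a `report.json` with robust-feature counts per scheme,
correlation-strength tallies, the top-3 most rater-stable features per
scheme, and a provenance block (seed, conventions) sufficient to reproduce
every byte.

## CLI

`radstab simulate | extract | score | agreement | leavepout | run |
summarize` — each stage reads/writes plain NIfTI/NRRD and CSV so stages can
be rerun or swapped independently. See `radstab --help`.

## Documentation

`docs/methods.md` describes the generative model, the feature conventions
(and the knobs for conventions the literature leaves open), the statistics,
and known limitations.
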