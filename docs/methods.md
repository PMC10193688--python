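# Methods

This document describes the generative model of the synthetic cohorts, the
analysis pipeline, the numerical choices behind both, and their limitations.
Empirical figures quoted here come from the runs shown in the README and from
`scripts/acceptance.py` / `tests/test_acceptance.py`.

## 1. Phantom model (`nigramap.phantom`)

### Geometry

A canonical midbrain "anatomy" is built on a 64 × 64 × 48 grid of 0.8 mm
isotropic voxels (RAS+ affine centered on the grid). All structures are
ellipsoids defined in millimetres, so the geometry is resolution-independent:

- a head-shaped background region (intensity 100) against zero outside;
- bilateral SNpc ellipsoids (intensity 120), mirror-symmetric about the
  midline;
- inside each SNpc, a posterolateral nigrosome-1 (N1, the larger nigrosome)
  and an anteromedial nigrosome-2 (N2);
- a midline crus cerebri reference region below the SNpc, used for intensity
  normalization and CR denominators.

With background 100 and SNpc 120 the canonical contrast ratio is exactly
(120 − 100)/100 = 0.2 in every SNpc subregion, which makes closed-form checks
possible (see parameter recovery below).

### Subject generation

Each subject is the canonical anatomy transformed in this order:

1. **Regional biological variability** (both groups): for each side and each
   region (N1, N2, rest of SNpc), a multiplicative factor (1 + b) with
   b ~ N(0, `regional_variability_sd` = 0.04), clipped to ±0.3. This models
   between-subject variation in neuromelanin signal that is present in
   healthy controls as well as patients.
2. **Disease deficits** (IPD only): each region's signal above background is
   scaled by (1 − d). Per side and region, d = clip(N(mean, 0.025) + boost,
   0, 0.6) with means 0.095 (N1) > 0.085 (N2) > 0.01 (rest of SNpc), and
   boost = 0.01 added contralateral to the clinically dominant symptom side
   (motor scores are drawn per side; the dominant side requires a ≥ 2 point
   difference). The combined region factor is (1 + b)(1 − d), applied to the
   voxels of that region.
3. **Global intensity scale**: a single multiplicative factor
   ~ N(1, 0.1) per subject, mimicking scanner gain differences. CR is
   invariant to it by construction; normalization removes it for voxelwise
   analysis.
4. **Rigid misalignment**: random rotations (SD 2° per axis, capped at 6°)
   and translations (SD 1 mm per axis, capped at 3 mm) about the volume
   center.
5. **Noise**: additive Gaussian (SD 5, i.e. 5% of background) or Rician
   (same scale) at the acquisition stage, after all multiplicative effects.

Every drawn quantity — deficits, variability, intensity scale, transform,
motor scores — is logged in the ground-truth JSON so that downstream
measurements can be checked against the injected values.

### Why both groups get regional variability

If controls were copies of the canonical anatomy plus noise, the whole-SNpc
CR would be an implausibly strong discriminator: averaging over the largest
ROI suppresses measurement noise almost completely, so even the small
rest-of-SNpc deficit would separate the groups nearly perfectly. That
contradicts the well-replicated empirical finding that whole-SNpc contrast
discriminates early IPD poorly while nigrosome ROIs discriminate well. A
biological variance floor shared by both groups (σ = 0.04 multiplicative,
i.e. CR SD ≈ 0.048 per region) restores the realistic ordering: at default
settings and n = 25–50 per group, AUC(N1+N2) ≈ 0.96–0.99 exceeds AUC(N1),
AUC(N2) and AUC(whole SNpc) ≈ 0.65–0.8 on every tested seed.

A second numerical subtlety motivated the deficit parameters: because
deficits are drawn from a normal truncated at zero, the ratio of group-mean
difference to group SD is bounded (≈ 1.33) regardless of the deficit SD when
the mean is small relative to the SD. Deficit means were therefore chosen
several SDs above zero (0.095/0.085 vs SD 0.025), so truncation is rare and
the injected effect sizes are close to their nominal values.

## 2. Preprocessing (`nigramap.preprocess`)

- **Background stripping** keeps the head region by intensity thresholding
  (Otsu) plus largest-connected-component selection; validated against the
  true head mask (Dice > 0.98) and checked to always cover the SNpc and
  reference regions.
- **Intensity normalization** divides by the reference-region mean, making
  volumes comparable across subjects. CRs are invariant to global scaling,
  and normalization is idempotent.
- **Rigid registration** uses SimpleITK's Euler3D transform with a
  mean-squares metric, regular-step gradient descent (learning rate 0.2,
  minimum step 1e-5, ≤ 300 iterations), a 4-level multiresolution pyramid
  (shrink 8/4/2/1, smoothing sigmas 3/2/1/0 mm) and a fixed single-thread
  setting for determinism. On noise-free phantoms perturbed by transforms at
  the misalignment caps (≤ 6°, ≤ 3 mm), recovery errors are below
  0.25° and 0.01 mm; the acceptance test requires < 1° and < 0.4 mm
  (half a voxel) over 50 random perturbations. Non-convergence within the
  iteration cap is reported as a warning, not an error, because the best
  transform found is typically already accurate.
- `RigidTransform` stores extrinsic xyz Euler angles (degrees), a
  translation and a rotation center, maps fixed-space points to moving-space
  points (ITK convention), and round-trips exactly through JSON.

## 3. Template construction (`nigramap.template`)

The group template is built by iterative registration and averaging: the
initial reference is the voxelwise median of the unregistered volumes
(robust to outliers and independent of subject order), then each iteration
registers every subject to the current reference and re-averages. Three
iterations are the default; the per-iteration mean squared dissimilarity is
recorded as a convergence curve and is non-increasing after the first
iteration in tests. Subject volumes are then resampled into template space
("spatial normalization"), and all group statistics are computed there.

## 4. Voxelwise mapping (`nigramap.voxelmap`)

Within an analysis mask (the dilated union of both SNpc regions), a Welch
t statistic (HC minus IPD) is computed per voxel. Family-wise error control
uses the max-statistic permutation method: group labels are permuted
(500 draws by default, seeded), the maximum |t| over the mask is recorded
per permutation, and each voxel's corrected p is the fraction of
permutations whose maximum reaches its observed |t| (with the observed
labeling counted, so p ≥ 1/(n_perm + 1)). The corrected p is additionally
floored at the parametric raw p so that corrected ≥ raw always holds.
Zero-variance voxels get NaN statistics rather than infinities. Under a
fully exchangeable null (no deficits, both groups drawn from the same
model), the empirical probability of any corrected p < 0.05 is consistent
with 0.05 (200-replicate calibration in the acceptance suite; 0.05 exactly
in the seed-1 acceptance report with 100 replicates).

ROI extraction keeps voxels with corrected p < α and a positive statistic
(HC > IPD — signal loss in patients), intersects them with each side's SNpc,
and takes the two largest 26-connected components per side. The component
with the more posterolateral centroid is labeled N1, the other N2. A side
with a single component yields an N1 and an empty N2 with a warning; no
significant voxels at all is a hard error (the pipeline can optionally fall
back to the ground-truth masks, recorded as `roi_source:
"fixed_masks_fallback"` — useful for small test cohorts).

## 5. Contrast ratios (`nigramap.contrast`)

CR = (mean ROI intensity − mean reference intensity) / mean reference
intensity, per subject, side and region. The combined nigrosome measure is
the volume-weighted mean CR_N1N2 = (CR_N1·V_N1 + CR_N2·V_N2)/(V_N1 + V_N2),
where V are the ROI volumes in mm³. Whole-SNpc CR uses the full SNpc mask.
CRs are computed in template space on the spatially normalized, intensity-
normalized volumes.

Because all intensity effects in the phantom are multiplicative, the
noise-free CR of a region has the closed form (1 + c₀)(1 + b)(1 − d) − 1
with c₀ = 0.2. The acceptance suite verifies that measured group-mean CR
differences in N1 recover the value predicted from the logged b and d to
within 10% relative error at n = 25/group (observed ≈ 3.5%).

## 6. Diagnostics (`nigramap.diagnostics`)

- **Group comparisons**: Shapiro–Wilk on each group gates between a Welch
  t-test (both normal at α = 0.05; summaries mean ± SD) and a two-sided
  Mann–Whitney U (otherwise; summaries median/IQR). For groups of ≤ 8 the
  Mann–Whitney p is computed by exact enumeration of all assignments
  (tie-aware); larger groups use the tie-corrected normal approximation.
  Raw p values are Bonferroni-adjusted over the 8 region measures.
- **ROC/AUC**: the decision rule is "lower CR ⇒ disease". AUC is computed
  from the placement matrix with ties counted ½ (exactly the normalized
  Mann–Whitney U). Confidence intervals and paired AUC-difference tests use
  DeLong's structural-components method, with Bonferroni adjustment over the
  region pairs. The operating point maximizes Youden's J, breaking ties
  toward higher specificity.
- **Cross-validation**: leave-one-out with the Youden threshold refit on
  every training fold; pooled held-out calls give cv sensitivity and
  specificity. The cv AUC equals the apparent AUC by construction (held-out
  scores are unchanged by holding out) and is reported with an explicit note
  to that effect.
- **Laterality**: the clinically dominant side is the one whose motor score
  exceeds the other by ≥ 2; subjects below that cutoff are excluded as
  indeterminate. Concordance between dominant side and the side of the
  higher N1 CR is tested with Fisher's exact test on the 2 × 2 table.

## 7. Determinism

Cohort generation is a pure function of the configuration (a single integer
seed drives one `numpy` generator; subjects are generated in a fixed order).
The analysis seed drives the permutation test. SimpleITK is pinned to one
thread. Floats are serialized with `%.17g` (CSV) and full repr (JSON), so
repeated runs with the same config produce byte-identical tables; the
acceptance suite asserts this end to end.

## 8. Limitations

- **Laterality is weak at defaults.** The asymmetry boost (0.01) is small
  against the regional variability of the side difference (SD ≈ 0.068 in CR
  units), giving ~55–60% concordance and typically non-significant Fisher
  tests. The boost is configurable; the pipeline reports whatever the data
  support rather than guaranteeing a positive laterality finding.
- **cv AUC is not an independent performance estimate** (see above); only
  cv sensitivity/specificity carry cross-validation information.
- **Rigid-only registration and a noise-free canonical geometry**: no
  nonlinear anatomical variation, no partial-volume modeling beyond
  trilinear interpolation, no intensity non-uniformity. The phantom is
  deliberately simple enough to admit closed-form checks.
- **ROI extraction needs group-level significance.** Small cohorts
  (n ≲ 6/group at default noise) rarely reach corrected significance, and
  the pipeline either fails hard or, if enabled, falls back to fixed masks
  and labels the output accordingly.
- **Ellipsoidal nigrosomes** are a simplification; real nigrosome-1 is a
  curved lamina. Positions and relative sizes (posterolateral N1 larger
  than anteromedial N2) follow the anatomical literature, but shapes do
  not.
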