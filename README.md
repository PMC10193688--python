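# nigramap

Template-based voxelwise analysis of neuromelanin-sensitive MRI (NM-MRI) for
early idiopathic Parkinson's disease (IPD), evaluated end-to-end on synthetic
midbrain phantoms with known ground truth.

NM-MRI shows the substantia nigra pars compacta (SNpc) as a hyperintense
region against the crus cerebri. In early IPD, neuromelanin loss is not
uniform: it concentrates in the nigrosomes, calbindin-poor subregions of the
SNpc, with nigrosome-1 (N1, posterolateral, the largest) affected first and
most, followed by nigrosome-2 (N2, anteromedial). Whole-SNpc contrast
averages the focal signal loss with unaffected tissue and discriminates
poorly; ROIs localized to the nigrosomes do much better. This package
implements the full analysis chain that produces such ROIs from group data
and then evaluates their diagnostic value — with a phantom generator in place
of a scanner, so every step can be validated against known truth.

## Pipeline

1. **Phantom cohort** (`nigramap.phantom`) — anatomically proportioned
   midbrain volumes: bilateral SNpc ellipsoids with embedded N1/N2
   subregions and a crus cerebri reference region. Patients receive graded
   multiplicative signal deficits (N1 > N2 > rest of SNpc) plus a small
   boost contralateral to the clinically dominant side; both groups receive
   per-subject regional biological variability, global intensity scaling,
   rigid misalignment and Gaussian or Rician noise. All drawn parameters are
   logged for parameter-recovery checks.
2. **Preprocessing** (`nigramap.preprocess`) — background stripping,
   reference-region intensity normalization, rigid registration
   (multi-resolution mean-squares via SimpleITK).
3. **Template** (`nigramap.template`) — iterative register-and-average
   template construction, then spatial normalization of every subject.
4. **Voxelwise mapping** (`nigramap.voxelmap`) — voxelwise Welch t statistics
   with max-statistic permutation FWE correction; significant HC > IPD
   clusters inside each SNpc are split into N1/N2 candidate ROIs by size and
   posterolateral position.
5. **Contrast ratios** (`nigramap.contrast`) — CR = (ROI mean − reference
   mean) / reference mean per subject and region, plus the volume-weighted
   N1+N2 combination.
6. **Diagnostics** (`nigramap.diagnostics`) — normality-gated group tests
   with Bonferroni correction, ROC/AUC with DeLong CIs and pairwise DeLong
   tests, leave-one-out cross-validated sensitivity/specificity, and
   laterality concordance (Fisher exact).

## Worked example

Write a configuration (all keys optional; these are the settings used for the
output shown below — misalignment is disabled so the run is faster, see
`docs/methods.md`):

```json
{
  "phantom": {"n_per_group": 25, "seed": 0,
              "misalign_rot_deg_sd": 0.0, "misalign_trans_mm_sd": 0.0},
  "voxelwise": {"n_permutations": 500, "seed": 0}
}
```

Then:

```sh
nigramap simulate --config config.json --out cohort/
nigramap run --config config.json --cohort cohort/ --out results/
nigramap report results/
```

The run takes about 7 minutes (dominated by the 150 rigid registrations of
the template stage). `results/results.json` from this exact run reports
`"roi_source": "voxelwise"` — the nigrosome ROIs were found by the
permutation map, not the fallback — and the extracted left N1 volume
(40.96 mm³) matches the ground-truth mask exactly. `nigramap report` then
prints, verbatim:

```
## Diagnostic performance (lower CR = disease)

| region | AUC | 95% CI | sens | spec | cv sens | cv spec |
|---|---|---|---|---|---|---|
| right_n1 | 0.9872 | (0.967, 1.000) | 0.920 | 0.960 | 0.920 | 0.920 |
| left_n1 | 0.9776 | (0.947, 1.000) | 0.920 | 0.920 | 0.880 | 0.880 |
| right_n2 | 0.9552 | (0.906, 1.000) | 0.840 | 0.960 | 0.800 | 0.920 |
| left_n2 | 0.9616 | (0.913, 1.000) | 0.800 | 1.000 | 0.800 | 0.840 |
| right_n1n2 | 0.9888 | (0.968, 1.000) | 0.960 | 0.960 | 0.960 | 0.920 |
| left_n1n2 | 0.9936 | (0.981, 1.000) | 0.920 | 1.000 | 0.920 | 0.920 |
| right_whole_sn | 0.6544 | (0.499, 0.809) | 0.440 | 0.880 | 0.440 | 0.840 |
| left_whole_sn | 0.6832 | (0.535, 0.831) | 0.320 | 0.960 | 0.320 | 0.360 |
```

and for the group comparisons:

```
| region | test | p (raw) | p (Bonferroni) | IPD | HC |
|---|---|---|---|---|---|
| right_n1 | t-test | 2.69e-14 | 2.15e-13 | 0.070219 ± 0.046279 | 0.211547 ± 0.047152 |
| left_n1 | t-test | 2.42e-13 | 1.93e-12 | 0.064954 ± 0.044360 | 0.200498 ± 0.050587 |
| right_whole_sn | t-test | 0.0278 | 0.223 | 0.163847 ± 0.053123 | 0.193733 ± 0.038602 |
| left_whole_sn | t-test | 0.0171 | 0.137 | 0.182483 ± 0.038480 | 0.209407 ± 0.038584 |
```

(N2 and combined rows omitted here for brevity; the full table is in
`results/report.md`.) The headline pattern is the expected one: the
volume-weighted N1+N2 combination is the best discriminator (AUC 0.99), the
nigrosome ROIs are strong individually, and whole-SNpc CR is weak
(AUC 0.65–0.68, group difference not significant after Bonferroni) — the
pairwise DeLong tests confirm every nigrosome ROI beats whole-SNpc at
adjusted p < 0.01. Laterality concordance is weak at the default asymmetry
settings (Fisher p = 0.63; see `docs/methods.md`).

### Python API

```python
from nigramap.config import PipelineConfig
from nigramap.pipeline import cmd_simulate, cmd_run, cmd_report

cfg = PipelineConfig.from_dict({"phantom": {"n_per_group": 25, "seed": 0}})
cmd_simulate(cfg, "cohort")
results = cmd_run(cfg, "cohort", "results")
print(results["auc"]["left_n1n2"])
print(cmd_report("results"))
```

## Outputs

`nigramap run` writes a self-contained results bundle: `template.nii`,
`transforms.json`, `statmap_t.nii` / `statmap_p_corrected.nii`, `rois.nii` +
`rois.json`, `cr_table.csv`, `comparisons.csv`, `roc.csv` / `roc_points.csv`,
`pairwise_p.csv`, `laterality.json`, `results.json`, and `run_manifest.json`
(stage timings, config hash, status). Runs are deterministic: identical
config and cohort produce byte-identical `results.json` and CSV outputs.

## Reproduction

Run the full test suite (includes the acceptance battery; ~8 minutes):

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Generate the acceptance report of headline quantities (~2 minutes):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

For seed 1 this reports, among others, `auc_left_n1n2` on ground-truth masks
at n = 50/group, an empirical family-wise error rate under the null of 0.05
(100 replicates), worst-case registration recovery errors of 0.24° / 0.002 mm
over 10 random in-range perturbations, and a 3.5% relative error recovering
the injected N1 group CR difference from measurements.

Methods, parameter choices and limitations are documented in
`docs/methods.md`.
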