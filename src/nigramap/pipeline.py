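"""End-to-end pipeline: simulate a cohort, run the analysis, render a report.

``cmd_run`` wires the stages together: foreground masking and rough intensity
scaling, iterative template construction, spatial normalization into template
space, reference-region intensity normalization, voxelwise group mapping, ROI
extraction, the contrast-ratio table, and the diagnostic battery.  Every output
is a plain file (NIfTI, CSV, JSON, Markdown) plus a run manifest with the
config hash, seeds and per-stage timings.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .contrast import REGION_COLUMNS, build_cr_table, cr_column
from .diagnostics import (
    DiagnosticsError,
    compare_groups,
    compare_rocs,
    comparisons_to_frame,
    laterality_concordance,
    loocv,
    roc_analysis,
    roc_curve_points,
)
from .phantom import SIDES, load_mask_labels, write_cohort
from .preprocess import normalize_intensity, strip_background
from .template import build_template
from .preprocess import resample
from .volume import Volume
from .voxelmap import RoiSet, VoxelMapError, extract_rois, voxelwise_test

__all__ = ["cmd_simulate", "cmd_run", "cmd_report", "PipelineError"]


class PipelineError(RuntimeError):
    pass


# --------------------------------------------------------------------------- #
# simulate
# --------------------------------------------------------------------------- #


def cmd_simulate(config: PipelineConfig, out_dir) -> dict:
    """Write a synthetic cohort plus a manifest with the config hash."""
    config.validate()
    paths = write_cohort(config.phantom, out_dir)
    manifest = {
        "tool": "nigramap",
        "version": __version__,
        "command": "simulate",
        "config_hash": config.content_hash(),
        "seed": config.phantom.seed,
    }
    manifest_path = Path(out_dir) / "simulate_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    config.to_json(Path(out_dir) / "config.json")
    paths["manifest"] = manifest_path
    return paths


def load_cohort(cohort_dir) -> tuple[pd.DataFrame, dict, dict, np.ndarray]:
    """Read a cohort directory: records, volumes, fixed masks, template affine."""
    cohort_dir = Path(cohort_dir)
    csv_path = cohort_dir / "cohort.csv"
    if not csv_path.exists():
        raise PipelineError(f"cohort CSV not found: {csv_path}")
    records = pd.read_csv(csv_path)
    volumes = {}
    for _, rec in records.iterrows():
        p = cohort_dir / rec["image_path"]
        if not p.exists():
            raise PipelineError(f"image for subject {rec['subject_id']} not found: {p}")
        volumes[rec["subject_id"]] = Volume.load(p)
    masks, affine = load_mask_labels(
        cohort_dir / "ground_truth_masks.nii", cohort_dir / "ground_truth_masks.json"
    )
    return records, volumes, masks, affine


# --------------------------------------------------------------------------- #
# run
# --------------------------------------------------------------------------- #


def cmd_run(config: PipelineConfig, cohort_dir, out_dir) -> dict:
    """Run the full analysis on a cohort directory; returns the results dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "nigramap",
        "version": __version__,
        "command": "run",
        "config_hash": config.content_hash(),
        "seeds": {"phantom": config.phantom.seed, "voxelwise": config.voxelwise.seed},
        "stages": {},
        "warnings": [],
    }
    results: dict = {}
    stage = "load"
    t0 = time.perf_counter()

    def _finish_stage(name: str) -> None:
        nonlocal t0
        manifest["stages"][name] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()

    try:
        records, volumes, fixed_masks, affine = load_cohort(cohort_dir)
        ids = list(records["subject_id"])
        _finish_stage(stage)

        stage = "preprocess"
        preprocessed = {}
        for sid in ids:
            vol = volumes[sid]
            fg = strip_background(vol)
            preprocessed[sid] = normalize_intensity(vol, fg)
        _finish_stage(stage)

        stage = "template"
        tpl = build_template(
            [preprocessed[sid] for sid in ids],
            n_iter=config.template.n_iter,
            initial_reference_policy=config.template.initial_reference,
            subject_ids=ids,
        )
        tpl.template.save(out / "template.nii")
        with open(out / "transforms.json", "w") as fh:
            json.dump(
                {sid: t.to_dict() for sid, t in zip(ids, tpl.transforms)},
                fh, indent=2, sort_keys=True,
            )
        _finish_stage(stage)

        stage = "spatial_normalization"
        reference_mask = fixed_masks["reference"]
        aligned = {}
        for sid, xform in zip(ids, tpl.transforms):
            moved = resample(preprocessed[sid], xform, tpl.template.shape, tpl.template.affine)
            aligned[sid] = normalize_intensity(moved, reference_mask)
        _finish_stage(stage)

        stage = "voxelwise"
        analysis_mask = fixed_masks[("left", "whole_sn")] | fixed_masks[("right", "whole_sn")]
        if config.voxelwise.analysis_margin_voxels > 0:
            import scipy.ndimage as ndi

            analysis_mask = ndi.binary_dilation(
                analysis_mask, iterations=config.voxelwise.analysis_margin_voxels
            )
        hc_ids = [s for s, g in zip(ids, records["group"]) if g == "HC"]
        ipd_ids = [s for s, g in zip(ids, records["group"]) if g == "IPD"]
        stat_map = voxelwise_test(
            [aligned[s] for s in hc_ids],
            [aligned[s] for s in ipd_ids],
            analysis_mask,
            n_permutations=config.voxelwise.n_permutations,
            seed=config.voxelwise.seed,
        )
        stat_map.save(out / "statmap")
        _finish_stage(stage)

        stage = "roi_extraction"
        whole_sn = {side: fixed_masks[(side, "whole_sn")] for side in SIDES}
        try:
            rois = extract_rois(
                stat_map, whole_sn, reference_mask, alpha=config.voxelwise.alpha
            )
            results["roi_source"] = "voxelwise"
        except VoxelMapError as exc:
            if not config.roi_fallback_to_truth:
                raise
            manifest["warnings"].append(
                f"voxelwise ROI extraction found nothing ({exc}); "
                "falling back to the supplied fixed N1/N2 masks"
            )
            masks = {
                (side, region): fixed_masks[(side, region)]
                for side in SIDES
                for region in ("n1", "n2", "whole_sn")
            }
            masks["reference"] = reference_mask
            vv = float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))
            rois = RoiSet(masks, np.asarray(affine, dtype=float), vv,
                          warnings=["fallback: fixed masks"])
            results["roi_source"] = "fixed_masks_fallback"
        rois.save(out / "rois.nii", out / "rois.json")
        manifest["warnings"].extend(rois.warnings)
        _finish_stage(stage)

        stage = "contrast"
        cr_table = build_cr_table(records, aligned, rois)
        cr_table.to_csv(out / "cr_table.csv", index=False, float_format="%.17g")
        _finish_stage(stage)

        stage = "diagnostics"
        n_hc, n_ipd = len(hc_ids), len(ipd_ids)
        if min(n_hc, n_ipd) >= 3:
            comparisons = comparisons_to_frame(compare_groups(cr_table))
        else:
            comparisons = comparisons_to_frame([])
            manifest["warnings"].append(
                "group comparisons skipped: fewer than 3 subjects in a group"
            )
        comparisons.to_csv(out / "comparisons.csv", index=False)

        roc_rows = []
        curve_frames = []
        for region in REGION_COLUMNS:
            roc = roc_analysis(cr_table, region)
            cv = loocv(cr_table, region)
            roc_rows.append(
                {
                    "region": region,
                    "auc": roc.auc,
                    "ci_low": roc.ci_low,
                    "ci_high": roc.ci_high,
                    "threshold": roc.threshold,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                    "cv_auc": cv["cv_auc"],
                    "cv_sensitivity": cv["cv_sensitivity"],
                    "cv_specificity": cv["cv_specificity"],
                }
            )
            pts = roc_curve_points(cr_table, region)
            pts.insert(0, "region", region)
            curve_frames.append(pts)
        roc_table = pd.DataFrame(roc_rows)
        roc_table.to_csv(out / "roc.csv", index=False, float_format="%.17g")
        pd.concat(curve_frames).to_csv(out / "roc_points.csv", index=False)

        pairwise = compare_rocs(cr_table)
        pairwise.to_csv(out / "pairwise_p.csv", float_format="%.17g")

        try:
            lat = laterality_concordance(records, cr_table)
            laterality = {
                "table": lat.table.tolist(),
                "fisher_p": lat.fisher_p,
                "n_indeterminate": lat.n_indeterminate,
                "n_concordant": int(lat.per_subject["concordant"].sum()),
                "n_ipd": int(len(lat.per_subject)),
            }
        except DiagnosticsError as exc:
            laterality = {"error": str(exc)}
            manifest["warnings"].append(f"laterality analysis skipped: {exc}")
        with open(out / "laterality.json", "w") as fh:
            json.dump(laterality, fh, indent=2, sort_keys=True)
        _finish_stage(stage)

        results.update(
            {
                "n_hc": n_hc,
                "n_ipd": n_ipd,
                "roi_volumes_mm3": rois.volumes_mm3,
                "auc": {row["region"]: row["auc"] for row in roc_rows},
                "cv_sensitivity": {row["region"]: row["cv_sensitivity"] for row in roc_rows},
                "cv_specificity": {row["region"]: row["cv_specificity"] for row in roc_rows},
                "laterality": laterality,
                "template_convergence": tpl.convergence_curve,
            }
        )
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
        config.to_json(out / "config.json")
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed at stage '{stage}': {exc}"
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results


# --------------------------------------------------------------------------- #
# report
# --------------------------------------------------------------------------- #

_REQUIRED_RESULT_FILES = [
    "results.json",
    "comparisons.csv",
    "roc.csv",
    "pairwise_p.csv",
    "cr_table.csv",
    "laterality.json",
]


def cmd_report(results_dir, out_path=None) -> str:
    """Render a Markdown summary of a completed results bundle."""
    results_dir = Path(results_dir)
    missing = [f for f in _REQUIRED_RESULT_FILES if not (results_dir / f).exists()]
    if missing:
        raise PipelineError(f"results bundle incomplete; missing: {missing}")

    with open(results_dir / "results.json") as fh:
        results = json.load(fh)
    comparisons = pd.read_csv(results_dir / "comparisons.csv")
    roc = pd.read_csv(results_dir / "roc.csv")
    pairwise = pd.read_csv(results_dir / "pairwise_p.csv", index_col=0)
    cr_table = pd.read_csv(results_dir / "cr_table.csv")
    with open(results_dir / "laterality.json") as fh:
        laterality = json.load(fh)

    lines = ["# nigramap results", ""]
    lines.append(f"Subjects: {results['n_ipd']} IPD / {results['n_hc']} HC; "
                 f"ROIs from {results.get('roi_source', 'unknown')}.")
    lines.append("")

    lines.append("## Group comparisons")
    lines.append("")
    if len(comparisons):
        lines.append("| region | test | p (raw) | p (Bonferroni) | IPD | HC |")
        lines.append("|---|---|---|---|---|---|")
        for _, r in comparisons.iterrows():
            lines.append(
                f"| {r['region']} | {r['test']} | {r['p_raw']:.3g} | "
                f"{r['p_adjusted']:.3g} | {r['summary_ipd']} | {r['summary_hc']} |"
            )
    else:
        lines.append("(skipped: too few subjects per group)")
    lines.append("")

    lines.append("## Diagnostic performance (lower CR = disease)")
    lines.append("")
    lines.append("| region | AUC | 95% CI | sens | spec | cv sens | cv spec |")
    lines.append("|---|---|---|---|---|---|---|")
    for _, r in roc.iterrows():
        # AUCs rendered from the same values stored in results.json
        auc = results["auc"][r["region"]]
        lines.append(
            f"| {r['region']} | {auc} | ({r['ci_low']:.3f}, {r['ci_high']:.3f}) "
            f"| {r['sensitivity']:.3f} | {r['specificity']:.3f} "
            f"| {r['cv_sensitivity']:.3f} | {r['cv_specificity']:.3f} |"
        )
    lines.append("")

    lines.append("## Pairwise AUC comparisons (Bonferroni-adjusted p)")
    lines.append("")
    lines.append("| | " + " | ".join(pairwise.columns) + " |")
    lines.append("|" + "---|" * (len(pairwise.columns) + 1))
    for idx, row in pairwise.iterrows():
        lines.append(f"| {idx} | " + " | ".join(f"{v:.3g}" for v in row) + " |")
    lines.append("")

    lines.append("## Laterality concordance")
    lines.append("")
    if "error" in laterality:
        lines.append(f"(skipped: {laterality['error']})")
    else:
        lines.append(
            f"2x2 table (dominant side x higher-CR side): {laterality['table']}; "
            f"Fisher exact p = {laterality['fisher_p']:.4g}; "
            f"{laterality['n_indeterminate']} indeterminate subjects excluded."
        )
    lines.append("")

    lines.append("## Per-region CR distribution (box-plot data)")
    lines.append("")
    lines.append("| region | group | min | q1 | median | q3 | max |")
    lines.append("|---|---|---|---|---|---|---|")
    for region in REGION_COLUMNS:
        col = cr_column(region)
        for group in ("IPD", "HC"):
            v = cr_table.loc[cr_table["group"] == group, col].to_numpy(dtype=float)
            q = np.percentile(v, [0, 25, 50, 75, 100])
            lines.append(
                f"| {region} | {group} | " + " | ".join(f"{x:.4f}" for x in q) + " |"
            )
    lines.append("")

    text = "\n".join(lines)
    out_path = Path(out_path) if out_path else results_dir / "report.md"
    out_path.write_text(text)
    return text
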