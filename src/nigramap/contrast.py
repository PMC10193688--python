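"""Contrast ratios and the volume-weighted N1+N2 combination.

The contrast ratio (CR) of a region is (mean ROI intensity - mean reference
intensity) / mean reference intensity, the dominant convention in the
neuromelanin-MRI literature; it is invariant under any positive global
rescaling of the image.  The headline marker combines the N1 and N2 CRs of a
side by a mean weighted with the template-space ROI volumes:

    CR_{N1+N2} = (CR_N1 * area_N1 + CR_N2 * area_N2) / (area_N1 + area_N2)

Weights are the fixed template ROI volumes, identical for every subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .voxelmap import RoiSet
from .volume import Volume

__all__ = [
    "contrast_ratio",
    "volume_weighted_mean",
    "build_cr_table",
    "REGION_COLUMNS",
    "cr_column",
]


class ContrastError(RuntimeError):
    pass


#: table column order: region key -> CR column name
REGION_COLUMNS = [
    "right_n1",
    "left_n1",
    "right_n2",
    "left_n2",
    "right_n1n2",
    "left_n1n2",
    "right_whole_sn",
    "left_whole_sn",
]


def cr_column(region: str) -> str:
    return f"cr_{region}"


def contrast_ratio(vol: Volume, roi_mask: np.ndarray, reference_mask: np.ndarray) -> float:
    """(ROI mean - reference mean) / reference mean."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not roi_mask.any():
        raise ContrastError("ROI mask is empty")
    if not reference_mask.any():
        raise ContrastError("reference mask is empty")
    ref = float(vol.data[reference_mask].mean())
    if ref <= 0:
        raise ContrastError(f"reference mean must be positive, got {ref}")
    roi = float(vol.data[roi_mask].mean())
    return (roi - ref) / ref


def volume_weighted_mean(cr_n1: float, area_n1: float, cr_n2: float, area_n2: float) -> float:
    """Area-weighted average of the N1 and N2 contrast ratios."""
    if area_n1 < 0 or area_n2 < 0:
        raise ContrastError("areas must be non-negative")
    total = area_n1 + area_n2
    if total <= 0:
        raise ContrastError("at least one area must be positive")
    return (cr_n1 * area_n1 + cr_n2 * area_n2) / total


def build_cr_table(records: pd.DataFrame, volumes: dict, rois: RoiSet) -> pd.DataFrame:
    """Per-subject CR table over all eight regions.

    ``volumes`` maps subject_id to its template-space :class:`Volume`; the
    RoiSet supplies the masks and the N1/N2 volume weights.  Columns:
    subject_id, group, cr_<region> for each region in :data:`REGION_COLUMNS`,
    and the subject's raw reference-region mean.
    """
    missing = [sid for sid in records["subject_id"] if sid not in volumes]
    if missing:
        raise ContrastError(f"missing template-space volumes for subjects: {missing}")

    ref_mask = rois.reference_mask
    areas = {
        (side, region): rois.volume_mm3(side, region)
        for side in ("right", "left")
        for region in ("n1", "n2", "whole_sn")
    }

    rows = []
    for _, rec in records.iterrows():
        vol = volumes[rec["subject_id"]]
        row = {"subject_id": rec["subject_id"], "group": rec["group"]}
        for side in ("right", "left"):
            crs = {}
            for region in ("n1", "n2", "whole_sn"):
                mask = rois.mask(side, region)
                if mask.any():
                    crs[region] = contrast_ratio(vol, mask, ref_mask)
                else:
                    crs[region] = np.nan
            row[cr_column(f"{side}_n1")] = crs["n1"]
            row[cr_column(f"{side}_n2")] = crs["n2"]
            row[cr_column(f"{side}_whole_sn")] = crs["whole_sn"]
            a1, a2 = areas[(side, "n1")], areas[(side, "n2")]
            if a2 == 0 or np.isnan(crs["n2"]):
                row[cr_column(f"{side}_n1n2")] = crs["n1"]
            else:
                row[cr_column(f"{side}_n1n2")] = volume_weighted_mean(
                    crs["n1"], a1, crs["n2"], a2
                )
        row["reference_mean"] = float(vol.data[ref_mask].mean())
        rows.append(row)

    columns = ["subject_id", "group"] + [cr_column(r) for r in REGION_COLUMNS] + ["reference_mean"]
    return pd.DataFrame(rows, columns=columns)
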