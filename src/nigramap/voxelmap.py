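"""Voxelwise group comparison and nigrosome ROI extraction.

Two-sample Welch t statistics are computed per voxel inside an analysis mask,
with family-wise error control by a seeded permutation max-T procedure (exact
under group exchangeability).  Voxels surviving the corrected threshold where
controls exceed patients (signal-loss voxels) are split by the midsagittal
plane and clustered with 26-connectivity; per side, the posterolateral
component is labeled N1 and the anteromedial one N2, by centroid position
relative to the side's SNpc centroid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy import stats

from .volume import Volume

__all__ = ["StatMap", "RoiSet", "voxelwise_test", "extract_rois"]


class VoxelMapError(RuntimeError):
    pass


@dataclass
class StatMap:
    """Per-voxel group statistic with raw and corrected p values.

    ``statistic`` is the Welch t of group A minus group B (NaN outside the
    analysis mask and at flagged zero-variance voxels); p values are two-sided.
    """

    statistic: np.ndarray
    p_raw: np.ndarray
    p_corrected: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    method: str = "welch-t + permutation max-T"

    def save(self, prefix) -> None:
        Volume(np.nan_to_num(self.statistic, nan=0.0), self.affine).save(f"{prefix}_t.nii")
        Volume(np.nan_to_num(self.p_corrected, nan=1.0), self.affine).save(
            f"{prefix}_p_corrected.nii"
        )


@dataclass
class RoiSet:
    """Labeled masks on the template grid with volumes in mm^3.

    Keys of ``masks``: ``(side, region)`` for side in {left, right} and region
    in {n1, n2, whole_sn}, plus ``"reference"``.
    """

    masks: dict
    affine: np.ndarray
    voxel_volume_mm3: float
    warnings: list = field(default_factory=list)

    def mask(self, side: str, region: str) -> np.ndarray:
        return self.masks[(side, region)]

    @property
    def reference_mask(self) -> np.ndarray:
        return self.masks["reference"]

    def volume_mm3(self, side: str, region: str) -> float:
        return float(self.masks[(side, region)].sum()) * self.voxel_volume_mm3

    @property
    def volumes_mm3(self) -> dict:
        out = {
            f"{side}_{region}": self.volume_mm3(side, region)
            for side in ("right", "left")
            for region in ("n1", "n2", "whole_sn")
            if (side, region) in self.masks
        }
        out["reference"] = float(self.reference_mask.sum()) * self.voxel_volume_mm3
        return out

    def save(self, label_path, legend_path) -> None:
        labels = np.zeros(self.reference_mask.shape, dtype=np.int16)
        legend = {}
        value = 0
        order = [
            ("right", "n1"), ("left", "n1"), ("right", "n2"), ("left", "n2"),
            ("right", "whole_sn"), ("left", "whole_sn"),
        ]
        for key in order:
            if key not in self.masks:
                continue
            value += 1
            labels[self.masks[key] & (labels == 0)] = value
            legend["_".join(key)] = {"label": value, "volume_mm3": self.volume_mm3(*key)}
        value += 1
        labels[self.reference_mask & (labels == 0)] = value
        legend["reference"] = {
            "label": value,
            "volume_mm3": float(self.reference_mask.sum()) * self.voxel_volume_mm3,
        }
        legend["warnings"] = list(self.warnings)
        Volume(labels.astype(np.float64), self.affine).save(label_path)
        with open(legend_path, "w") as fh:
            json.dump(legend, fh, indent=2, sort_keys=True)


# --------------------------------------------------------------------------- #
# Welch t, vectorized over voxels
# --------------------------------------------------------------------------- #


def _welch_t(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch t and degrees of freedom along axis 0.  Zero/zero -> NaN."""
    na, nb = xa.shape[0], xb.shape[0]
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    va, vb = xa.var(axis=0, ddof=1), xb.var(axis=0, ddof=1)
    sa, sb = va / na, vb / nb
    denom2 = sa + sb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(denom2)
        df = denom2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    zero_var = denom2 <= 0
    t = np.where(zero_var, np.nan, t)
    df = np.where(zero_var, np.nan, df)
    # equal means with zero variance: no evidence of difference, t = 0 exactly
    same = zero_var & (ma == mb)
    t = np.where(same, np.nan, t)
    return t, df


def voxelwise_test(
    group_a_volumes: list[Volume],
    group_b_volumes: list[Volume],
    analysis_mask: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> StatMap:
    """Voxelwise Welch t map of group A vs group B with max-T FWE correction.

    ``p_corrected`` is the permutation max-|t| family-wise p value, floored at
    the parametric ``p_raw`` so the corrected value never undercuts the raw
    one.  Voxels with zero variance in both groups are flagged NaN and excluded
    from the correction.
    """
    if len(group_a_volumes) < 2 or len(group_b_volumes) < 2:
        raise VoxelMapError("need at least 2 subjects per group")
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    shape = group_a_volumes[0].shape
    affine = group_a_volumes[0].affine
    for v in list(group_a_volumes) + list(group_b_volumes):
        if v.shape != shape or not np.allclose(v.affine, affine):
            raise VoxelMapError("all volumes must be on the template grid")
    if analysis_mask.shape != shape or not analysis_mask.any():
        raise VoxelMapError("analysis mask empty or mismatched")

    na = len(group_a_volumes)
    pooled = np.stack([v.data[analysis_mask] for v in group_a_volumes]
                      + [v.data[analysis_mask] for v in group_b_volumes])
    n = pooled.shape[0]

    t_obs, df = _welch_t(pooled[:na], pooled[na:])
    valid = np.isfinite(t_obs)
    if not valid.any():
        raise VoxelMapError("no voxel with non-zero variance inside the analysis mask")

    p_raw = np.full(t_obs.shape, np.nan)
    p_raw[valid] = 2.0 * stats.t.sf(np.abs(t_obs[valid]), df[valid])

    rng = np.random.default_rng(seed)
    abs_obs = np.abs(t_obs[valid])
    max_t = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        t_b, _ = _welch_t(pooled[perm[:na]], pooled[perm[na:]])
        t_b = np.abs(t_b[valid])
        max_t[b] = np.nanmax(t_b) if np.isfinite(t_b).any() else 0.0

    exceed = (max_t[None, :] >= abs_obs[:, None]).sum(axis=1)
    p_corr_valid = (1.0 + exceed) / (n_permutations + 1.0)
    p_corrected = np.full(t_obs.shape, np.nan)
    p_corrected[valid] = np.minimum(1.0, np.maximum(p_corr_valid, p_raw[valid]))

    def _unflatten(values: np.ndarray) -> np.ndarray:
        out = np.full(shape, np.nan)
        out[analysis_mask] = values
        return out

    return StatMap(
        statistic=_unflatten(t_obs),
        p_raw=_unflatten(p_raw),
        p_corrected=_unflatten(p_corrected),
        mask=analysis_mask,
        affine=np.asarray(affine, dtype=float),
    )


# --------------------------------------------------------------------------- #
# ROI extraction
# --------------------------------------------------------------------------- #

_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


def _posterolateral_score(centroid_mm, sn_centroid_mm, mid_x: float) -> float:
    """Higher = more posterolateral relative to the side's SNpc centroid.

    Posterior is -y (RAS+); lateral is away from the midsagittal plane.
    """
    posterior = float(sn_centroid_mm[1] - centroid_mm[1])
    lateral = float(abs(centroid_mm[0] - mid_x) - abs(sn_centroid_mm[0] - mid_x))
    return posterior + lateral


def extract_rois(
    stat_map: StatMap,
    whole_sn_masks: dict,
    reference_mask: np.ndarray,
    alpha: float = 0.05,
    side_split_x_mm: float = 0.0,
) -> RoiSet:
    """Significant signal-loss clusters as per-side N1/N2 ROIs.

    Keeps voxels with corrected p < ``alpha`` and group A (controls) above
    group B (patients); per side of the midsagittal plane, the two largest
    26-connected components are labeled N1 (posterolateral) and N2
    (anteromedial).  A side with a single component yields N1 only plus a
    warning; a side with none is a hard error.
    """
    if not (0.0 < alpha <= 1.0):
        raise VoxelMapError(f"alpha must be in (0, 1], got {alpha}")
    with np.errstate(invalid="ignore"):
        sig = (stat_map.p_corrected < alpha) & (stat_map.statistic > 0)
    sig &= stat_map.mask
    if not sig.any():
        raise VoxelMapError(f"no significant voxels at corrected p < {alpha}")

    vol = Volume(sig.astype(np.float64), stat_map.affine)
    x_world = vol.world_x_coordinates()
    voxel_volume = vol.voxel_volume_mm3

    masks: dict = {}
    warnings: list = []
    for side in ("right", "left"):
        side_sel = x_world > side_split_x_mm if side == "right" else x_world < side_split_x_mm
        # ties exactly on the plane: assign by the sign convention (left gets x <= 0)
        if side == "left":
            side_sel = side_sel | (x_world == side_split_x_mm)
        sig_side = sig & side_sel
        if not sig_side.any():
            raise VoxelMapError(f"no significant voxels on the {side} side")
        labels, n_comp = ndi.label(sig_side, structure=_CONNECTIVITY_26)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        order = np.argsort(counts)[::-1]
        top = [int(lab) for lab in order[:2] if counts[lab] > 0]

        sn_mask = whole_sn_masks[side]
        sn_centroid = _centroid_mm(sn_mask, vol)
        comp_masks = [labels == lab for lab in top]
        scores = [
            _posterolateral_score(_centroid_mm(m, vol), sn_centroid, side_split_x_mm)
            for m in comp_masks
        ]
        if len(comp_masks) == 1:
            masks[(side, "n1")] = comp_masks[0]
            masks[(side, "n2")] = np.zeros_like(sig)
            warnings.append(f"{side}: single significant component; N2 not identified")
        else:
            i_n1 = int(np.argmax(scores))
            masks[(side, "n1")] = comp_masks[i_n1]
            masks[(side, "n2")] = comp_masks[1 - i_n1]
            if n_comp > 2:
                warnings.append(
                    f"{side}: {n_comp} components; kept the two largest"
                )
        masks[(side, "whole_sn")] = np.asarray(sn_mask, dtype=bool)

    masks["reference"] = np.asarray(reference_mask, dtype=bool)
    return RoiSet(masks, stat_map.affine, voxel_volume, warnings)


def _centroid_mm(mask: np.ndarray, vol: Volume) -> np.ndarray:
    idx = np.argwhere(mask)
    return vol.voxel_to_world(idx.mean(axis=0))
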