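"""Group template construction by iterative registration and averaging.

Each iteration rigidly registers every subject volume to the current
reference and re-averages; the initial reference is the voxelwise median of
the unregistered volumes by default (robust and order-invariant) or the first
volume.  Contrast ratios are measured in template space on the spatially
normalized subject volumes (masks fixed, images moved);
:func:`map_rois_to_subject` supports the alternative convention of carrying
template-space ROIs back into native subject space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import (
    RegistrationSettings,
    RigidTransform,
    register_rigid,
    resample,
)
from .volume import Volume

__all__ = ["TemplateResult", "build_template", "map_rois_to_subject"]


class TemplateError(RuntimeError):
    pass


@dataclass
class TemplateResult:
    template: Volume
    transforms: list  # one RigidTransform per input volume, template -> subject
    iterations_run: int
    convergence_curve: list  # per-iteration mean squared dissimilarity to the template


def _initial_reference(volumes: list[Volume], policy: str) -> Volume:
    if policy == "median":
        stack = np.stack([v.data for v in volumes])
        return Volume(np.median(stack, axis=0), volumes[0].affine.copy())
    if policy == "first":
        return volumes[0].copy()
    raise TemplateError(f"unknown initial reference policy {policy!r}")


def build_template(
    volumes: list[Volume],
    n_iter: int = 3,
    initial_reference_policy: str = "median",
    settings: RegistrationSettings | None = None,
    subject_ids: list[str] | None = None,
) -> TemplateResult:
    """Iteratively register-and-average ``volumes`` into a template.

    All volumes must share a grid for the median initial reference; the
    template lives on that grid.  Registration failures are re-raised with the
    offending subject attached.
    """
    if len(volumes) < 2:
        raise TemplateError("need at least 2 volumes to build a template")
    ids = subject_ids or [f"volume_{i}" for i in range(len(volumes))]
    if len(ids) != len(volumes):
        raise TemplateError("one subject id per volume required")
    for v in volumes[1:]:
        if v.shape != volumes[0].shape or not np.allclose(v.affine, volumes[0].affine):
            raise TemplateError("all volumes must share the same grid")

    reference = _initial_reference(volumes, initial_reference_policy)
    transforms: list[RigidTransform] = []
    curve: list[float] = []

    for _ in range(max(1, n_iter)):
        transforms = []
        aligned = []
        for sid, vol in zip(ids, volumes):
            try:
                result = register_rigid(vol, reference, settings)
            except Exception as exc:  # attach the subject to the failure
                raise TemplateError(f"registration failed for subject {sid}: {exc}") from exc
            transforms.append(result.transform)
            aligned.append(resample(vol, result.transform, reference.shape, reference.affine))
        stack = np.stack([a.data for a in aligned])
        reference = Volume(stack.mean(axis=0), reference.affine.copy())
        curve.append(float(np.mean((stack - reference.data) ** 2)))

    return TemplateResult(reference, transforms, max(1, n_iter), curve)


def map_rois_to_subject(
    masks: dict,
    xform: RigidTransform,
    subject: Volume,
    template_affine: np.ndarray | None = None,
) -> dict:
    """Carry template-space label masks into a subject's native space.

    ``xform`` is the template->subject transform returned for that subject by
    :func:`build_template` (fixed=template, moving=subject); masks are mapped
    through its inverse with nearest-neighbour resampling.  Raises when a mask
    lands entirely outside the subject field of view.
    """
    if template_affine is None:
        template_affine = subject.affine
    out: dict = {}
    for name, mask in masks.items():
        mask = np.asarray(mask)
        mapped = resample(
            Volume(mask.astype(np.float64), template_affine),
            xform.inverse(),
            subject.shape,
            subject.affine,
            fill_value=0.0,
            order=0,
        )
        m = mapped.data > 0.5
        if mask.any() and not m.any():
            raise TemplateError(f"ROI {name!r} falls outside the subject field of view")
        out[name] = m
    return out
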