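"""Spatial and intensity normalization of subject volumes.

Implements the preprocessing contract of the pipeline: rigid registration
(moving-to-fixed, sub-voxel recovery of in-range transforms), trilinear
resampling onto a target grid, reference-region intensity normalization and
foreground (skull-strip surrogate) masking.

Conventions
-----------
World coordinates are mm, RAS+.  A :class:`RigidTransform` maps points in the
*fixed* (target) world frame to the *moving* (source) world frame, matching the
ITK convention, so resampling a moving image through the transform returned by
:func:`register_rigid` aligns it with the fixed image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial.transform import Rotation

from .volume import Volume

__all__ = [
    "RigidTransform",
    "RegistrationSettings",
    "RegistrationResult",
    "register_rigid",
    "resample",
    "normalize_intensity",
    "strip_background",
    "transform_difference",
]


class PreprocessError(RuntimeError):
    pass


# --------------------------------------------------------------------------- #
# Rigid transforms
# --------------------------------------------------------------------------- #


@dataclass
class RigidTransform:
    """Rigid body transform: rotation (extrinsic x-y-z Euler angles, degrees)
    about ``center_mm``, followed by translation (mm).

    Maps a fixed-frame point p to R (p - c) + c + t in the moving frame.
    """

    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float).reshape(3)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)

    # -- matrix forms -------------------------------------------------------

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def as_affine(self) -> np.ndarray:
        """Homogeneous 4x4 world-to-world map."""
        R = self.rotation_matrix
        A = np.eye(4)
        A[:3, :3] = R
        A[:3, 3] = self.translation_mm + self.center_mm - R @ self.center_mm
        return A

    @classmethod
    def from_affine(cls, A: np.ndarray, center_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        A = np.asarray(A, dtype=float)
        R = A[:3, :3]
        center = np.asarray(center_mm, dtype=float)
        angles = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        translation = A[:3, 3] - center + R @ center
        return cls(angles, translation, center)

    # -- algebra -------------------------------------------------------------

    @classmethod
    def identity(cls, center_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), np.asarray(center_mm, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        A = self.as_affine()
        return points @ A[:3, :3].T + A[:3, 3]

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_affine(np.linalg.inv(self.as_affine()), self.center_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform.from_affine(self.as_affine() @ other.as_affine(), self.center_mm)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation_deg.tolist(),
            "translation_mm": self.translation_mm.tolist(),
            "center_mm": self.center_mm.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(d["rotation_deg"], d["translation_mm"], d["center_mm"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def transform_difference(
    a: RigidTransform, b: RigidTransform, at_point=None
) -> tuple[float, float]:
    """Rotation-angle (deg) and displacement (mm) difference between transforms.

    The displacement is measured at ``at_point`` (default: the shared rotation
    center of ``a``), i.e. how far the two transforms move that point apart.
    """
    Ra = a.rotation_matrix
    Rb = b.rotation_matrix
    R = Ra @ Rb.T
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    rot_deg = float(np.degrees(np.arccos(cos_theta)))
    p = np.asarray(at_point if at_point is not None else a.center_mm, dtype=float)
    trans_mm = float(np.linalg.norm(a.apply(p) - b.apply(p)))
    return rot_deg, trans_mm


# --------------------------------------------------------------------------- #
# Resampling
# --------------------------------------------------------------------------- #


def resample(
    vol: Volume,
    xform: RigidTransform,
    target_shape=None,
    target_affine=None,
    fill_value: float = 0.0,
    order: int = 1,
) -> Volume:
    """Resample ``vol`` onto a target grid through ``xform`` (fixed -> moving).

    Trilinear by default (``order=1``); ``order=0`` gives nearest-neighbour for
    label masks.  Voxels mapping outside the source field of view are set to
    ``fill_value``.
    """
    if target_shape is None:
        target_shape = vol.shape
    if target_affine is None:
        target_affine = vol.affine
    M = np.linalg.inv(vol.affine) @ xform.as_affine() @ np.asarray(target_affine)
    data = ndi.affine_transform(
        vol.data,
        M[:3, :3],
        offset=M[:3, 3],
        output_shape=tuple(target_shape),
        order=order,
        mode="constant",
        cval=fill_value,
        prefilter=order > 1,
    )
    return Volume(data, np.asarray(target_affine, dtype=float))


# --------------------------------------------------------------------------- #
# Rigid registration (SimpleITK backend)
# --------------------------------------------------------------------------- #


@dataclass
class RegistrationSettings:
    """Deterministic multi-resolution mean-squared-error registration settings.

    Sampling is dense (no random subsampling) and the optimizer is single
    threaded, so identical inputs yield identical transforms.  ``multi_start``
    is a fixed list of initial rotation offsets (degrees) tried in order; the
    best final metric wins.
    """

    metric: str = "mse"
    shrink_factors: tuple[int, ...] = (8, 4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (3.0, 2.0, 1.0, 0.0)
    max_iterations: int = 300
    learning_rate: float = 0.2
    min_step: float = 1e-5
    multi_start: tuple[tuple[float, float, float], ...] = ((0.0, 0.0, 0.0),)


@dataclass
class RegistrationResult:
    transform: RigidTransform
    converged: bool
    final_metric: float
    message: str = ""


def _require_axis_aligned(vol: Volume) -> None:
    R = vol.affine[:3, :3]
    if not np.allclose(R, np.diag(np.diag(R))) or np.any(np.diag(R) <= 0):
        raise PreprocessError("registration requires axis-aligned RAS+ grids")


def _to_sitk(vol: Volume):
    import SimpleITK as sitk

    _require_axis_aligned(vol)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0), dtype=np.float64))
    img.SetSpacing(tuple(np.diag(vol.affine[:3, :3])))
    img.SetOrigin(tuple(vol.affine[:3, 3]))
    return img


def register_rigid(
    moving: Volume, fixed: Volume, settings: RegistrationSettings | None = None
) -> RegistrationResult:
    """Estimate the rigid transform aligning ``moving`` to ``fixed``.

    Returns a transform in the fixed->moving convention suitable for
    :func:`resample`\\ ``(moving, transform, fixed grid)``.  Non-convergence
    within the iteration cap is flagged, not raised; the best transform found
    is still returned.
    """
    import SimpleITK as sitk

    settings = settings or RegistrationSettings()
    if settings.metric != "mse":
        raise PreprocessError(f"unsupported metric: {settings.metric!r}")

    sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)
    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)

    best: tuple[float, RigidTransform, bool, str] | None = None
    for start_deg in settings.multi_start:
        initial = sitk.CenteredTransformInitializer(
            f_img, m_img, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
        )
        initial = sitk.Euler3DTransform(initial)
        rx, ry, rz = np.radians(np.asarray(start_deg, dtype=float))
        initial.SetRotation(rx, ry, rz)

        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=settings.learning_rate,
            minStep=settings.min_step,
            numberOfIterations=settings.max_iterations,
            relaxationFactor=0.5,
            gradientMagnitudeTolerance=1e-8,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel(list(settings.shrink_factors))
        reg.SetSmoothingSigmasPerLevel(list(settings.smoothing_sigmas))
        reg.SetInitialTransform(initial, inPlace=True)

        final = sitk.Euler3DTransform(reg.Execute(f_img, m_img))
        metric = float(reg.GetMetricValue())
        stop = reg.GetOptimizerStopConditionDescription()
        converged = "Maximum number of iterations" not in stop

        R = np.asarray(final.GetMatrix(), dtype=float).reshape(3, 3)
        center = np.asarray(final.GetCenter(), dtype=float)
        t = np.asarray(final.GetTranslation(), dtype=float)
        A = np.eye(4)
        A[:3, :3] = R
        A[:3, 3] = t + center - R @ center
        xform = RigidTransform.from_affine(A, center_mm=center)

        if best is None or metric < best[0]:
            best = (metric, xform, converged, stop)

    assert best is not None
    metric, xform, converged, stop = best
    if not converged:
        warnings.warn(f"rigid registration did not converge: {stop}", stacklevel=2)
    return RegistrationResult(xform, converged, metric, stop)


# --------------------------------------------------------------------------- #
# Intensity normalization and foreground masking
# --------------------------------------------------------------------------- #


def normalize_intensity(vol: Volume, reference_mask: np.ndarray) -> Volume:
    """Divide by the mean intensity inside ``reference_mask``.

    After normalization the reference region has mean 1.0, which makes
    contrast ratios directly comparable across subjects.  Idempotent.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != vol.shape:
        raise PreprocessError("reference mask shape does not match volume")
    if not reference_mask.any():
        raise PreprocessError("reference mask is empty")
    ref_mean = float(vol.data[reference_mask].mean())
    if ref_mean <= 0:
        raise PreprocessError(f"reference mean must be positive, got {ref_mean}")
    return Volume(vol.data / ref_mean, vol.affine.copy())


def strip_background(vol: Volume, closing_iterations: int = 2) -> np.ndarray:
    """Foreground mask: Otsu-style threshold, largest component, closing.

    Serves as the skull-strip surrogate on phantoms, where the head region is
    a bright body on a dark background.
    """
    data = vol.data
    lo, hi = float(data.min()), float(data.max())
    if hi - lo <= 0 or not np.isfinite(hi - lo):
        raise PreprocessError("no separable foreground: volume is constant")

    threshold = _otsu_threshold(data)
    fg = data > threshold
    if not fg.any():
        raise PreprocessError("no separable foreground found")

    labels, n = ndi.label(fg)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == int(np.argmax(counts))
    if closing_iterations > 0:
        fg = ndi.binary_closing(fg, iterations=closing_iterations)
        fg |= ndi.binary_fill_holes(fg)
    return fg


def _otsu_threshold(data: np.ndarray, bins: int = 256) -> float:
    """Threshold maximizing between-class variance of the intensity histogram."""
    hist, edges = np.histogram(data.ravel(), bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return float(centers[int(np.argmax(sigma_b))])
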