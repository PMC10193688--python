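"""Synthetic neuromelanin-MRI midbrain phantoms with known ground truth.

The phantom emulates the statistical structure the analysis assumes: two
groups (patients and controls), bilateral hyperintense SNpc bodies containing
a larger posterolateral subregion (N1) and a smaller anteromedial subregion
(N2), patient-specific fractional signal loss graded N1 > N2 > remaining SNpc,
a left/right asymmetry coupled to simulated clinical laterality, between-subject
regional neuromelanin variability in both groups, per-subject rigid
misalignment, global intensity scaling and additive noise.

Geometry is parametric-analytic (ellipsoid primitives, sizes in mm), so the
generator is exactly reproducible and grid-size independent: the same anatomy
is rendered on any grid large enough to contain it.  Ground-truth masks,
transforms and per-subject drawn deficits are recorded for parameter-recovery
testing.

Full cohort generation is a pure function of (config, seed): identical inputs
give bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RigidTransform, resample
from .volume import Volume, make_grid_affine

__all__ = [
    "PhantomConfig",
    "PhantomConfigError",
    "GroundTruth",
    "SubjectRecord",
    "SubjectTruth",
    "Cohort",
    "make_canonical_anatomy",
    "simulate_subject",
    "generate_cohort",
    "write_cohort",
    "SIDES",
    "REGIONS",
]

SIDES = ("right", "left")
REGIONS = ("n1", "n2", "whole_sn")


class PhantomConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings.

    Intensities are arbitrary units; with the defaults the canonical contrast
    ratio of every SNpc region against the reference region is
    (120 - 100) / 100 = 0.2.  Deficits are fractional signal reductions applied
    to patients, graded N1 > N2 > rest of the SNpc; ``asymmetry_boost`` is the
    extra deficit on the side contralateral to the simulated dominant symptom
    side.  Misalignment scales are per-subject rigid perturbation SDs (capped
    at 6 degrees / 3 mm).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: float = 0.8
    n_per_group: int = 50
    background_intensity: float = 100.0
    snpc_intensity: float = 120.0
    n1_deficit_mean: float = 0.095
    n2_deficit_mean: float = 0.085
    sn_deficit_mean: float = 0.01
    deficit_sd: float = 0.025
    asymmetry_boost: float = 0.01
    regional_variability_sd: float = 0.04
    noise_sd: float = 5.0
    noise_model: str = "gaussian"  # or "rician"
    misalign_rot_deg_sd: float = 2.0
    misalign_trans_mm_sd: float = 1.0
    intensity_scale_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 8 for s in self.grid_shape):
            raise PhantomConfigError(f"invalid grid shape {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise PhantomConfigError("voxel size must be positive")
        if self.n_per_group < 2:
            raise PhantomConfigError("need at least 2 subjects per group")
        for name in ("n1_deficit_mean", "n2_deficit_mean", "sn_deficit_mean", "asymmetry_boost"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise PhantomConfigError(f"{name} must be in [0, 1), got {v}")
        for name in ("deficit_sd", "regional_variability_sd", "noise_sd",
                     "misalign_rot_deg_sd", "misalign_trans_mm_sd", "intensity_scale_sd"):
            if getattr(self, name) < 0:
                raise PhantomConfigError(f"{name} must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise PhantomConfigError(f"unknown noise model {self.noise_model!r}")
        if self.background_intensity <= 0:
            raise PhantomConfigError("background intensity must be positive")

    def replace(self, **kw) -> "PhantomConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PhantomConfigError(f"unknown phantom config keys: {sorted(unknown)}")
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(int(v) for v in d["grid_shape"])
        if "seed" in d and not isinstance(d["seed"], (int, np.integer)):
            raise PhantomConfigError(f"seed must be an integer, got {d['seed']!r}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


# --------------------------------------------------------------------------- #
# Anatomy: ellipsoid geometry in mm, centred on the world origin
# --------------------------------------------------------------------------- #

# Centers/semi-axes in mm relative to the grid centre.  The SNpc sits lateral
# to the midline; N1 is posterolateral and larger (and larger on the left,
# matching the asymmetry of the template ROIs), N2 anteromedial and smaller.
# The reference region is a homogeneous midline area anterior to the SNpc
# (tegmentum/decussation surrogate), never modified by disease effects.
_GEOMETRY = {
    # anisotropic on purpose: a head with three distinct axes gives the rigid
    # registration a well-conditioned rotational signal
    "head": {"center": (0.0, 0.0, 0.0), "semi_axes_frac": (0.44, 0.36, 0.42)},
    "sn_lateral_offset": 7.2,
    "sn": {"center_y": -1.6, "semi_axes": (3.2, 6.4, 4.8)},
    "n1": {
        "offset": (1.2, -2.8, 0.0),  # lateral, posterior
        "semi_axes": {"left": (1.8, 2.6, 2.2), "right": (1.6, 2.2, 2.0)},
    },
    "n2": {
        "offset": (-1.2, 2.8, 0.0),  # medial, anterior
        "semi_axes": {"left": (1.7, 2.3, 2.0), "right": (1.5, 2.0, 1.8)},
    },
    "reference": {"center": (0.0, 6.4, 0.0), "semi_axes": (2.4, 2.4, 3.2)},
}


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "IPD" or "HC"
    right_motor_score: int
    left_motor_score: int
    image_path: str = ""

    def __post_init__(self) -> None:
        if self.group not in ("IPD", "HC"):
            raise ValueError(f"group must be IPD or HC, got {self.group!r}")
        if self.right_motor_score < 0 or self.left_motor_score < 0:
            raise ValueError("motor scores must be non-negative")


@dataclass
class SubjectTruth:
    """Drawn per-subject simulation parameters."""

    group: str
    intensity_scale: float
    transform: RigidTransform
    dominant_symptom_side: str | None  # None for controls
    # deficits[side][region] with region in {"n1", "n2", "sn_rest"}
    deficits: dict = field(default_factory=dict)
    # regional_variability[side][region]: multiplicative biological variation
    # (both groups); the region signal is scaled by (1 + b) * (1 - deficit)
    regional_variability: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "intensity_scale": self.intensity_scale,
            "transform": self.transform.to_dict(),
            "dominant_symptom_side": self.dominant_symptom_side,
            "deficits": self.deficits,
            "regional_variability": self.regional_variability,
        }


@dataclass
class GroundTruth:
    """Canonical masks plus per-subject drawn parameters."""

    masks: dict  # keys: (side, region) for region masks, "reference", "head"
    voxel_volume_mm3: float
    subjects: dict = field(default_factory=dict)  # subject_id -> SubjectTruth

    def mask(self, side: str, region: str) -> np.ndarray:
        return self.masks[(side, region)]

    @property
    def reference_mask(self) -> np.ndarray:
        return self.masks["reference"]

    def volume_mm3(self, side: str, region: str) -> float:
        return float(self.mask(side, region).sum()) * self.voxel_volume_mm3

    def analysis_mask(self, margin_voxels: int = 2) -> np.ndarray:
        """Both whole-SNpc masks dilated by a safety margin."""
        import scipy.ndimage as ndi

        m = self.mask("left", "whole_sn") | self.mask("right", "whole_sn")
        if margin_voxels > 0:
            m = ndi.binary_dilation(m, iterations=margin_voxels)
        return m

    def to_dict(self) -> dict:
        return {
            "voxel_volume_mm3": self.voxel_volume_mm3,
            "mask_volumes_mm3": {
                f"{side}_{region}": self.volume_mm3(side, region)
                for side in SIDES
                for region in REGIONS
            },
            "subjects": {sid: t.to_dict() for sid, t in sorted(self.subjects.items())},
        }


def _ellipsoid_mask(shape, affine, center_mm, semi_axes_mm) -> np.ndarray:
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    R = affine[:3, :3]
    t = affine[:3, 3]
    x = ii * R[0, 0] + t[0]
    y = jj * R[1, 1] + t[1]
    z = kk * R[2, 2] + t[2]
    cx, cy, cz = center_mm
    ax, ay, az = semi_axes_mm
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def make_canonical_anatomy(config: PhantomConfig) -> tuple[Volume, GroundTruth]:
    """Noise-free canonical volume plus ground-truth masks.

    Raises :class:`PhantomConfigError` when the grid is too small to contain
    all structures.
    """
    config.validate()
    shape = tuple(int(s) for s in config.grid_shape)
    affine = make_grid_affine(shape, config.voxel_size_mm)
    g = _GEOMETRY

    fov_mm = np.asarray(shape) * config.voxel_size_mm
    head_axes = np.asarray(g["head"]["semi_axes_frac"]) * fov_mm
    head = _ellipsoid_mask(shape, affine, g["head"]["center"], head_axes)

    masks: dict = {"head": head}
    for side, sign in (("right", +1.0), ("left", -1.0)):
        sn_center = np.array([sign * g["sn_lateral_offset"], g["sn"]["center_y"], 0.0])
        sn = _ellipsoid_mask(shape, affine, sn_center, g["sn"]["semi_axes"])
        n1_off = np.array(g["n1"]["offset"])
        n2_off = np.array(g["n2"]["offset"])
        n1_center = sn_center + np.array([sign * n1_off[0], n1_off[1], n1_off[2]])
        n2_center = sn_center + np.array([sign * n2_off[0], n2_off[1], n2_off[2]])
        n1 = _ellipsoid_mask(shape, affine, n1_center, g["n1"]["semi_axes"][side]) & sn
        n2 = _ellipsoid_mask(shape, affine, n2_center, g["n2"]["semi_axes"][side]) & sn & ~n1
        masks[(side, "whole_sn")] = sn
        masks[(side, "n1")] = n1
        masks[(side, "n2")] = n2
    masks["reference"] = _ellipsoid_mask(
        shape, affine, g["reference"]["center"], g["reference"]["semi_axes"]
    )

    _check_anatomy(masks, head)

    data = np.zeros(shape, dtype=np.float64)
    data[head] = config.background_intensity
    sn_both = masks[("left", "whole_sn")] | masks[("right", "whole_sn")]
    data[sn_both] = config.snpc_intensity

    vol = Volume(data, affine)
    truth = GroundTruth(masks=masks, voxel_volume_mm3=vol.voxel_volume_mm3)
    return vol, truth


def _check_anatomy(masks: dict, head: np.ndarray) -> None:
    for key in [(s, r) for s in SIDES for r in REGIONS] + ["reference"]:
        m = masks[key]
        if not m.any():
            raise PhantomConfigError(f"grid too small: structure {key} is empty")
        # structure must not touch the grid boundary (would be clipped)
        if (
            m[0].any() or m[-1].any()
            or m[:, 0].any() or m[:, -1].any()
            or m[:, :, 0].any() or m[:, :, -1].any()
        ):
            raise PhantomConfigError(f"grid too small: structure {key} touches the boundary")
        if not (m & ~head).sum() == 0:
            raise PhantomConfigError(f"structure {key} extends outside the head region")
    for side in SIDES:
        if (masks[(side, "n1")] & masks[(side, "n2")]).any():
            raise PhantomConfigError("N1 and N2 overlap")
        if (masks["reference"] & masks[(side, "whole_sn")]).any():
            raise PhantomConfigError("reference region overlaps the SNpc")
        if masks[(side, "n1")].sum() <= masks[(side, "n2")].sum():
            raise PhantomConfigError("N1 must be larger than N2 on each side")
    if masks[("left", "n1")].sum() <= masks[("right", "n1")].sum():
        raise PhantomConfigError("left N1 must be larger than right N1")


# --------------------------------------------------------------------------- #
# Subject simulation
# --------------------------------------------------------------------------- #

_MAX_ROT_DEG = 6.0
_MAX_TRANS_MM = 3.0
_DEFICIT_CAP = 0.95
_MAX_REGIONAL_VARIABILITY = 0.3


def _contralateral(side: str) -> str:
    return "left" if side == "right" else "right"


def simulate_subject(
    canonical: Volume,
    truth: GroundTruth,
    record: SubjectRecord,
    config: PhantomConfig,
    rng: np.random.Generator,
    dominant_side: str | None = None,
) -> tuple[Volume, SubjectTruth]:
    """One noisy subject volume from the canonical anatomy.

    Every subject (both groups) receives a per-subject, per-side, per-region
    multiplicative neuromelanin variability drawn from
    N(0, ``regional_variability_sd``): without between-subject regional
    variance in controls, the whole-SNpc mean would be an implausibly
    noise-free discriminator.  Patients additionally lose signal inside N1,
    N2 and the remaining SNpc, with an extra ``asymmetry_boost`` on the side
    contralateral to the simulated dominant symptom side.  Both groups also
    get a global intensity scale, a rigid perturbation and voxel noise.  The
    drawn parameters are logged in the returned :class:`SubjectTruth` (and
    into ``truth.subjects``).
    """
    data = canonical.data.copy()
    deficits: dict = {s: {"n1": 0.0, "n2": 0.0, "sn_rest": 0.0} for s in SIDES}
    variability: dict = {s: {"n1": 0.0, "n2": 0.0, "sn_rest": 0.0} for s in SIDES}

    if record.group == "IPD":
        if dominant_side is None:
            dominant_side = str(rng.choice(SIDES))
        boosted = _contralateral(dominant_side)
        base = {
            "n1": rng.normal(config.n1_deficit_mean, config.deficit_sd),
            "n2": rng.normal(config.n2_deficit_mean, config.deficit_sd),
            "sn_rest": rng.normal(config.sn_deficit_mean, config.deficit_sd),
        }
        for side in SIDES:
            boost = config.asymmetry_boost if side == boosted else 0.0
            for region in ("n1", "n2", "sn_rest"):
                deficits[side][region] = float(np.clip(base[region] + boost, 0.0, _DEFICIT_CAP))
    else:
        dominant_side = None

    if config.regional_variability_sd > 0:
        for side in SIDES:
            for region in ("n1", "n2", "sn_rest"):
                variability[side][region] = float(
                    np.clip(
                        rng.normal(0.0, config.regional_variability_sd),
                        -_MAX_REGIONAL_VARIABILITY,
                        _MAX_REGIONAL_VARIABILITY,
                    )
                )

    for side in SIDES:
        n1 = truth.mask(side, "n1")
        n2 = truth.mask(side, "n2")
        rest = truth.mask(side, "whole_sn") & ~n1 & ~n2
        for region, mask in (("n1", n1), ("n2", n2), ("sn_rest", rest)):
            factor = (1.0 + variability[side][region]) * (1.0 - deficits[side][region])
            if factor != 1.0:
                data[mask] *= factor

    scale = 1.0
    if config.intensity_scale_sd > 0:
        scale = float(max(rng.normal(1.0, config.intensity_scale_sd), 0.2))
    data *= scale

    center = canonical.world_center()
    if config.misalign_rot_deg_sd > 0 or config.misalign_trans_mm_sd > 0:
        rot = np.clip(
            rng.normal(0.0, config.misalign_rot_deg_sd, 3), -_MAX_ROT_DEG, _MAX_ROT_DEG
        )
        trans = np.clip(
            rng.normal(0.0, config.misalign_trans_mm_sd, 3), -_MAX_TRANS_MM, _MAX_TRANS_MM
        )
        xform = RigidTransform(rot, trans, center)
        out = resample(Volume(data, canonical.affine), xform, fill_value=0.0)
        data = out.data
    else:
        xform = RigidTransform.identity(center)

    if config.noise_sd > 0:
        if config.noise_model == "rician":
            n1_ = rng.normal(0.0, config.noise_sd, data.shape)
            n2_ = rng.normal(0.0, config.noise_sd, data.shape)
            data = np.sqrt((data + n1_) ** 2 + n2_**2)
        else:
            data = data + rng.normal(0.0, config.noise_sd, data.shape)

    sub_truth = SubjectTruth(
        group=record.group,
        intensity_scale=scale,
        transform=xform,
        dominant_symptom_side=dominant_side,
        deficits=deficits,
        regional_variability=variability,
    )
    truth.subjects[record.subject_id] = sub_truth
    return Volume(data, canonical.affine.copy()), sub_truth


# --------------------------------------------------------------------------- #
# Cohort generation and on-disk layout
# --------------------------------------------------------------------------- #


@dataclass
class Cohort:
    records: pd.DataFrame  # SubjectRecord rows
    volumes: dict  # subject_id -> Volume
    canonical: Volume
    truth: GroundTruth
    config: PhantomConfig


def _draw_motor_scores(group: str, dominant: str | None, rng: np.random.Generator):
    """UPDRS-III-like per-side sums.

    Patients get a higher score on the dominant symptom side; the gap is drawn
    so roughly a quarter of patients stay below the two-point laterality cutoff
    (clinically indeterminate).  Controls score low and symmetrically.
    """
    if group == "HC":
        return int(rng.integers(0, 3)), int(rng.integers(0, 3))
    base = int(rng.integers(4, 10))
    gap = int(rng.integers(0, 8))
    dom_score, other_score = base + gap, base
    if dominant == "right":
        return dom_score, other_score
    return other_score, dom_score


def generate_cohort(config: PhantomConfig) -> Cohort:
    """Full synthetic cohort: records, volumes and ground truth.

    Pure function of (config, seed): subjects are generated in a fixed order
    (controls first) from a single RNG stream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    canonical, truth = make_canonical_anatomy(config)

    rows = []
    volumes: dict = {}
    for group, prefix in (("HC", "hc"), ("IPD", "ipd")):
        for i in range(config.n_per_group):
            sid = f"{prefix}_{i + 1:03d}"
            dominant = str(rng.choice(SIDES)) if group == "IPD" else None
            right, left = _draw_motor_scores(group, dominant, rng)
            record = SubjectRecord(sid, group, right, left)
            vol, _ = simulate_subject(canonical, truth, record, config, rng, dominant)
            volumes[sid] = vol
            rows.append(record)

    records = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in rows],
            "group": [r.group for r in rows],
            "right_motor_score": [r.right_motor_score for r in rows],
            "left_motor_score": [r.left_motor_score for r in rows],
            "image_path": [r.image_path for r in rows],
        }
    )
    return Cohort(records, volumes, canonical, truth, config)


def write_cohort(config: PhantomConfig, out_dir) -> dict:
    """Write a cohort to disk: one NIfTI per subject, cohort CSV, masks, truth JSON.

    Re-running with the same config and seed reproduces identical CSV/JSON
    content.  Returns the paths written.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        images = out / "images"
        images.mkdir(exist_ok=True)
        cohort = generate_cohort(config)

        paths = []
        for sid in cohort.records["subject_id"]:
            p = images / f"{sid}.nii"
            cohort.volumes[sid].save(p)
            paths.append(str(p.relative_to(out)))
        cohort.records["image_path"] = paths

        csv_path = out / "cohort.csv"
        cohort.records.to_csv(csv_path, index=False)

        label_path = out / "ground_truth_masks.nii"
        legend = save_mask_labels(cohort.truth, cohort.canonical.affine, label_path)
        legend_path = out / "ground_truth_masks.json"
        with open(legend_path, "w") as fh:
            json.dump(legend, fh, indent=2, sort_keys=True)

        gt_path = out / "ground_truth.json"
        gt = cohort.truth.to_dict()
        gt["config"] = config.to_dict()
        with open(gt_path, "w") as fh:
            json.dump(gt, fh, indent=2, sort_keys=True)
    except OSError as exc:
        raise OSError(f"failed writing cohort under {out}: {exc}") from exc

    return {
        "cohort_csv": csv_path,
        "ground_truth_json": gt_path,
        "mask_labels": label_path,
        "mask_legend": legend_path,
        "out_dir": out,
    }


_LABEL_ORDER = [
    ("right", "n1"), ("left", "n1"),
    ("right", "n2"), ("left", "n2"),
    ("right", "whole_sn"), ("left", "whole_sn"),
]


def save_mask_labels(truth: GroundTruth, affine: np.ndarray, path) -> dict:
    """Integer label volume for the ground-truth masks plus a JSON-able legend.

    N1/N2 get their own labels; whole-SNpc voxels not in N1/N2 get the
    whole-SN label; the reference region is last.  Later labels never
    overwrite earlier ones.
    """
    shape = truth.masks["reference"].shape
    labels = np.zeros(shape, dtype=np.int16)
    legend = {}
    value = 0
    for side, region in _LABEL_ORDER:
        value += 1
        m = truth.mask(side, region) & (labels == 0)
        labels[m] = value
        legend[f"{side}_{region}"] = {
            "label": value,
            "volume_mm3": truth.volume_mm3(side, region),
        }
    value += 1
    labels[truth.reference_mask & (labels == 0)] = value
    legend["reference"] = {
        "label": value,
        "volume_mm3": float(truth.reference_mask.sum()) * truth.voxel_volume_mm3,
    }
    Volume(labels.astype(np.float64), affine).save(path)
    return legend


def load_mask_labels(label_path, legend_path) -> tuple[dict, np.ndarray]:
    """Rebuild (side, region)/reference masks from a label volume + legend.

    The whole-SN masks are reassembled as the union of the side's N1, N2 and
    whole-SN labels.  Returns (masks dict, affine).
    """
    vol = Volume.load(label_path)
    with open(legend_path) as fh:
        legend = json.load(fh)
    labels = np.rint(vol.data).astype(int)
    masks: dict = {}
    for side in SIDES:
        n1 = labels == legend[f"{side}_n1"]["label"]
        n2 = labels == legend[f"{side}_n2"]["label"]
        sn = labels == legend[f"{side}_whole_sn"]["label"]
        masks[(side, "n1")] = n1
        masks[(side, "n2")] = n2
        masks[(side, "whole_sn")] = n1 | n2 | sn
    masks["reference"] = labels == legend["reference"]["label"]
    return masks, vol.affine
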