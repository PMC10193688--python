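"""Phantom generator: anatomy invariants, effect injection, determinism, I/O."""

import json

import numpy as np
import pandas as pd
import pytest

from nigramap.contrast import contrast_ratio
from nigramap.phantom import (
    PhantomConfig,
    PhantomConfigError,
    SubjectRecord,
    generate_cohort,
    make_canonical_anatomy,
    simulate_subject,
    write_cohort,
    SIDES,
)

from conftest import NOISE_FREE, NO_DEFICITS


# --------------------------------------------------------------------------- #
# Canonical anatomy
# --------------------------------------------------------------------------- #


def test_anatomy_mask_invariants(canonical):
    _, truth = canonical
    for side in SIDES:
        n1 = truth.mask(side, "n1")
        n2 = truth.mask(side, "n2")
        sn = truth.mask(side, "whole_sn")
        assert not (n1 & n2).any()
        assert (n1 & ~sn).sum() == 0 and (n2 & ~sn).sum() == 0
        assert not (truth.reference_mask & sn).any()
        assert n1.sum() > n2.sum()


def test_left_n1_larger_than_right_n1(canonical):
    _, truth = canonical
    assert truth.volume_mm3("left", "n1") > truth.volume_mm3("right", "n1")


def test_no_contrast_when_intensities_equal():
    cfg = PhantomConfig(snpc_intensity=100.0, background_intensity=100.0)
    vol, truth = make_canonical_anatomy(cfg)
    for side in SIDES:
        for region in ("n1", "n2", "whole_sn"):
            cr = contrast_ratio(vol, truth.mask(side, region), truth.reference_mask)
            assert cr == 0.0


def test_canonical_contrast_ratio_default(canonical):
    vol, truth = canonical
    for side in SIDES:
        cr = contrast_ratio(vol, truth.mask(side, "n1"), truth.reference_mask)
        assert cr == pytest.approx(0.2, abs=1e-12)


def test_grid_too_small_raises():
    with pytest.raises(PhantomConfigError):
        make_canonical_anatomy(PhantomConfig(grid_shape=(16, 16, 16)))


# --------------------------------------------------------------------------- #
# Subject simulation
# --------------------------------------------------------------------------- #


def test_clean_subject_equals_canonical_times_scale(canonical, rng):
    vol, truth = canonical
    cfg = PhantomConfig(**{**NOISE_FREE, **NO_DEFICITS, "intensity_scale_sd": 0.1})
    rec = SubjectRecord("hc_x", "HC", 1, 1)
    out, sub = simulate_subject(vol, truth, rec, cfg, rng)
    assert sub.intensity_scale != 1.0
    np.testing.assert_array_equal(out.data, vol.data * sub.intensity_scale)


def test_exact_deficit_injection(canonical, rng):
    vol, truth = canonical
    cfg = PhantomConfig(
        **NOISE_FREE, n1_deficit_mean=0.3, n2_deficit_mean=0.1,
        sn_deficit_mean=0.05, asymmetry_boost=0.0,
    )
    rec = SubjectRecord("ipd_x", "IPD", 9, 4)
    out, _ = simulate_subject(vol, truth, rec, cfg, rng)
    for side in SIDES:
        n1 = truth.mask(side, "n1")
        assert out.data[n1].mean() == pytest.approx(vol.data[n1].mean() * 0.7, rel=1e-12)


def test_effect_injection_fidelity_all_regions(canonical, rng):
    vol, truth = canonical
    cfg = PhantomConfig(
        **NOISE_FREE, n1_deficit_mean=0.12, n2_deficit_mean=0.08,
        sn_deficit_mean=0.03, asymmetry_boost=0.0,
    )
    rec = SubjectRecord("ipd_x", "IPD", 9, 4)
    out, sub = simulate_subject(vol, truth, rec, cfg, rng)
    for side in SIDES:
        for region, deficit in (("n1", 0.12), ("n2", 0.08)):
            m = truth.mask(side, region)
            reduction = 1.0 - out.data[m].mean() / vol.data[m].mean()
            assert reduction == pytest.approx(deficit, abs=1e-12)
            assert sub.deficits[side][region] == deficit


def test_asymmetry_boost_on_contralateral_side(canonical, rng):
    vol, truth = canonical
    cfg = PhantomConfig(**NOISE_FREE, n1_deficit_mean=0.1, asymmetry_boost=0.05)
    rec = SubjectRecord("ipd_x", "IPD", 9, 4)
    _, sub = simulate_subject(vol, truth, rec, cfg, rng, dominant_side="right")
    assert sub.deficits["left"]["n1"] == pytest.approx(0.15)
    assert sub.deficits["right"]["n1"] == pytest.approx(0.10)


def test_control_gets_no_deficit_but_regional_variability(canonical, rng):
    vol, truth = canonical
    cfg = PhantomConfig(**{**NOISE_FREE, "regional_variability_sd": 0.05})
    rec = SubjectRecord("hc_x", "HC", 1, 0)
    out, sub = simulate_subject(vol, truth, rec, cfg, rng)
    assert all(v == 0.0 for side in SIDES for v in sub.deficits[side].values())
    b = sub.regional_variability["left"]["n1"]
    assert b != 0.0
    m = truth.mask("left", "n1")
    assert out.data[m].mean() == pytest.approx(vol.data[m].mean() * (1 + b), rel=1e-12)


def test_monotone_deficit_response(canonical):
    vol, truth = canonical
    means = []
    for deficit in (0.05, 0.15, 0.30):
        rng = np.random.default_rng(0)
        cfg = PhantomConfig(**NOISE_FREE, n1_deficit_mean=deficit, asymmetry_boost=0.0)
        rec = SubjectRecord("ipd_x", "IPD", 9, 4)
        out, _ = simulate_subject(vol, truth, rec, cfg, rng)
        means.append(contrast_ratio(out, truth.mask("left", "n1"), truth.reference_mask))
    assert means[0] > means[1] > means[2]


def test_misalignment_within_caps(canonical, rng):
    vol, truth = canonical
    cfg = PhantomConfig(misalign_rot_deg_sd=4.0, misalign_trans_mm_sd=2.0,
                        noise_sd=0.0, intensity_scale_sd=0.0)
    rec = SubjectRecord("hc_x", "HC", 0, 0)
    for _ in range(5):
        _, sub = simulate_subject(vol, truth, rec, cfg, rng)
        assert np.all(np.abs(sub.transform.rotation_deg) <= 6.0)
        assert np.all(np.abs(sub.transform.translation_mm) <= 3.0)


def test_rician_noise_runs_and_nonnegative(canonical, rng):
    vol, truth = canonical
    cfg = PhantomConfig(noise_model="rician", misalign_rot_deg_sd=0.0,
                        misalign_trans_mm_sd=0.0)
    rec = SubjectRecord("hc_x", "HC", 0, 0)
    out, _ = simulate_subject(vol, truth, rec, cfg, rng)
    assert (out.data >= 0).all()


# --------------------------------------------------------------------------- #
# Cohort-level properties
# --------------------------------------------------------------------------- #


def test_group_mean_cr_ordering_all_regions(small_cohort):
    """IPD group-mean CR below HC in every region (disease direction)."""
    cohort = small_cohort
    truth = cohort.truth
    for side in SIDES:
        for region in ("n1", "n2", "whole_sn"):
            crs = {"IPD": [], "HC": []}
            for _, rec in cohort.records.iterrows():
                vol = cohort.volumes[rec["subject_id"]]
                crs[rec["group"]].append(
                    contrast_ratio(vol, truth.mask(side, region), truth.reference_mask)
                )
            assert np.mean(crs["IPD"]) < np.mean(crs["HC"])


def test_cohort_determinism():
    cfg = PhantomConfig(n_per_group=2, seed=42)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    pd.testing.assert_frame_equal(a.records, b.records)
    for sid in a.volumes:
        np.testing.assert_array_equal(a.volumes[sid].data, b.volumes[sid].data)


def test_truth_logs_every_subject(small_cohort):
    assert set(small_cohort.truth.subjects) == set(small_cohort.records["subject_id"])


# --------------------------------------------------------------------------- #
# write_cohort
# --------------------------------------------------------------------------- #


def test_write_cohort_layout(tmp_path):
    cfg = PhantomConfig(n_per_group=3, seed=3)
    paths = write_cohort(cfg, tmp_path / "cohort")
    records = pd.read_csv(paths["cohort_csv"])
    assert len(records) == 6
    assert sorted(records["group"].unique()) == ["HC", "IPD"]
    images = list((tmp_path / "cohort" / "images").glob("*.nii"))
    assert len(images) == 6
    with open(paths["ground_truth_json"]) as fh:
        gt = json.load(fh)
    assert len(gt["subjects"]) == 6


def test_write_cohort_rerun_identical_bytes(tmp_path):
    cfg = PhantomConfig(n_per_group=2, seed=5)
    p1 = write_cohort(cfg, tmp_path / "a")
    p2 = write_cohort(cfg, tmp_path / "b")
    for key in ("cohort_csv", "ground_truth_json"):
        assert p1[key].read_bytes() == p2[key].read_bytes()


# --------------------------------------------------------------------------- #
# Config validation
# --------------------------------------------------------------------------- #


@pytest.mark.parametrize(
    "kw",
    [
        dict(n_per_group=1),
        dict(n1_deficit_mean=1.5),
        dict(n1_deficit_mean=-0.1),
        dict(noise_sd=-1.0),
        dict(noise_model="poisson"),
        dict(voxel_size_mm=0.0),
    ],
)
def test_config_validation_errors(kw):
    with pytest.raises(PhantomConfigError):
        PhantomConfig(**kw).validate()


def test_config_rejects_unknown_keys_and_bad_seed():
    with pytest.raises(PhantomConfigError):
        PhantomConfig.from_dict({"not_a_key": 1})
    with pytest.raises(PhantomConfigError):
        PhantomConfig.from_dict({"seed": "tomorrow"})


def test_config_round_trip():
    cfg = PhantomConfig(n_per_group=4, seed=9, noise_model="rician")
    assert PhantomConfig.from_dict(cfg.to_dict()) == cfg
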