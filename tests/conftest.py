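"""Shared fixtures: canonical anatomy and small deterministic cohorts.

Everything here is seeded; expensive fixtures are session-scoped so the suite
builds each phantom at most once.
"""

from __future__ import annotations

import numpy as np
import pytest

from nigramap.phantom import (
    PhantomConfig,
    generate_cohort,
    make_canonical_anatomy,
)

#: generator settings that switch off every stochastic ingredient; tests add
#: back exactly the ones they exercise
NOISE_FREE = dict(
    deficit_sd=0.0,
    regional_variability_sd=0.0,
    noise_sd=0.0,
    misalign_rot_deg_sd=0.0,
    misalign_trans_mm_sd=0.0,
    intensity_scale_sd=0.0,
)

NO_DEFICITS = dict(
    n1_deficit_mean=0.0,
    n2_deficit_mean=0.0,
    sn_deficit_mean=0.0,
    asymmetry_boost=0.0,
)


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def canonical(default_config):
    """(Volume, GroundTruth) for the default grid; read-only."""
    return make_canonical_anatomy(default_config)


@pytest.fixture(scope="session")
def small_cohort():
    """6/6 cohort at default grid without misalignment (fast, deterministic)."""
    cfg = PhantomConfig(
        n_per_group=6, misalign_rot_deg_sd=0.0, misalign_trans_mm_sd=0.0, seed=7
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
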