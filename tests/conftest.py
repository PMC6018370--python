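"""Shared fixtures: phantoms, atlases and small cohorts built at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from octdr import (
    PhantomConfig,
    build_shape_atlas,
    descriptors_from_cohort,
    generate_bscan,
)
from octdr.synthetic import generate_cohort


@pytest.fixture(autouse=True)
def _quiet_zero_thickness_warnings():
    """Boundary repairs near the foveal pit warn; tests assert explicitly."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*zero-thickness.*")
        warnings.filterwarnings("ignore", message=".*empty in both maps.*")
        yield


@pytest.fixture(scope="session")
def noiseless_phantom():
    cfg = PhantomConfig(noise_sd=0.0, seed=7)
    scan, truth = generate_bscan(cfg)
    return cfg, scan, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    cfg = PhantomConfig(noise_sd=0.05, seed=11)
    scan, truth = generate_bscan(cfg)
    return cfg, scan, truth


@pytest.fixture(scope="session")
def normal_atlas():
    """Shape atlas built from 12 normal eyes (6 subjects)."""
    records, _ = generate_cohort(6, (1.0, 0.0, 0.0), PhantomConfig(), seed=99)
    return build_shape_atlas([r.truth.layer_map for r in records])


@pytest.fixture(scope="session")
def small_cohort():
    """16-subject cohort with ground-truth descriptors (classifier input)."""
    records, manifest = generate_cohort(16, (0.5, 0.25, 0.25),
                                        PhantomConfig(), seed=1)
    descriptors = descriptors_from_cohort(records)
    return records, manifest, descriptors


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
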