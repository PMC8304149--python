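"""Shared fixtures: one small synthetic cohort and one quality model per session."""

from __future__ import annotations

import numpy as np
import pytest

from octriage import pipeline
from octriage.config import RunConfig
from octriage.synth import TissueModel, default_profiles, generate_bscan


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def niqe_model(cfg):
    """Quality model fitted on the default pristine corpus."""
    return pipeline.fit_quality_model(cfg, seed=42)


@pytest.fixture(scope="session")
def small_records(cfg):
    """In-memory cohort: 6 sites per class, 2-3 frames per site."""
    return pipeline.simulate_records(6, (2, 3), seed=5, config=cfg)


@pytest.fixture(scope="session")
def small_split(cfg, small_records):
    """The small cohort after mirror-pair segmentation (no quality gate)."""
    template = pipeline.default_template(cfg, seed=0)
    split, _rejects = pipeline.split_records(
        small_records,
        template,
        cfg.preprocess.ncc_accept_threshold,
        cfg.preprocess.smoothing_sigma,
    )
    return split


@pytest.fixture(scope="session")
def small_features(cfg, small_split):
    return pipeline.feature_table(
        small_split, "default", include_mirror=True,
        smoothing_sigma=cfg.preprocess.smoothing_sigma,
    )


@pytest.fixture()
def single_layer_model() -> TissueModel:
    """Homogeneous decay below the surface, no membrane, no keratin."""
    return TissueModel(
        epithelial_thickness_um=3000.0,
        basement_membrane_contrast=0.0,
        epithelium_attenuation_per_um=0.0136,
        stroma_attenuation_per_um=0.0136,
        speckle_shape=1e9,
    )


@pytest.fixture(scope="session")
def example_scan():
    model = default_profiles()["normal"].sample_tissue_model(
        "buccal", np.random.default_rng(3)
    )
    return generate_bscan(model, seed=11)
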