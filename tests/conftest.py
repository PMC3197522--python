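import logging

import numpy as np
import pytest

from rsntopo.pipeline import PipelineConfig, run_pipeline
from rsntopo.simulate import (GeneratorConfig, NetworkSpec, generate_atlas,
                              generate_cohort)

logging.getLogger("rsntopo").setLevel(logging.ERROR)


def tiny_networks(n_voxels=60, n_communities=3, within=0.5, between=0.2,
                  low=0.7):
    """Six small networks (3 cognitive / 3 perceptual) for unit tests."""
    specs = []
    for i, (name, group) in enumerate([
            ("CEN", "cognitive"), ("DAN", "cognitive"), ("DMN", "cognitive"),
            ("SMN", "perceptual"), ("AN", "perceptual"), ("VN", "perceptual")]):
        specs.append(NetworkSpec(
            name=name, group=group, n_voxels=n_voxels,
            n_communities=n_communities, within_community_r=within,
            between_community_r=between, low_freq_fraction=low))
    return specs


def tiny_config(seed=0, n_subjects=2, **net_kw):
    return GeneratorConfig(
        n_subjects=n_subjects, networks=tiny_networks(**net_kw),
        grid_shape=(18, 18, 10), seed=seed)


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = tiny_config(seed=11)
    atlas = generate_atlas(cfg)
    return cfg, atlas, generate_cohort(cfg, atlas)


def null_cohort_config(seed):
    """Six identically parameterised networks: no true group difference."""
    specs = [
        NetworkSpec(name=name, group=group, n_voxels=100, n_communities=3,
                    within_community_r=0.44, between_community_r=0.30,
                    low_freq_fraction=0.65)
        for name, group in [("CEN", "cognitive"), ("DAN", "cognitive"),
                            ("DMN", "cognitive"), ("SMN", "perceptual"),
                            ("AN", "perceptual"), ("VN", "perceptual")]
    ]
    gen = GeneratorConfig(n_subjects=8, networks=specs,
                          grid_shape=(20, 20, 10), seed=seed)
    return PipelineConfig(generator=gen, n_null=6, equalize=False, seed=seed)


@pytest.fixture(scope="session")
def default_bundle():
    """The full default-condition analysis: 12 subjects, six networks,
    18-threshold sweep, 30-member null ensembles, node equalization."""
    cfg = PipelineConfig(seed=1)
    cfg.generator.seed = 1
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
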