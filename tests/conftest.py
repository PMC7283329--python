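import numpy as np
import pytest

from grainspec.synthetic import (
    SimConfig,
    render_scene,
    simulate_genotypes,
    simulate_traits,
)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-top study: 24 samples, 400 SNPs, 4 grains per sample."""
    return SimConfig(n_samples=24, n_snps=400, grains_per_sample=4, seed=7)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    geno, truth = simulate_genotypes(small_cfg)
    traits = simulate_traits(geno, truth, small_cfg)
    return small_cfg, geno, truth, traits


@pytest.fixture(scope="session")
def small_scene(small_study):
    cfg, geno, truth, traits = small_study
    return render_scene(traits, cfg)


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimConfig(
        n_samples=12,
        n_snps=200,
        grains_per_sample=4,
        noise_sd=0.0,
        chalk_noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_cfg):
    cfg = noiseless_cfg
    geno, truth = simulate_genotypes(cfg)
    traits = simulate_traits(geno, truth, cfg)
    return cfg, traits, render_scene(traits, cfg)
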