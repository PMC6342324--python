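import numpy as np
import pandas as pd
import pytest

import allelesim as al


@pytest.fixture(scope="session")
def coin_flip_counts():
    """A medium binomial-model population (p=0.6, Poisson-3 totals)."""
    cfg = al.GeneratorConfig(n_cells=1000, p_bl6=0.6, lam=3.0, rng_seed=11)
    return al.gen_coin_flip_population(cfg)


@pytest.fixture(scope="session")
def all_or_none_counts():
    """A medium monoallelic population with 2% false-detection noise."""
    cfg = al.GeneratorConfig(
        n_cells=1000, p_bl6=0.5, lam=3.0, fdr_bl6=0.02, fdr_jf1=0.02, rng_seed=12
    )
    return al.gen_all_or_none_population(cfg)


@pytest.fixture(scope="session")
def spot_field():
    """Synthetic three-channel spot field with known shift and truth."""
    spec = al.SpotFieldSpec(
        n_guide=2000,
        chromatic_shift=(0.4, -0.3),
        localization_jitter_sd=0.15,
        coloc_prob_bl6=0.3,
        coloc_prob_jf1=0.3,
        spurious_density=1e-4,
        rng_seed=21,
    )
    guide, bl6, jf1, truth = al.gen_spot_field(spec)
    return spec, guide, bl6, jf1, truth


@pytest.fixture(scope="session")
def foci_scene():
    """Guide + SNV channel images of 50 well-separated foci with truth."""
    img, truth = al.gen_foci_image(n_foci=50, extent=(512, 512), rng_seed=31)
    bl6, jf1 = al.render_foci_channels(truth, extent=(512, 512), rng_seed=32)
    return img, bl6, jf1, truth
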