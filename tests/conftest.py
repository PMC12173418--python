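import numpy as np
import pytest

import pathomix as px


@pytest.fixture(scope="session")
def small_cohort():
    """A small classification cohort shared by read-only tests."""
    cfg = px.SyntheticConfig(n_patients=24, n_patches=24, feat_dim=12,
                             n_regions=3, n_pathways=4, genes_per_pathway=5,
                             effect_size=3.0, seed=7)
    return px.generate_cohort(cfg)


@pytest.fixture(scope="session")
def prepared_small(small_cohort):
    kp = px.KernelParams(delta_c=0.5, delta_h=0.5)
    return px.prepare_cohort(
        small_cohort.patch_bags, small_cohort.omics, small_cohort.gene_sets,
        kp, k_regions=3, seed=0, labels=small_cohort.labels, auto_bandwidth=True,
    )


@pytest.fixture(scope="session")
def tiny_model(prepared_small):
    """An untrained model over the small cohort (forward-pass tests)."""
    return px.MultimodalNetwork(
        prepared_small, task="classification", n_classes=2,
        config=px.ModelConfig(zdim=6, vae_hidden=(12, 8), gate_hidden=6,
                              mfb_rank=2, batch_norm=False),
        seed=0,
    )


def rng(seed=0):
    return np.random.default_rng(seed)
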