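import numpy as np
import pytest

from deca import (
    ModelConfig,
    build_patches,
    generate_reference,
    make_pseudobulk,
    simulate_proportions,
)
from deca.model import DecaModel


@pytest.fixture(scope="session")
def small_atlas():
    """3 cell types, 60 peaks on 2 chromosomes, well-separated markers."""
    return generate_reference(
        n_celltypes=3, n_peaks=60, cells_per_type=30, n_chroms=2,
        marker_fraction=0.3, marker_fold=10.0, base_rate=0.2, seed=7,
    )


@pytest.fixture(scope="session")
def small_layout(small_atlas):
    return build_patches(small_atlas.peaks, patch_size=12)


@pytest.fixture
def tiny_model(small_atlas, small_layout):
    """Small but full architecture: 5 patches + class token, 2 layers."""
    cfg = ModelConfig(k=3, n_peaks=60, patch_size=12, d=16, L=2, h=2,
                      decoder_dims=[8, 8, 8, 8], seed=3)
    return DecaModel(cfg, small_layout)


@pytest.fixture(scope="session")
def small_batch(small_atlas):
    props = []
    for i, regime in enumerate(["random", "rare", "dominant", "average"]):
        props += simulate_proportions(3, 10, regime, seed=100 + i)
    return make_pseudobulk(small_atlas, props, n_cells_per_sample=100, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
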