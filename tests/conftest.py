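import numpy as np
import pytest

from lsphen.preprocess import TRAITS
from lsphen.synthetic_data import SyntheticFieldConfig, render_plot_scene, simulate_field


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticFieldConfig:
    """Tiny field: 10 accessions x 2 treatments x 2 reps, 64x64 imagery."""
    return SyntheticFieldConfig(
        n_accessions=10,
        n_snps=200,
        n_qtl=20,
        image_height=64,
        image_width=64,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_field(small_cfg):
    return simulate_field(small_cfg)


@pytest.fixture(scope="session")
def scenes(small_field):
    """First 10 rendered scenes of the small field."""
    out = []
    for scene in small_field.render_all():
        out.append(scene)
        if len(out) == 10:
            break
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def mid_traits():
    """Mid-range trait vector (DW, SL, NN, NB, PH) for renderer tests."""
    return dict(zip(TRAITS, (60.0, 60.0, 15.0, 6.0, 70.0)))
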