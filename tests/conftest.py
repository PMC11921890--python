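import numpy as np
import pytest

from dbytk.cube import DEFAULT_WAVELENGTHS, SpectralCube
from dbytk.synth import SceneConfig, make_spectra_bank, render_scene


@pytest.fixture(scope="session")
def bank():
    return make_spectra_bank(0)


@pytest.fixture(scope="session")
def small_scene(bank):
    """One deterministic 64x64 spectral scene with one NTRM per class."""
    cfg = SceneConfig(height=64, width=64, n_leaves=5,
                      n_ntrms_per_class=(1, 1, 1), occlusion_prob=0.0,
                      size_range=(0.12, 0.2), seed=11)
    return render_scene(cfg, bank)


@pytest.fixture()
def random_cube():
    rng = np.random.default_rng(3)
    data = rng.random((8, 9, 101), dtype=np.float32)
    return SpectralCube(data, DEFAULT_WAVELENGTHS.copy())
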