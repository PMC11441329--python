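import numpy as np
import pytest

from synquant import synthdata as sd


@pytest.fixture(scope="session")
def small_optics():
    """A 384×384 px field at the synapse-imaging pixel size (14.194 nm)."""
    return sd.OpticsSpec(field_px=(384, 384))


@pytest.fixture(scope="session")
def single_synapse_stack(small_optics):
    """One noiseless targeted side-view synapse (offset −50 nm)."""
    scene = sd.build_scene(
        small_optics, 1, fixed_offsets_nm=[-50.0], amplitude_regime="targeted",
        seed=42, margin_nm=2000.0,
    )
    return scene, sd.render_stack(scene, noise="none")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
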