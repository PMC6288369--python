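import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from filamech import synthetic
from filamech.synthetic import FlexParams


@pytest.fixture(scope="session")
def template():
    return synthetic.build_template_monomer(seed=0)


@pytest.fixture(scope="session")
def ideal_frame(template):
    return synthetic.build_ideal_filament(template)


@pytest.fixture(scope="session")
def jittered_ensemble(template):
    """Small nearly-straight ensemble with thermal jitter (60 frames)."""
    flex = FlexParams(persistence_length=10.0, n_frames=60,
                      residue_jitter_sd=0.5, seed=11)
    return synthetic.sample_flexible_ensemble(template, None, flex)


def random_rigid_motion(rng):
    """A uniformly random rotation and a translation up to 100 A."""
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.uniform(-100, 100, size=3)
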