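import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fvfold.features import one_hot_encode, relative_position_encoding
from fvfold.fixtures import FixtureSpec, make_mini_fv
from fvfold.geometry.rigid import Rigid
from fvfold.network import ModelConfig, init_params


def random_rigid(rng) -> Rigid:
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return Rigid(rot.as_matrix(), rng.normal(0, 5, size=3))


@pytest.fixture(scope="session")
def mini_fv():
    return make_mini_fv(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def tiny_model():
    """A small structure module with seeded random (nonzero-update) weights."""
    cfg = ModelConfig(
        num_blocks=2, node_width=32, heads=2,
        scalar_qk=8, scalar_v=8, point_qk=4, point_v=4, weight_init_seed=2,
    )
    params = init_params(cfg)
    rng = np.random.default_rng(3)
    for b in range(cfg.num_blocks):  # nonzero backbone updates
        w = params[f"block{b}.bb_update.w"]
        w.data = rng.normal(0, 0.2, size=w.data.shape)
    return cfg, params


@pytest.fixture(scope="session")
def mini_inputs(mini_fv):
    pair = mini_fv.sequence_pair
    return pair, one_hot_encode(pair), relative_position_encoding(pair, clip=32)
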