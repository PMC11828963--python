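import numpy as np
import pytest

from cryoice import autodiff as ad
from cryoice.meta import MetaConfig
from cryoice.model import BackboneConfig, ModelParameters, build_model
from cryoice.synthetic import (ConfigPrior, IcePhaseParams,
                               SyntheticDatasetConfig, Task, make_task)


@pytest.fixture(scope="session")
def tiny_backbone() -> BackboneConfig:
    return BackboneConfig(family="residual", stage_channels=(4, 8, 16),
                          blocks_per_stage=(1, 1, 1), fpn_channels=4)


@pytest.fixture(scope="session")
def tiny_theta(tiny_backbone):
    return build_model(tiny_backbone, init_seed=0)


@pytest.fixture(scope="session")
def hex_dataset_cfg() -> SyntheticDatasetConfig:
    return SyntheticDatasetConfig(
        dataset_id="fixture-hex", image_size=(32, 32),
        phases=[IcePhaseParams(phase="hexagonal", carrier_freq=0.3,
                               contrast=1.5, patch_scale_px=6.0)],
        ice_fraction_target=0.08, artifact_rate=0.3, seed=11)


@pytest.fixture(scope="session")
def small_task(hex_dataset_cfg) -> Task:
    return make_task(hex_dataset_cfg, k_support=2, n_query=2, seed=5)


# ---------------------------------------------------------------------------
# toy quadratic task family: loss_τ(w) = Σ_i (w_i − t_τ,i)², t stored as the
# single "pair" of each support/query set. Small enough for exact analysis.
# ---------------------------------------------------------------------------

def quad_loss(mp: ModelParameters, pairs):
    target = ad.Tensor(np.asarray(pairs[0], dtype=np.float64))
    diff = mp.params["w"] - target
    return ad.tsum(diff * diff)


def make_quad_theta(w0) -> ModelParameters:
    return ModelParameters(
        {"w": ad.Tensor(np.asarray(w0, dtype=np.float64), requires_grad=True)},
        config=None)


def make_quad_task(support_target, query_target) -> Task:
    return Task(support=[np.asarray(support_target, dtype=np.float64)],
                query=[np.asarray(query_target, dtype=np.float64)],
                dataset_id="toy")


@pytest.fixture
def quad_cfg():
    return MetaConfig(inner_lr=0.1, inner_steps=1, outer_lr=0.1,
                      second_order=True, loss="bce")
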