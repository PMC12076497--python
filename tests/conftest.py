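import numpy as np
import pytest

from fewshotmol import _autodiff as ad
from fewshotmol.chem_io import Featurizer
from fewshotmol.model import ContextSet, FewShotModel, ModelConfig, init_params
from fewshotmol.pipeline import fit_featurizer, split_taskdbs
from fewshotmol.synthdata import SynthConfig, generate_database


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small synthetic corpus shared across the unit tests."""
    cfg = SynthConfig(
        n_train_tasks=12,
        n_val_tasks=4,
        n_test_tasks=4,
        molecules_per_task=(40, 70),
        train_pool_size=600,
        seed=7,
    )
    records, manifest = generate_database(cfg)
    return cfg, records, manifest


@pytest.fixture(scope="session")
def tiny_featurizer(tiny_corpus):
    _, records, manifest = tiny_corpus
    return fit_featurizer(records, manifest)


@pytest.fixture(scope="session")
def tiny_taskdbs(tiny_corpus):
    _, records, manifest = tiny_corpus
    return split_taskdbs(records, manifest)


@pytest.fixture(scope="session")
def toy_model():
    """Untrained but fixed model on 20-dim features, with a random context."""
    cfg = ModelConfig(feature_dim=20, embed_dim=16, seed=3)
    rng = np.random.default_rng(3)
    context = ContextSet(rng.normal(size=(32, 16)))
    return FewShotModel(cfg, init_params(cfg), context)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def numeric_grad(fn, tensor, indices, eps=1e-6):
    """Central-difference gradient of scalar fn() wrt tensor[indices]."""
    tensor.value[indices] += eps
    up = fn().value
    tensor.value[indices] -= 2 * eps
    down = fn().value
    tensor.value[indices] += eps
    return (up - down) / (2 * eps)
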