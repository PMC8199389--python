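import dataclasses

import numpy as np
import pytest

from emocomp import datagen, odcnn


@pytest.fixture(scope="session")
def base_records():
    """A seeded default-size base dataset shared by read-only tests."""
    return datagen.generate_dataset(datagen.GeneratorConfig(seed=1234))


@pytest.fixture(scope="session")
def small_records():
    """A small (n=240) dataset for fast pipeline-level tests."""
    return datagen.generate_dataset(datagen.GeneratorConfig(n_base=240, seed=99))


@pytest.fixture()
def tiny_cnn_config():
    """A geometrically small network that trains in well under a second."""
    return odcnn.ODCNNConfig(depth=2, kernel_size=3, filters_per_layer=4,
                             mlp_hidden=(8,), epochs=20, batch_size=16,
                             learning_rate=0.005, seed=0)


@pytest.fixture()
def separable_toy():
    """Four linearly separable Gaussian blobs in 13 dimensions."""
    rng = np.random.default_rng(7)
    X, y = [], []
    for c in range(4):
        center = np.zeros(13)
        center[c] = 4.0
        X.append(center + 0.1 * rng.standard_normal((40, 13)))
        y.append(np.full(40, c))
    return np.vstack(X), np.concatenate(y)


def replace_cfg(cfg, **kw):
    return dataclasses.replace(cfg, **kw)


def make_rank_consistent_profiles(n_orgs=40, seed=0):
    """Organizations whose emotion mix matches their rank-implied category."""
    from emocomp import som
    from emocomp.datagen import EMOTIONS

    rng = np.random.default_rng(seed)
    dominant_by_cat = {"high": ("happy", "excited"), "moderate": ("neutral",),
                       "low": ("angry",)}
    profiles = []
    for _ in range(n_orgs):
        rank = int(rng.integers(1, 11))
        cat = som.rank_to_category(rank)
        dom = rng.choice(dominant_by_cat[cat])
        frac = rng.dirichlet(np.ones(4)) * 0.25
        frac[EMOTIONS.index(dom)] += 0.75
        frac /= frac.sum()
        profiles.append(som.OrgProfile(org_rank=rank, n_employees=50,
                                       emotion_fractions=frac))
    return profiles
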