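import time

import numpy as np
import pytest

from celltypetree import build_hierarchy, generate, preset_scenarios


@pytest.fixture(scope="session")
def ladder():
    """The coarse/mid/fine resolution-ladder scenario at seed 0."""
    config = preset_scenarios(seed=0)["pbmc-like ladder"]
    embeddings, truth = generate(config)
    return {"config": config, "embeddings": embeddings, "truth": truth}


@pytest.fixture(scope="session")
def ladder_builder(ladder):
    """Hierarchy built from the three ladder reference datasets."""
    t0 = time.time()
    builder = build_hierarchy(ladder["embeddings"][:3])
    builder.fit_seconds_ = time.time() - t0
    return builder


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_blobs(rng, means, n_per, d=None):
    """Unit-sigma Gaussian blobs at the given means; returns (X, labels)."""
    means = {k: np.asarray(v, dtype=float) for k, v in means.items()}
    X, y = [], []
    for name, mu in means.items():
        X.append(mu + rng.standard_normal((n_per, mu.shape[0])))
        y.extend([name] * n_per)
    return np.vstack(X), np.array(y, dtype=object)
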