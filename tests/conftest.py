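import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cellpresence as cp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


# A reduced-scale study: 4 types x 15 markers over a 260-gene space with
# 120 cells per type trains in about a second yet keeps the planted
# structure of the full-size generator defaults.
SMALL = dict(
    n_types=4,
    markers_per_type=15,
    n_background_genes=200,
    cells_per_type=120,
    seed=42,
)


@pytest.fixture(scope="session")
def small_cfg():
    return cp.SyntheticConfig(**SMALL)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    """(BinaryProfileMatrix, labels, marker_map) at reduced scale."""
    return cp.generate_labeled_dataset(small_cfg)


@pytest.fixture(scope="session")
def small_catalog(small_cfg):
    return small_cfg.catalog()


@pytest.fixture(scope="session")
def trained_model(small_data, small_catalog, small_cfg):
    """A classifier trained (with synthetic unknowns) on the small dataset.

    Session-scoped: tests that mutate it must deepcopy first.
    Returns (model, training matrix, training labels).
    """
    matrix, labels, _ = small_data
    unk = cp.synthesize_unknown(matrix, 120, seed=43)
    train_m = matrix.concat(unk)
    train_l = list(labels) + ["Unknown"] * 120
    cw = cp.compute_class_weights(train_l, small_catalog)
    model = cp.init_model(
        cp.NetworkConfig(input_size=matrix.gene_space.size),
        small_catalog,
        matrix.gene_space,
        seed=42,
    )
    # batch size scaled down with the dataset (1024 would be a single
    # mini-batch per epoch at 720 cells)
    model, _ = cp.train(
        model, train_m, train_l,
        cp.TrainConfig(seed=42, max_epochs=20, batch_size=128), cw,
    )
    return model, train_m, train_l


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
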