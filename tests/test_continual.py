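"""Online updates with review training, and catalog expansion."""

import copy

import numpy as np
import pytest

import cellpresence as cp
from cellpresence.continual import _bump_version, _make_replay_hook
from cellpresence.io import DataError


@pytest.fixture()
def model_and_data(trained_model):
    model, train_m, train_l = trained_model
    return copy.deepcopy(model), train_m, train_l


class TestOnlineUpdate:
    def test_zero_epochs_leaves_weights_unchanged(self, model_and_data):
        model, train_m, train_l = model_and_data
        before = model.copy_weights()
        model, hist = cp.online_update(
            model, train_m, train_l, cp.TrainConfig(seed=0, max_epochs=0),
            cp.ReviewPolicy(review_size=0),
        )
        assert hist.n_epochs == 0
        for (W1, b1), (W2, b2) in zip(before, model.weights):
            assert np.array_equal(W1, W2) and np.array_equal(b1, b2)

    def test_label_outside_catalog_directs_to_expand(self, model_and_data):
        model, train_m, train_l = model_and_data
        bad = ["Novel"] * train_m.n_cells
        with pytest.raises(DataError, match="expand_catalog"):
            cp.online_update(model, train_m, bad, cp.TrainConfig(max_epochs=1))

    def test_empty_new_data_rejected(self, model_and_data):
        model, train_m, _ = model_and_data
        empty = train_m.subset(np.array([], dtype=int))
        with pytest.raises(DataError, match="empty"):
            cp.online_update(model, empty, [], cp.TrainConfig(max_epochs=1))

    def test_missing_replay_pool_warns_and_skips_review(self, model_and_data):
        model, train_m, train_l = model_and_data
        with pytest.warns(UserWarning, match="review training skipped"):
            cp.online_update(
                model, train_m, train_l, cp.TrainConfig(seed=0, max_epochs=1),
                cp.ReviewPolicy(review_size=100), replay_pool=None,
            )

    def test_update_is_reproducible(self, trained_model):
        model, train_m, train_l = trained_model
        results = []
        for _ in range(2):
            m = copy.deepcopy(model)
            m, _ = cp.online_update(
                m, train_m, train_l, cp.TrainConfig(seed=4, max_epochs=3),
                cp.ReviewPolicy(review_size=100, seed=4),
                replay_pool=(train_m, train_l),
            )
            results.append(m)
        for (W1, _), (W2, _) in zip(results[0].weights, results[1].weights):
            assert np.array_equal(W1, W2)


class TestReplaySampling:
    def test_per_epoch_sample_is_without_replacement_and_sized(self, trained_model):
        model, train_m, train_l = trained_model
        # give every pool cell a distinct binary pattern so replayed rows
        # can be mapped back to pool indices
        n = 64
        gs = train_m.gene_space
        values = np.zeros((n, gs.size), dtype=np.uint8)
        for i in range(n):
            values[i, :7] = [int(x) for x in f"{i:07b}"]
        pool = cp.BinaryProfileMatrix(
            gene_space=gs, cells=[f"p{i}" for i in range(n)], values=values
        )
        pool_labels = [model.catalog.classes[0]] * n
        policy = cp.ReviewPolicy(review_size=40, seed=3)
        hook = _make_replay_hook(
            model, pool, pool_labels, policy, cp.TrainConfig(batch_size=16), None
        )
        seen = []
        hook(0, lambda X, y, w: seen.extend(
            int("".join(str(int(v)) for v in row[:7]), 2) for row in X
        ))
        assert len(seen) == 40
        assert len(set(seen)) == 40  # no cell replayed twice within the epoch

    def test_oversized_review_warns_and_uses_whole_pool(self, trained_model):
        model, train_m, train_l = trained_model
        policy = cp.ReviewPolicy(review_size=10 * train_m.n_cells, seed=0)
        with pytest.warns(UserWarning, match="whole pool"):
            _make_replay_hook(
                model, train_m, train_l, policy, cp.TrainConfig(), None
            )


class TestExpandCatalog:
    def test_output_widened_and_old_columns_copied(self, model_and_data):
        model, train_m, train_l = model_and_data
        old_classes = model.catalog.classes
        W_old, b_old = (a.copy() for a in model.weights[-1])
        labels = list(train_l)
        # relabel the Unknown training cells as a new type so it has examples
        labels = ["NovelT" if l == "Unknown" else l for l in labels]
        model, _ = cp.expand_catalog(
            model, ["NovelT"], train_m, labels,
            cp.TrainConfig(seed=0, max_epochs=0),  # widen only, no training
            cp.ReviewPolicy(review_size=0),
        )
        assert model.catalog.classes == old_classes[:-1] + ["NovelT", "Unknown"]
        W_new, b_new = model.weights[-1]
        assert W_new.shape[1] == len(old_classes) + 1
        new_idx = model.catalog.class_index()
        for name, i_old in zip(old_classes, range(len(old_classes))):
            assert np.array_equal(W_new[:, new_idx[name]], W_old[:, i_old])
            assert b_new[new_idx[name]] == b_old[i_old]

    def test_first_hidden_layer_frozen_bit_exact(self, model_and_data):
        model, train_m, train_l = model_and_data
        W0, b0 = (a.copy() for a in model.weights[0])
        W1_before = model.weights[1][0].copy()
        labels = ["NovelT" if l == "Unknown" else l for l in train_l]
        model, _ = cp.expand_catalog(
            model, ["NovelT"], train_m, labels,
            cp.TrainConfig(seed=0, max_epochs=5),
            cp.ReviewPolicy(review_size=0),
        )
        assert np.array_equal(model.weights[0][0], W0)
        assert np.array_equal(model.weights[0][1], b0)
        # deeper layers did train
        assert not np.array_equal(model.weights[1][0], W1_before)

    def test_zero_new_types_behaves_as_online_update(self, model_and_data):
        model, train_m, train_l = model_and_data
        width_before = model.weights[-1][0].shape[1]
        model, _ = cp.expand_catalog(
            model, [], train_m, train_l,
            cp.TrainConfig(seed=0, max_epochs=1), cp.ReviewPolicy(review_size=0),
        )
        assert model.weights[-1][0].shape[1] == width_before

    def test_duplicate_or_existing_type_rejected(self, model_and_data):
        model, train_m, train_l = model_and_data
        with pytest.raises(DataError, match="duplicate"):
            cp.expand_catalog(
                model, ["X", "X"], train_m, train_l, cp.TrainConfig(max_epochs=1)
            )
        existing = model.catalog.known_types[0]
        with pytest.raises(DataError):
            cp.expand_catalog(
                model, [existing], train_m,
                [existing] * train_m.n_cells, cp.TrainConfig(max_epochs=1),
            )

    def test_new_type_without_examples_rejected(self, model_and_data):
        model, train_m, train_l = model_and_data
        with pytest.raises(DataError, match="no training examples"):
            cp.expand_catalog(
                model, ["Ghost"], train_m, train_l, cp.TrainConfig(max_epochs=1)
            )

    def test_version_bumped(self, model_and_data):
        model, train_m, train_l = model_and_data
        labels = ["NovelT" if l == "Unknown" else l for l in train_l]
        model, _ = cp.expand_catalog(
            model, ["NovelT"], train_m, labels,
            cp.TrainConfig(seed=0, max_epochs=1), cp.ReviewPolicy(review_size=0),
        )
        assert model.version == "v2"


@pytest.mark.parametrize(
    "tag,expected", [("v1", "v2"), ("v1m", "v2m"), ("v12h", "v13h"), ("weird", "weird+1")]
)
def test_version_bump_rule(tag, expected):
    assert _bump_version(tag) == expected
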