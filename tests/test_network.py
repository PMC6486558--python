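"""Classifier architecture, training behaviour and prediction contract."""

import numpy as np
import pytest

import cellpresence as cp
from cellpresence.io import DataError
from cellpresence.network import _evaluate, _stratified_split


def _gene_space(n):
    return cp.GeneSpace([f"g{i}" for i in range(n)])


class TestInit:
    @pytest.mark.parametrize("n_known,n_outputs", [(30, 31), (37, 38)])
    def test_output_width_is_known_types_plus_unknown(self, n_known, n_outputs):
        gs = _gene_space(50)
        cat = cp.CellTypeCatalog(known_types=[f"T{i}" for i in range(n_known)])
        model = cp.init_model(cp.NetworkConfig(input_size=50), cat, gs, seed=0)
        W_out, b_out = model.weights[-1]
        assert W_out.shape == (100, n_outputs)
        assert b_out.shape == (n_outputs,)

    def test_same_seed_gives_identical_weights(self):
        gs = _gene_space(40)
        cat = cp.CellTypeCatalog(known_types=["A", "B"])
        cfg = cp.NetworkConfig(input_size=40)
        m1 = cp.init_model(cfg, cat, gs, seed=5)
        m2 = cp.init_model(cfg, cat, gs, seed=5)
        for (W1, b1), (W2, b2) in zip(m1.weights, m2.weights):
            assert np.array_equal(W1, W2) and np.array_equal(b1, b2)

    def test_size_mismatch_rejected(self):
        with pytest.raises(DataError):
            cp.init_model(
                cp.NetworkConfig(input_size=10),
                cp.CellTypeCatalog(known_types=["A"]),
                _gene_space(11),
            )


class TestPredict:
    def test_probability_rows_sum_to_one(self, trained_model):
        model, train_m, _ = trained_model
        _, probs = cp.predict(model, train_m)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_final_layer_gives_uniform_and_first_class(self, small_cfg):
        gs = small_cfg.gene_space()
        cat = small_cfg.catalog()
        model = cp.init_model(cp.NetworkConfig(input_size=gs.size), cat, gs, seed=0)
        W, b = model.weights[-1]
        model.weights[-1] = (np.zeros_like(W), np.zeros_like(b))
        data = cp.BinaryProfileMatrix(
            gene_space=gs, cells=["z"], values=np.zeros((1, gs.size), dtype=np.uint8)
        )
        labels, probs = cp.predict(model, data)
        assert np.allclose(probs, 1.0 / cat.n_outputs)
        assert labels == [cat.classes[0]]

    def test_duplicated_cell_gets_same_label(self, trained_model):
        model, train_m, _ = trained_model
        one = train_m.subset([0])
        two = cp.BinaryProfileMatrix(
            gene_space=one.gene_space,
            cells=["a", "b"],
            values=np.vstack([one.values, one.values]),
        )
        labels, probs = cp.predict(model, two)
        assert labels[0] == labels[1]
        assert np.array_equal(probs[0], probs[1])

    def test_gene_space_mismatch_rejected(self, trained_model):
        model, _, _ = trained_model
        other = cp.BinaryProfileMatrix(
            gene_space=_gene_space(7), cells=["x"],
            values=np.zeros((1, 7), dtype=np.uint8),
        )
        with pytest.raises(DataError, match="gene space"):
            cp.predict(model, other)

    def test_prediction_is_pure(self, trained_model):
        model, train_m, _ = trained_model
        l1, p1 = cp.predict(model, train_m)
        l2, p2 = cp.predict(model, train_m)
        assert l1 == l2 and np.array_equal(p1, p2)


class TestTrain:
    def test_single_class_rejected(self, small_data, small_catalog):
        matrix, labels, _ = small_data
        model = cp.init_model(
            cp.NetworkConfig(input_size=matrix.gene_space.size),
            small_catalog, matrix.gene_space, seed=0,
        )
        with pytest.raises(DataError, match="single class"):
            cp.train(model, matrix, [labels[0]] * matrix.n_cells)

    def test_untrained_uniform_loss_is_log_n_outputs(self, small_data, small_catalog):
        matrix, labels, _ = small_data
        model = cp.init_model(
            cp.NetworkConfig(input_size=matrix.gene_space.size),
            small_catalog, matrix.gene_space, seed=0,
        )
        W, b = model.weights[-1]
        model.weights[-1] = (np.zeros_like(W), np.zeros_like(b))
        y = small_catalog.encode(labels)
        loss, _ = _evaluate(
            model.weights, matrix.values.astype(float), y, np.ones(len(y))
        )
        assert loss == pytest.approx(np.log(small_catalog.n_outputs), abs=1e-9)

    def test_separable_dataset_learned(self, trained_model, small_cfg):
        model, _, _ = trained_model
        test_m, test_l, _ = cp.generate_labeled_dataset(
            cp.SyntheticConfig(**{**small_cfg.__dict__, "seed": 1042})
        )
        pred, _ = cp.predict(model, test_m)
        assert cp.concordance(pred, test_l) >= 0.9

    def test_history_has_one_record_per_epoch(self, small_data, small_catalog):
        matrix, labels, _ = small_data
        model = cp.init_model(
            cp.NetworkConfig(input_size=matrix.gene_space.size),
            small_catalog, matrix.gene_space, seed=0,
        )
        _, hist = cp.train(
            model, matrix, labels, cp.TrainConfig(seed=0, max_epochs=4, patience=10)
        )
        assert hist.n_epochs == 4
        for rec in hist.epochs:
            assert np.isfinite(rec["train_loss"]) and np.isfinite(rec["val_loss"])

    def test_reproducible_without_dropout(self, small_data, small_catalog):
        matrix, labels, _ = small_data
        cfg = cp.NetworkConfig(input_size=matrix.gene_space.size, dropout_rate=0.0)
        runs = []
        for _ in range(2):
            m = cp.init_model(cfg, small_catalog, matrix.gene_space, seed=8)
            m, _ = cp.train(m, matrix, labels, cp.TrainConfig(seed=8, max_epochs=5))
            runs.append(m)
        for (W1, b1), (W2, b2) in zip(runs[0].weights, runs[1].weights):
            assert np.array_equal(W1, W2) and np.array_equal(b1, b2)

    def test_dropout_training_reproducible_with_same_seed(
        self, small_data, small_catalog
    ):
        matrix, labels, _ = small_data
        cfg = cp.NetworkConfig(input_size=matrix.gene_space.size)
        runs = []
        for _ in range(2):
            m = cp.init_model(cfg, small_catalog, matrix.gene_space, seed=8)
            m, _ = cp.train(m, matrix, labels, cp.TrainConfig(seed=8, max_epochs=5))
            runs.append(m)
        for (W1, _), (W2, _) in zip(runs[0].weights, runs[1].weights):
            assert np.array_equal(W1, W2)

    def test_early_stopping_restores_best_epoch(self, small_data, small_catalog):
        matrix, labels, _ = small_data
        m = cp.init_model(
            cp.NetworkConfig(input_size=matrix.gene_space.size),
            small_catalog, matrix.gene_space, seed=0,
        )
        m, hist = cp.train(
            m, matrix, labels,
            cp.TrainConfig(seed=0, max_epochs=40, patience=2, learning_rate=0.2),
        )
        # with an aggressive learning rate the run stops before max_epochs
        assert hist.n_epochs < 40

    def test_zero_epochs_is_identity(self, small_data, small_catalog):
        matrix, labels, _ = small_data
        m = cp.init_model(
            cp.NetworkConfig(input_size=matrix.gene_space.size),
            small_catalog, matrix.gene_space, seed=0,
        )
        before = m.copy_weights()
        m, hist = cp.train(m, matrix, labels, cp.TrainConfig(seed=0, max_epochs=0))
        assert hist.n_epochs == 0
        for (W1, b1), (W2, b2) in zip(before, m.weights):
            assert np.array_equal(W1, W2) and np.array_equal(b1, b2)


class TestValidationSplit:
    def test_membership_counts_invariant_to_sample_order(self, rng):
        y = np.repeat(np.arange(4), [40, 30, 20, 10])
        idx = np.arange(len(y))
        _, va1 = _stratified_split(idx, y, 0.2, seed=7)
        perm = rng.permutation(idx)
        # same split policy on a permuted view: per-class validation counts agree
        _, va2_perm = _stratified_split(np.arange(len(y)), y[perm], 0.2, seed=7)
        counts1 = np.bincount(y[va1], minlength=4)
        counts2 = np.bincount(y[perm][va2_perm], minlength=4)
        assert np.array_equal(counts1, counts2)

    def test_tiny_class_degrades_with_warning(self):
        y = np.array([0] * 20 + [1])
        with pytest.warns(UserWarning, match="unstratified"):
            tr, va = _stratified_split(np.arange(len(y)), y, 0.2, seed=0)
        assert len(tr) + len(va) == len(y)
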