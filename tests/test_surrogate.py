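"""Surrogate network: forward pass, training, prediction, serialization."""

import numpy as np
import pandas as pd
import pytest

from episurf.cellmodel import ConfigurationError
from episurf.datagen import Dataset
from episurf.surrogate import (MLPSpec, Scaler, TrainConfig, TrainedSurrogate,
                               direction_columns, load_surrogate, mlp_forward,
                               predict, save_surrogate, train_surrogate)

from conftest import make_synthetic_dataset


def _zero_surrogate(n_in=4, n_out=4, dropout=0.1):
    sizes = (n_in, 16, 16, n_out)
    weights = [np.zeros((sizes[k], sizes[k + 1])) for k in range(3)]
    biases = [np.zeros(sizes[k + 1]) for k in range(3)]
    return TrainedSurrogate(
        spec=MLPSpec(layer_sizes=sizes, dropout_rate=dropout),
        weights=weights, biases=biases,
        x_scaler=Scaler(np.zeros(n_in), np.ones(n_in)),
        y_scaler=Scaler(np.arange(1.0, n_out + 1), np.ones(n_out)),
        direction="forward",
        feature_names=tuple(f"f{i}" for i in range(n_in)),
        target_names=tuple(f"t{i}" for i in range(n_out)))


class TestForwardPass:
    def test_zero_network_returns_output_mean(self):
        surr = _zero_surrogate()
        out = mlp_forward(surr, np.random.default_rng(0).normal(size=(5, 4)))
        np.testing.assert_allclose(out, np.tile([1.0, 2.0, 3.0, 4.0], (5, 1)))

    def test_inference_is_deterministic(self, synthetic_dataset, fast_train_config):
        surr = train_surrogate(synthetic_dataset, "forward", fast_train_config)
        x = np.array([[1.0, 1.2, 0.8, 1.5]])
        a = mlp_forward(surr, x)
        b = mlp_forward(surr, x)
        np.testing.assert_array_equal(a, b)

    def test_zero_dropout_training_mode_equals_inference(self):
        surr = _zero_surrogate(dropout=0.0)
        x = np.ones((3, 4))
        np.testing.assert_array_equal(
            mlp_forward(surr, x, training_mode=True, dropout_seed=1),
            mlp_forward(surr, x))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            mlp_forward(_zero_surrogate(), np.ones((2, 3)))


class TestTraining:
    def test_loss_decreases_and_best_weights_restored(self, synthetic_dataset,
                                                      fast_train_config):
        surr = train_surrogate(synthetic_dataset, "forward", fast_train_config)
        hist = surr.history
        assert hist["test_loss"][hist["best_epoch"]] == hist["best_test_loss"]
        assert hist["best_test_loss"] < hist["test_loss"][0]

    def test_seeded_training_bitwise_reproducible(self, synthetic_dataset,
                                                  fast_train_config):
        a = train_surrogate(synthetic_dataset, "forward", fast_train_config)
        b = train_surrogate(synthetic_dataset, "forward", fast_train_config)
        for Wa, Wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(Wa, Wb)
        for ba, bb in zip(a.biases, b.biases):
            np.testing.assert_array_equal(ba, bb)

    def test_merged_datasets_train_one_surrogate(self, fast_train_config):
        d1 = make_synthetic_dataset(n=200, seed=1)
        d2 = make_synthetic_dataset(n=200, seed=2)
        surr = train_surrogate([d1, d2], "forward", fast_train_config)
        assert surr.provenance["n_samples"] == 400

    def test_refuses_tiny_dataset(self, fast_train_config):
        with pytest.raises(ConfigurationError, match="49"):
            train_surrogate(make_synthetic_dataset(n=49), "forward",
                            fast_train_config)

    def test_inverse_direction_swaps_features_and_targets(self,
                                                          synthetic_dataset,
                                                          fast_train_config):
        surr = train_surrogate(synthetic_dataset, "inverse", fast_train_config)
        assert surr.feature_names == ("Na_cell", "K_cell",
                                      "J_Na_trans", "J_K_trans")
        assert all(t.startswith("frac_") for t in surr.target_names)

    def test_output_unit_change_rescales_consistently(self, fast_train_config):
        """Training on outputs in different units then undoing the unit
        change must reproduce the original predictions."""
        ds = make_synthetic_dataset(n=300, seed=3)
        scaled = Dataset(table=ds.table.copy(), metadata=dict(ds.metadata))
        out_cols = ["Na_cell", "K_cell", "Va", "Vb"]
        scaled.table[out_cols] = scaled.table[out_cols] * 1000.0
        a = train_surrogate(ds, "forward", fast_train_config)
        b = train_surrogate(scaled, "forward", fast_train_config)
        x = ds.table.iloc[:20]
        pa = predict(a, x).to_numpy()
        pb = predict(b, x).to_numpy() / 1000.0
        np.testing.assert_allclose(pa, pb, rtol=1e-6)

    def test_row_shuffle_statistically_equivalent(self, fast_train_config):
        ds = make_synthetic_dataset(n=400, seed=5)
        shuffled = Dataset(
            table=ds.table.sample(frac=1.0, random_state=3).reset_index(drop=True),
            metadata=dict(ds.metadata))
        a = train_surrogate(ds, "forward", fast_train_config)
        b = train_surrogate(shuffled, "forward", fast_train_config)
        la, lb = a.history["best_test_loss"], b.history["best_test_loss"]
        assert 0.5 <= la / lb <= 2.0


class TestPredict:
    def test_batch_and_single_row_agree(self, synthetic_dataset,
                                        fast_train_config):
        surr = train_surrogate(synthetic_dataset, "forward", fast_train_config)
        rows = synthetic_dataset.table.iloc[:8]
        batch = predict(surr, rows).to_numpy()
        singles = np.vstack([predict(surr, rows.iloc[[i]]).to_numpy()
                             for i in range(len(rows))])
        np.testing.assert_allclose(batch, singles, rtol=1e-14)

    def test_missing_column_named(self, synthetic_dataset, fast_train_config):
        surr = train_surrogate(synthetic_dataset, "forward", fast_train_config)
        with pytest.raises(ConfigurationError, match="frac_d"):
            predict(surr, synthetic_dataset.table.drop(columns=["frac_d"]))

    def test_out_of_range_input_warns_but_predicts(self, synthetic_dataset,
                                                   fast_train_config):
        surr = train_surrogate(synthetic_dataset, "forward", fast_train_config)
        x = pd.DataFrame([{f"frac_{p}": 3.0 for p in "abcd"}])
        with pytest.warns(UserWarning, match="extrapolating"):
            out = predict(surr, x)
        assert np.all(np.isfinite(out.to_numpy()))


class TestSerialization:
    def test_save_load_prediction_parity(self, tmp_path, synthetic_dataset,
                                         fast_train_config):
        surr = train_surrogate(synthetic_dataset, "forward", fast_train_config)
        save_surrogate(surr, tmp_path / "bundle")
        back = load_surrogate(tmp_path / "bundle")
        rng = np.random.default_rng(0)
        x = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=(100, 4)))
        np.testing.assert_allclose(mlp_forward(surr, x), mlp_forward(back, x),
                                   rtol=1e-12)
        assert back.history["best_epoch"] == surr.history["best_epoch"]
        assert back.history["test_loss"] == pytest.approx(surr.history["test_loss"])

    def test_manifest_shape_mismatch_detected(self, tmp_path,
                                              synthetic_dataset,
                                              fast_train_config):
        import json
        surr = train_surrogate(synthetic_dataset, "forward", fast_train_config)
        save_surrogate(surr, tmp_path / "bundle")
        manifest = json.loads((tmp_path / "bundle" / "manifest.json").read_text())
        manifest["spec"]["layer_sizes"] = [4, 8, 8, 4]
        (tmp_path / "bundle" / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(ConfigurationError):
            load_surrogate(tmp_path / "bundle")


def test_direction_columns_contract():
    feats, targets = direction_columns("forward", ["x", "y", "z", "w"])
    assert feats == ("frac_x", "frac_y", "frac_z", "frac_w")
    assert targets == ("Na_cell", "K_cell", "Va", "Vb")
    with pytest.raises(ConfigurationError):
        direction_columns("sideways", ["x"])


def test_scaler_rejects_constant_column():
    with pytest.raises(ConfigurationError):
        Scaler.fit(np.ones((10, 2)))
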