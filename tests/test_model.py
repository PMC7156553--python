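import numpy as np
import pandas as pd
import pytest

from hicres import network
from hicres.model import (
    CheckpointError,
    HiCEnhancer,
    HiCEnhancerResults,
    TrainConfig,
    mse_loss,
)
from hicres.network import NetworkSpec

SMALL = NetworkSpec(features=8, expand=16)


def toy_data(rng, n=12, spec=SMALL):
    x = rng.random((n, spec.input_size, spec.input_size, 1))
    y = rng.random((n, spec.output_size, spec.output_size, 1))
    return x, y


class TestArchitecture:
    def test_spatial_contract_40_to_28(self):
        spec = NetworkSpec()
        assert spec.input_size == 40
        assert spec.shrink == 12
        assert spec.output_size == 28

    def test_parameter_count_closed_form(self):
        # hand-enumerated (kernel, c_in, c_out) of all 14 convolutions
        layers = [
            (7, 1, 32), (5, 32, 32),                      # feature extraction
            (1, 32, 128), (1, 128, 32), (7, 32, 32),      # first residual block
            (5, 32, 32), (3, 32, 32), (5, 32, 32), (3, 32, 32),  # crops
            (1, 32, 128), (1, 128, 32), (7, 32, 32),      # second residual block
            (7, 32, 32), (5, 32, 1),                      # prediction head
        ]
        expected = sum(k * k * ci * co + co for k, ci, co in layers)
        spec = NetworkSpec()
        assert network.param_count(spec) == expected
        params = network.init_params(spec, 0)
        total = sum(p["W"].size + p["b"].size for p in params.values())
        assert total == expected

    def test_seeded_build_is_deterministic(self):
        a = network.init_params(NetworkSpec(), seed=7)
        b = network.init_params(NetworkSpec(), seed=7)
        c = network.init_params(NetworkSpec(), seed=8)
        for name in a:
            np.testing.assert_array_equal(a[name]["W"], b[name]["W"])
        assert any((a[n]["W"] != c[n]["W"]).any() for n in a)

    def test_forward_shape_and_finiteness(self, rng):
        spec = NetworkSpec()
        params = network.init_params(spec, 1)
        out = network.forward(spec, params, rng.random((3, 40, 40, 1), dtype=np.float32))
        assert out.shape == (3, 28, 28, 1)
        assert np.isfinite(out).all()

    def test_wrong_input_side_rejected(self, rng):
        spec = NetworkSpec()
        params = network.init_params(spec, 1)
        with pytest.raises(ValueError, match="expected"):
            network.forward(spec, params, rng.random((2, 28, 28, 1)))

    def test_zero_weights_final_bias_propagates(self, rng):
        spec = SMALL
        params = network.init_params(spec, 0, dtype=np.float64)
        for p in params.values():
            p["W"][:] = 0.0
            p["b"][:] = 0.0
        params["pred2"]["b"][:] = 2.5
        out = network.forward(spec, params, rng.random((2, 40, 40, 1)))
        np.testing.assert_allclose(out, 2.5)

    def test_residual_block_with_zeroed_branch_is_identity(self, rng):
        """With the residual branch's final convolution zeroed, each block
        passes its input through unchanged."""
        spec = SMALL
        params = network.init_params(spec, 3, dtype=np.float64)
        for name in ("res1_conv", "res2_conv"):
            params[name]["W"][:] = 0.0
            params[name]["b"][:] = 0.0
        x = rng.random((2, 40, 40, 1))
        got = network.forward(spec, params, x)
        # manual chain without the residual blocks
        h = x
        for name, same, relu in [
            ("feat1", True, True), ("feat2", True, True),
            ("crop1", False, True), ("crop2", False, True),
            ("crop3", False, True), ("crop4", False, True),
            ("pred1", True, True), ("pred2", True, False),
        ]:
            h = network.conv_forward(h, params[name]["W"], params[name]["b"], same)
            if relu:
                h = np.maximum(h, 0.0)
        np.testing.assert_allclose(got, h, atol=1e-12)


class TestGradients:
    def test_gradients_match_finite_differences(self, rng):
        spec = NetworkSpec(features=4, expand=8)
        params = network.init_params(spec, 3, dtype=np.float64)
        # zero-initialized biases sit exactly on the ReLU kink for dead
        # pixels, where one-sided finite differences disagree; nudge off it
        for p in params.values():
            p["b"] = rng.normal(scale=0.05, size=p["b"].shape)
        x = rng.random((2, 40, 40, 1))
        y = rng.random((2, 28, 28, 1))
        _, grads = network.loss_and_grads(spec, params, x, y)
        eps = 1e-6
        for name in params:
            for part in ("W", "b"):
                arr = params[name][part]
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = network.loss_and_grads(spec, params, x, y)
                arr[idx] = orig - eps
                lm, _ = network.loss_and_grads(spec, params, x, y)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads[name][part][idx]
                assert an == pytest.approx(fd, rel=1e-4, abs=1e-10), f"{name}.{part}"


class TestMseLoss:
    def test_identical_arrays_give_zero(self, rng):
        x = rng.random((3, 28, 28, 1))
        assert mse_loss(x, x) == 0.0

    def test_unit_difference_gives_one(self):
        pred = np.ones((1, 28, 28, 1))
        target = np.zeros((1, 28, 28, 1))
        # per-element mean; the per-patch squared-norm convention differs by 784
        assert mse_loss(pred, target) == pytest.approx(1.0)
        assert 28 * 28 * mse_loss(pred, target) == pytest.approx(784.0)

    def test_matches_double_loop(self, rng):
        pred = rng.random((2, 4, 4, 1))
        target = rng.random((2, 4, 4, 1))
        acc = 0.0
        for n in range(2):
            for i in range(4):
                for j in range(4):
                    acc += (pred[n, i, j, 0] - target[n, i, j, 0]) ** 2
        assert mse_loss(pred, target) == pytest.approx(acc / 32, abs=1e-15)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            mse_loss(rng.random((1, 28, 28, 1)), rng.random((2, 28, 28, 1)))


class TestFit:
    def test_loss_decreases_on_synthetic_patch_set(self, rng):
        x, y = toy_data(rng, n=64)
        y = y + 0.2 * x[:, 6:34, 6:34, :]  # make targets input-dependent
        res = HiCEnhancer(x, y, spec=SMALL).fit(
            TrainConfig(batch_size=16, max_epochs=50, patience=50, seed=0)
        )
        assert res.history["train_loss"].iloc[-1] < res.history["train_loss"].iloc[0]
        assert list(res.history["epoch"]) == sorted(res.history["epoch"])

    def test_overfits_single_repeated_patch(self, rng):
        x = np.tile(rng.random((1, 40, 40, 1)), (8, 1, 1, 1))
        y = np.tile(rng.random((1, 28, 28, 1)), (8, 1, 1, 1))
        model = HiCEnhancer(x, y, val_inputs=x[:1], val_targets=y[:1], spec=SMALL)
        res = model.fit(TrainConfig(batch_size=1, max_epochs=150, patience=150, seed=1))
        pred = res.predict(x[:1])
        assert mse_loss(pred, y[:1]) < 1e-2

    def test_identical_seeds_give_identical_histories(self, rng):
        x, y = toy_data(rng, n=16)
        cfg = TrainConfig(batch_size=8, max_epochs=5, patience=5, seed=42)
        h1 = HiCEnhancer(x, y, spec=SMALL).fit(cfg).history
        h2 = HiCEnhancer(x, y, spec=SMALL).fit(cfg).history
        pd.testing.assert_frame_equal(h1, h2)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            HiCEnhancer(np.empty((0, 40, 40, 1)), np.empty((0, 28, 28, 1)), spec=SMALL)

    def test_summary_mentions_key_facts(self, rng):
        x, y = toy_data(rng, n=12)
        res = HiCEnhancer(x, y, spec=SMALL).fit(
            TrainConfig(batch_size=4, max_epochs=2, patience=2, seed=0)
        )
        text = res.summary()
        assert "validation MSE" in text
        assert str(network.param_count(SMALL)) in text


class TestCheckpoints:
    @pytest.fixture()
    def fitted(self, rng):
        x, y = toy_data(rng, n=12)
        return HiCEnhancer(x, y, spec=SMALL).fit(
            TrainConfig(batch_size=4, max_epochs=3, patience=3, seed=5)
        )

    def test_round_trip_forward_equality(self, tmp_path, fitted, rng):
        path = tmp_path / "ck.npz"
        fitted.save(path)
        loaded = HiCEnhancerResults.load(path)
        x = rng.random((3, 40, 40, 1))
        np.testing.assert_array_equal(fitted.predict(x), loaded.predict(x))
        assert loaded.best_val_loss == fitted.best_val_loss
        pd.testing.assert_frame_equal(loaded.history, fitted.history)

    def test_mismatched_architecture_rejected(self, tmp_path, fitted):
        path = tmp_path / "ck.npz"
        fitted.save(path)
        with pytest.raises(CheckpointError, match="architecture"):
            HiCEnhancerResults.load(path, spec=NetworkSpec())

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        path.write_bytes(b"not a checkpoint")
        with pytest.raises(CheckpointError):
            HiCEnhancerResults.load(path)

    def test_training_resumes_from_checkpoint_without_regressing(self, tmp_path, rng):
        x, y = toy_data(rng, n=12)
        model = HiCEnhancer(x[:8], y[:8], val_inputs=x[8:], val_targets=y[8:], spec=SMALL)
        first = model.fit(TrainConfig(batch_size=4, max_epochs=5, patience=5, seed=5))
        first.save(tmp_path / "ck.npz")
        loaded = HiCEnhancerResults.load(tmp_path / "ck.npz")
        resumed = model.fit(
            TrainConfig(batch_size=4, max_epochs=1, patience=1, seed=6), start=loaded
        )
        # best-so-far starts from the checkpointed state's validation loss
        assert resumed.best_val_loss <= first.best_val_loss + 1e-12
        assert resumed.value_scale == first.value_scale

    def test_warm_start_with_wrong_architecture_rejected(self, rng):
        x, y = toy_data(rng, n=8)
        res = HiCEnhancer(x, y, spec=SMALL).fit(
            TrainConfig(batch_size=4, max_epochs=1, patience=1, seed=0)
        )
        other = HiCEnhancer(x, y, spec=NetworkSpec(features=4, expand=8))
        with pytest.raises(ValueError, match="architecture"):
            other.fit(TrainConfig(max_epochs=1), start=res)
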