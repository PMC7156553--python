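"""Model / results objects for training and applying the enhancement network.

``HiCEnhancer`` is constructed from paired patch stacks (low-coverage 40x40
inputs, high-coverage 28x28 targets); ``fit`` minimizes the mean squared
error with Adam and returns a ``HiCEnhancerResults`` carrying the best
parameter state, the per-epoch loss history, and prediction / persistence
methods.  The workflow mirrors the usual model/results split of statistical
modelling packages::

    model = HiCEnhancer(train_inputs, train_targets, val_inputs, val_targets)
    res = model.fit(TrainConfig(max_epochs=30, batch_size=32, seed=1))
    enhanced = res.predict(test_inputs)
    print(res.summary())

Value normalization
-------------------
Raw Hi-C counts span orders of magnitude and the low-coverage input sits a
factor 1/ratio below its target, which makes first-order optimizers crawl.
``fit`` therefore (a) multiplies inputs by ``input_rescale`` — normally the
inverse thinning ratio, so input and target share a scale — and (b) divides
both by a data-derived value scale (a high percentile of the training
targets).  This is an affine reparameterization with the same optimum; the
scales are stored in the results and inverted by ``predict``.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json

import numpy as np
import pandas as pd

from . import network
from .network import NetworkSpec, mse_loss
from .patching import PatchSet

__all__ = ["HiCEnhancer", "HiCEnhancerResults", "TrainConfig", "CheckpointError", "mse_loss"]


class CheckpointError(RuntimeError):
    """Raised when a checkpoint file is corrupt or inconsistent."""


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings.

    Defaults follow the published recipe (Adam with default hyperparameters,
    batch size 256, Glorot init) with early stopping on validation MSE.
    """

    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 10
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    input_rescale: float = 1.0   # e.g. 1/thinning-ratio coverage compensation
    normalize: bool = True       # divide by a target-derived value scale
    clip: float | None = None    # optional cap on input counts, off by default
    val_fraction: float = 0.1    # used only when no explicit validation set
    grad_clip: float | None = 5.0  # global gradient-norm cap (normalized units)
    lr_patience: int = 8         # epochs without val improvement before halving lr
    min_lr: float = 1e-4         # floor guards against premature decay on noisy val sets

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _as_array(x) -> np.ndarray:
    if isinstance(x, PatchSet):
        x = x.data
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        x = x[..., None]
    return x


class HiCEnhancer:
    """Residual-CNN enhancement model over paired patch stacks."""

    def __init__(
        self,
        inputs,
        targets,
        val_inputs=None,
        val_targets=None,
        spec: NetworkSpec | None = None,
        dtype=np.float32,
    ):
        self.spec = spec or NetworkSpec()
        self.dtype = dtype
        self.inputs = _as_array(inputs)
        self.targets = _as_array(targets)
        if len(self.inputs) == 0:
            raise ValueError("empty training set")
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs and targets must have matching patch counts")
        s_in, s_out = self.spec.input_size, self.spec.output_size
        if self.inputs.shape[1:3] != (s_in, s_in):
            raise ValueError(f"inputs must be {s_in}x{s_in}, got {self.inputs.shape[1:3]}")
        if self.targets.shape[1:3] != (s_out, s_out):
            raise ValueError(f"targets must be {s_out}x{s_out}, got {self.targets.shape[1:3]}")
        if (val_inputs is None) != (val_targets is None):
            raise ValueError("provide both val_inputs and val_targets or neither")
        self.val_inputs = None if val_inputs is None else _as_array(val_inputs)
        self.val_targets = None if val_targets is None else _as_array(val_targets)

    def initialize(self, seed: int) -> dict:
        """Glorot-initialized parameter state, deterministic in the seed."""
        return network.init_params(self.spec, seed, dtype=self.dtype)

    def fit(
        self,
        config: TrainConfig | None = None,
        start: "HiCEnhancerResults | None" = None,
    ) -> "HiCEnhancerResults":
        """Train with Adam; returns the best-validation parameter state.

        ``start`` warm-starts from a previous fit's parameters (and reuses
        its value scale); the optimizer state itself starts fresh.
        """
        config = config or TrainConfig()
        spec = self.spec
        if start is not None and start.spec != spec:
            raise ValueError("warm-start results use a different architecture")
        rng = np.random.default_rng(config.seed)

        x, y = self.inputs, self.targets
        vx, vy = self.val_inputs, self.val_targets
        if vx is None:
            n_val = max(1, int(round(len(x) * config.val_fraction)))
            if n_val >= len(x):
                raise ValueError("training set too small to split a validation set")
            perm = rng.permutation(len(x))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            vx, vy = x[val_idx], y[val_idx]
            x, y = x[train_idx], y[train_idx]

        if config.clip is not None:
            x = np.minimum(x, config.clip)
            vx = np.minimum(vx, config.clip)
        value_scale = 1.0
        if start is not None:
            value_scale = start.value_scale
        elif config.normalize:
            ref = np.percentile(y, 99.0)
            if ref > 0:
                value_scale = 1.0 / ref
        in_scale = config.input_rescale * value_scale
        xs = (x * in_scale).astype(self.dtype)
        ys = (y * value_scale).astype(self.dtype)
        vxs = (vx * in_scale).astype(self.dtype)
        vys = (vy * value_scale).astype(self.dtype)

        if start is not None:
            params = {
                k: {n: v.astype(self.dtype).copy() for n, v in p.items()}
                for k, p in start.params.items()
            }
        else:
            params = self.initialize(config.seed)
        m_state = {k: {n: np.zeros_like(v) for n, v in p.items()} for k, p in params.items()}
        v_state = {k: {n: np.zeros_like(v) for n, v in p.items()} for k, p in params.items()}

        def val_loss(p) -> float:
            # batched to bound memory on large validation sets
            tot, cnt = 0.0, 0
            for s in range(0, len(vxs), 256):
                pred = network.forward(spec, p, vxs[s : s + 256])
                d = pred.astype(np.float64) - vys[s : s + 256]
                tot += float((d * d).sum())
                cnt += d.size
            return tot / cnt

        history: list[dict] = []
        best = {k: {n: v.copy() for n, v in p.items()} for k, p in params.items()}
        best_val = val_loss(params)
        best_epoch = 0
        step = 0
        bad_epochs = 0
        lr = config.learning_rate
        lr_stall = 0
        for epoch in range(1, config.max_epochs + 1):
            order = rng.permutation(len(xs))
            epoch_loss, n_batches = 0.0, 0
            for s in range(0, len(order), config.batch_size):
                idx = order[s : s + config.batch_size]
                loss, grads = network.loss_and_grads(spec, params, xs[idx], ys[idx])
                epoch_loss += loss
                n_batches += 1
                step += 1
                if config.grad_clip is not None:
                    # global-norm clipping guards against rare exploding
                    # batches that can kill the ReLU network outright
                    sq = 0.0
                    for g in grads.values():
                        for part in ("W", "b"):
                            sq += float((g[part].astype(np.float64) ** 2).sum())
                    gnorm = np.sqrt(sq)
                    if gnorm > config.grad_clip:
                        scale = config.grad_clip / gnorm
                        for g in grads.values():
                            g["W"] *= scale
                            g["b"] *= scale
                bc1 = 1.0 - config.beta1**step
                bc2 = 1.0 - config.beta2**step
                for name, g in grads.items():
                    for part in ("W", "b"):
                        m = m_state[name][part]
                        v = v_state[name][part]
                        gp = g[part]
                        m *= config.beta1
                        m += (1 - config.beta1) * gp
                        v *= config.beta2
                        v += (1 - config.beta2) * gp * gp
                        params[name][part] -= (
                            lr * (m / bc1) / (np.sqrt(v / bc2) + config.eps)
                        ).astype(self.dtype)
            vl = val_loss(params)
            history.append(
                {"epoch": epoch, "train_loss": epoch_loss / n_batches, "val_loss": vl, "lr": lr}
            )
            if vl < best_val:
                best_val = vl
                best_epoch = epoch
                best = {k: {n: v.copy() for n, v in p.items()} for k, p in params.items()}
                bad_epochs = 0
                lr_stall = 0
            else:
                bad_epochs += 1
                lr_stall += 1
                if bad_epochs >= config.patience:
                    break
                if lr_stall >= config.lr_patience and lr > config.min_lr:
                    lr = max(lr * 0.5, config.min_lr)
                    lr_stall = 0

        return HiCEnhancerResults(
            spec=spec,
            params=best,
            config=config,
            history=pd.DataFrame(history),
            value_scale=value_scale,
            best_val_loss=best_val,
            best_epoch=best_epoch,
            dtype=self.dtype,
        )


@dataclasses.dataclass
class HiCEnhancerResults:
    """Fitted enhancement network plus training diagnostics."""

    spec: NetworkSpec
    params: dict
    config: TrainConfig
    history: pd.DataFrame
    value_scale: float
    best_val_loss: float
    best_epoch: int
    dtype: type = np.float32

    def predict(self, inputs) -> np.ndarray:
        """Enhanced 28x28 patches for a stack of 40x40 low-coverage patches.

        Applies the stored input rescaling and value normalization and
        inverts the latter, so outputs are on the raw count scale.
        """
        x = _as_array(inputs)
        if self.config.clip is not None:
            x = np.minimum(x, self.config.clip)
        xs = (x * (self.config.input_rescale * self.value_scale)).astype(self.dtype)
        outs = []
        for s in range(0, len(xs), 256):
            outs.append(network.forward(self.spec, self.params, xs[s : s + 256]))
        pred = np.concatenate(outs).astype(np.float64)
        return pred / self.value_scale

    @property
    def n_parameters(self) -> int:
        return network.param_count(self.spec)

    def summary(self) -> str:
        buf = _io.StringIO()
        buf.write("Hi-C enhancement network — fit summary\n")
        buf.write("=" * 46 + "\n")
        buf.write(f"{'parameters':<28}{self.n_parameters}\n")
        buf.write(f"{'input -> output size':<28}{self.spec.input_size} -> {self.spec.output_size}\n")
        buf.write(f"{'epochs run':<28}{len(self.history)}\n")
        buf.write(f"{'best epoch':<28}{self.best_epoch}\n")
        buf.write(f"{'best validation MSE':<28}{self.best_val_loss:.6g}\n")
        buf.write(f"{'batch size':<28}{self.config.batch_size}\n")
        buf.write(f"{'learning rate':<28}{self.config.learning_rate}\n")
        buf.write(f"{'input rescale':<28}{self.config.input_rescale}\n")
        buf.write(f"{'value scale':<28}{self.value_scale:.6g}\n")
        buf.write(f"{'seed':<28}{self.config.seed}\n")
        return buf.getvalue()

    def plot_history(self, ax=None):
        """Training/validation loss curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["train_loss"], label="train")
        ax.plot(self.history["epoch"], self.history["val_loss"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE (normalized units)")
        ax.set_yscale("log")
        ax.legend()
        return ax

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "spec": self.spec.to_dict(),
            "config": self.config.to_dict(),
            "value_scale": self.value_scale,
            "best_val_loss": self.best_val_loss,
            "best_epoch": self.best_epoch,
            "dtype": np.dtype(self.dtype).name,
        }
        arrays = {}
        for name, p in self.params.items():
            arrays[f"param.{name}.W"] = p["W"]
            arrays[f"param.{name}.b"] = p["b"]
        hist = self.history.to_dict(orient="list") if len(self.history) else {}
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            history=np.frombuffer(json.dumps(hist).encode(), dtype=np.uint8),
            **arrays,
        )

    @classmethod
    def load(cls, path, spec: NetworkSpec | None = None) -> "HiCEnhancerResults":
        try:
            with np.load(path) as data:
                meta = json.loads(bytes(data["meta"]).decode())
                hist = json.loads(bytes(data["history"]).decode())
                arrays = {k: data[k] for k in data.files if k.startswith("param.")}
        except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
            raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
        stored_spec = NetworkSpec.from_dict(meta["spec"])
        if spec is not None and spec != stored_spec:
            raise CheckpointError(
                f"checkpoint was trained with a different architecture: "
                f"{stored_spec} != {spec}"
            )
        params: dict[str, dict[str, np.ndarray]] = {}
        for key, arr in arrays.items():
            _, name, part = key.split(".")
            params.setdefault(name, {})[part] = arr
        expected = {l.name for l in network.layers_of(stored_spec)}
        if set(params) != expected:
            raise CheckpointError("checkpoint parameter set does not match its architecture")
        cfg = meta["config"]
        cfg["clip"] = cfg.get("clip")
        return cls(
            spec=stored_spec,
            params=params,
            config=TrainConfig(**cfg),
            history=pd.DataFrame(hist),
            value_scale=meta["value_scale"],
            best_val_loss=meta["best_val_loss"],
            best_epoch=meta["best_epoch"],
            dtype=np.dtype(meta["dtype"]).type,
        )
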