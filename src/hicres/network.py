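"""The enhancement network: architecture, forward pass, and gradients.

The network maps a 40x40 single-channel window of a low-coverage contact
matrix to the central 28x28 window of the high-coverage matrix.  It is a
moderate-depth residual CNN:

* feature extraction: 7x7 then 5x5 convolutions (32 maps, size-preserving);
* a residual bottleneck block: 1x1 expansion to 128 maps + ReLU, 1x1
  reduction to 32 maps, a 7x7 size-preserving convolution, and an additive
  skip from the block input (no activation after the addition);
* cropping: four unpadded convolutions with kernels 5, 3, 5, 3 (32 maps,
  ReLU each), shrinking each spatial side by 4+2+4+2 = 12 bins, so 40 -> 28;
* a second residual bottleneck block;
* prediction: a 7x7 convolution (32 maps, ReLU) and a linear 5x5
  convolution to one output map.

Everything is plain numpy: convolutions are im2col + GEMM, gradients are
derived by hand (the transposed-convolution identity for the input gradient),
weights are Glorot-uniform initialized, biases start at zero.  Layouts are
NHWC for activations and (kh, kw, c_in, c_out) for kernels.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "NetworkSpec",
    "ConvLayer",
    "init_params",
    "param_count",
    "forward",
    "loss_and_grads",
    "mse_loss",
]


@dataclasses.dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters.

    The defaults are the published configuration; ``features``/``expand`` can
    be reduced for cheap test fixtures without changing the wiring.
    """

    input_size: int = 40
    features: int = 32
    expand: int = 128
    conv1_kernels: tuple[int, ...] = (7, 5)
    crop_kernels: tuple[int, ...] = (5, 3, 5, 3)
    res_kernel: int = 7
    conv3_kernels: tuple[int, ...] = (7, 5)

    @property
    def shrink(self) -> int:
        return sum(k - 1 for k in self.crop_kernels)

    @property
    def output_size(self) -> int:
        return self.input_size - self.shrink

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("conv1_kernels", "crop_kernels", "conv3_kernels"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        for key in ("conv1_kernels", "crop_kernels", "conv3_kernels"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class ConvLayer:
    name: str
    kernel: int
    c_in: int
    c_out: int
    same: bool  # size-preserving padding vs unpadded
    relu: bool


def build_blocks(spec: NetworkSpec) -> list[tuple[str, list[ConvLayer]]]:
    """Layer wiring as (block_kind, layers) with kind 'seq' or 'res'."""
    f, e = spec.features, spec.expand
    k1a, k1b = spec.conv1_kernels
    k3a, k3b = spec.conv3_kernels

    def res(prefix: str) -> list[ConvLayer]:
        return [
            ConvLayer(f"{prefix}_expand", 1, f, e, same=True, relu=True),
            ConvLayer(f"{prefix}_reduce", 1, e, f, same=True, relu=False),
            ConvLayer(f"{prefix}_conv", spec.res_kernel, f, f, same=True, relu=False),
        ]

    crop = [
        ConvLayer(f"crop{i}", k, f, f, same=False, relu=True)
        for i, k in enumerate(spec.crop_kernels, start=1)
    ]
    return [
        ("seq", [
            ConvLayer("feat1", k1a, 1, f, same=True, relu=True),
            ConvLayer("feat2", k1b, f, f, same=True, relu=True),
        ]),
        ("res", res("res1")),
        ("seq", crop),
        ("res", res("res2")),
        ("seq", [
            ConvLayer("pred1", k3a, f, f, same=True, relu=True),
            ConvLayer("pred2", k3b, f, 1, same=True, relu=False),
        ]),
    ]


def layers_of(spec: NetworkSpec) -> list[ConvLayer]:
    return [layer for _, block in build_blocks(spec) for layer in block]


def param_count(spec: NetworkSpec) -> int:
    return sum(l.kernel * l.kernel * l.c_in * l.c_out + l.c_out for l in layers_of(spec))


def init_params(spec: NetworkSpec, seed: int, dtype=np.float32) -> dict[str, dict[str, np.ndarray]]:
    """Glorot-uniform kernels, zero biases, deterministic in the seed."""
    rng = np.random.default_rng(seed)
    params = {}
    for l in layers_of(spec):
        fan_in = l.kernel * l.kernel * l.c_in
        fan_out = l.kernel * l.kernel * l.c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(l.kernel, l.kernel, l.c_in, l.c_out))
        params[l.name] = {
            "W": w.astype(dtype),
            "b": np.zeros(l.c_out, dtype=dtype),
        }
    return params


# ---------------------------------------------------------------------------
# convolution primitives (NHWC, kernels (kh, kw, cin, cout))

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))


def _conv_valid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Unpadded convolution as a sum of shifted GEMMs.

    Summing ``x[:, a:a+oh, b:b+ow] @ w[a, b]`` over kernel offsets avoids the
    large transposed im2col copy, which dominates runtime on a single CPU.
    """
    k, _, c_in, c_out = w.shape
    n, h, wd, _ = x.shape
    if k == 1:
        return (x.reshape(-1, c_in) @ w.reshape(c_in, c_out)).reshape(n, h, wd, c_out)
    oh, ow = h - k + 1, wd - k + 1
    acc = np.zeros((n * oh * ow, c_out), dtype=x.dtype)
    for a in range(k):
        for b in range(k):
            xs = np.ascontiguousarray(x[:, a : a + oh, b : b + ow, :]).reshape(-1, c_in)
            acc += xs @ w[a, b]
    return acc.reshape(n, oh, ow, c_out)


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, same: bool) -> np.ndarray:
    k = w.shape[0]
    p = (k - 1) // 2 if same else 0
    return _conv_valid(_pad_hw(x, p), w) + b


def conv_backward(
    dy: np.ndarray, x: np.ndarray, w: np.ndarray, same: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dW, db) of a convolution given upstream dy."""
    k, _, c_in, c_out = w.shape
    p = (k - 1) // 2 if same else 0
    xp = _pad_hw(x, p)
    db = dy.sum(axis=(0, 1, 2))

    if k == 1:
        n, h, wd, _ = x.shape
        dw = (xp.reshape(-1, c_in).T @ dy.reshape(-1, c_out)).reshape(1, 1, c_in, c_out)
        dx = (dy.reshape(-1, c_out) @ w.reshape(c_in, c_out).T).reshape(n, h, wd, c_in)
        return dx, dw, db

    n, oh, ow, _ = dy.shape
    dyf = np.ascontiguousarray(dy).reshape(-1, c_out)
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp)
    for a in range(k):
        for b in range(k):
            xs = np.ascontiguousarray(xp[:, a : a + oh, b : b + ow, :]).reshape(-1, c_in)
            dw[a, b] = xs.T @ dyf
            dxp[:, a : a + oh, b : b + ow, :] += (dyf @ w[a, b].T).reshape(n, oh, ow, c_in)
    if p:
        dxp = dxp[:, p:-p, p:-p, :]
    return dxp, dw, db


# ---------------------------------------------------------------------------
# full network

def forward(
    spec: NetworkSpec,
    params: dict,
    x: np.ndarray,
    caches: list | None = None,
) -> np.ndarray:
    """Run the network on a (n, s, s, 1) stack.

    When ``caches`` is a list it is filled with per-layer records needed by
    :func:`backward`.
    """
    x = np.asarray(x)
    if x.ndim == 3:
        x = x[..., None]
    if x.ndim != 4 or x.shape[1] != spec.input_size or x.shape[2] != spec.input_size:
        raise ValueError(
            f"expected (n, {spec.input_size}, {spec.input_size}, 1) input, got {x.shape}"
        )
    h = x
    for kind, block in build_blocks(spec):
        block_in = h
        for layer in block:
            p = params[layer.name]
            z = conv_forward(h, p["W"], p["b"], layer.same)
            if layer.relu:
                mask = z > 0
                a = z * mask
            else:
                mask = None
                a = z
            if caches is not None:
                caches.append((layer, h, mask))
            h = a
        if kind == "res":
            h = block_in + h
    return h


def backward(spec: NetworkSpec, params: dict, caches: list, dy: np.ndarray) -> dict:
    """Parameter gradients by reverse traversal of the cached forward pass."""
    grads: dict[str, dict[str, np.ndarray]] = {}
    blocks = build_blocks(spec)
    n_layers = [len(b) for _, b in blocks]
    offsets = np.cumsum([0, *n_layers])
    d = dy
    for bi in range(len(blocks) - 1, -1, -1):
        kind, block = blocks[bi]
        d_branch = d
        for li in range(len(block) - 1, -1, -1):
            layer, x_in, mask = caches[offsets[bi] + li]
            if mask is not None:
                d_branch = d_branch * mask
            dx, dw, db = conv_backward(d_branch, x_in, params[layer.name]["W"], layer.same)
            grads[layer.name] = {"W": dw, "b": db}
            d_branch = dx
        d = d + d_branch if kind == "res" else d_branch
    return grads


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Per-element mean squared error.

    The training objective is often written as a mean over patches of the
    squared Frobenius norm; dividing additionally by the elements per patch
    (a constant) leaves the optimum unchanged and keeps the scale readable.
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    diff = pred.astype(np.float64) - target.astype(np.float64)
    return float(np.mean(diff * diff))


def loss_and_grads(
    spec: NetworkSpec, params: dict, x: np.ndarray, y: np.ndarray
) -> tuple[float, dict]:
    caches: list = []
    pred = forward(spec, params, x, caches)
    if pred.shape != y.shape:
        raise ValueError(f"prediction shape {pred.shape} != target shape {y.shape}")
    diff = pred - y
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    dy = (2.0 / diff.size) * diff
    grads = backward(spec, params, caches, dy.astype(pred.dtype))
    return loss, grads
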