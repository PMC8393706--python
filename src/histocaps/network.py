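"""Multi-input dual-stream capsule network.

Two input streams are processed in parallel: the raw RGB tile goes through
a block of four conventional 3x3 convolutions (CLB) and the enhanced tile
— reduced to luminance — through a block of four depthwise-separable 3x3
convolutions (SCLB).  The two 64-channel feature maps are concatenated,
reduced by per-stream stride-2 capsule convolutions into 32 + 16 = 48
primary capsules of dimension 8, squashed, and routed by agreement to 5
class capsules of dimension 16.  The predicted class is the capsule with
the largest output norm.

Layers are implemented directly on NumPy (im2col convolution with BLAS
matmuls) with hand-written backward passes, so the whole model trains on a
CPU without a deep-learning framework.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .capsules import coupling_from_logits, dynamic_routing, squash

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "CapsNet",
    "build_model",
    "count_parameters",
    "reference_parameter_table",
    "check_reference_counts",
    "merge_features",
    "forward",
    "model_summary",
    "write_summary_csv",
    "Adam",
]


# ---------------------------------------------------------------------------
# declarative architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    """One convolutional layer of a stream block.

    Trainable parameters:
      conv            kh*kw*in*out + out          (bias per filter)
      separable_conv  kh*kw*in + in*out + out     (depthwise without bias,
                                                   pointwise with bias)
    """

    kind: str  # "conv" | "separable_conv"
    in_channels: int
    out_channels: int
    kernel: tuple[int, int] = (3, 3)
    stride: int = 1
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "separable_conv"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")

    @property
    def param_count(self) -> int:
        kh, kw = self.kernel
        if self.kind == "conv":
            return kh * kw * self.in_channels * self.out_channels + self.out_channels
        return (
            kh * kw * self.in_channels
            + self.in_channels * self.out_channels
            + self.out_channels
        )


@dataclass(frozen=True)
class ModelSpec:
    """The dual-stream architecture as declarative configuration."""

    input_shape: tuple[int, int, int] = (50, 50, 3)
    conv_channels: int = 64
    n_block_layers: int = 4
    sclb_input_channels: int = 1
    primary_capsules_clb: int = 32
    primary_capsules_sclb: int = 16
    primary_capsule_dim: int = 8
    class_capsules: int = 5
    class_capsule_dim: int = 16
    routing_iterations: int = 3
    caps_kernel: tuple[int, int] = (3, 3)
    caps_stride: int = 2

    def __post_init__(self) -> None:
        if self.n_block_layers < 1:
            raise ValueError("n_block_layers must be >= 1")
        if self.routing_iterations < 1:
            raise ValueError("routing_iterations must be >= 1")
        if min(self.primary_capsules_clb, self.primary_capsules_sclb) < 1:
            raise ValueError("capsule counts must be positive")

    @property
    def clb(self) -> list[LayerSpec]:
        c = self.conv_channels
        layers = [LayerSpec("conv", self.input_shape[2], c)]
        layers += [LayerSpec("conv", c, c) for _ in range(self.n_block_layers - 1)]
        return layers

    @property
    def sclb(self) -> list[LayerSpec]:
        c = self.conv_channels
        layers = [LayerSpec("separable_conv", self.sclb_input_channels, c)]
        layers += [
            LayerSpec("separable_conv", c, c) for _ in range(self.n_block_layers - 1)
        ]
        return layers

    @property
    def total_primary_capsules(self) -> int:
        return self.primary_capsules_clb + self.primary_capsules_sclb


#: published per-layer trainable-parameter counts for the default spec
REFERENCE_CONV_PARAMS: dict[str, int] = {
    "Convolutional Layer1": 1792,
    "Convolutional Layer2": 36928,
    "Convolutional Layer3": 36928,
    "Convolutional Layer4": 36928,
    "Separable Convolutional Layer1": 137,
    "Separable Convolutional Layer2": 4736,
    "Separable Convolutional Layer3": 4736,
    "Separable Convolutional Layer4": 4736,
}
REFERENCE_PRIMARY_CAPSULES = 48
REFERENCE_CLASS_CAPSULES = 5


def count_parameters(spec: ModelSpec) -> list[dict]:
    """Per-layer trainable-parameter table (closed formulas, no arrays).

    Rows mirror the model summary: the four CLB layers, the four SCLB
    layers, the primary-capsule stage (both stride-2 capsule convolutions)
    and the class-capsule transform matrices.
    """
    rows: list[dict] = []
    for i, ls in enumerate(spec.clb, start=1):
        rows.append(
            {
                "layer": f"Convolutional Layer{i}",
                "channels": ls.out_channels,
                "filter_size": "x".join(map(str, ls.kernel)),
                "stride": ls.stride,
                "parameters": ls.param_count,
                "capsules": None,
            }
        )
    for i, ls in enumerate(spec.sclb, start=1):
        rows.append(
            {
                "layer": f"Separable Convolutional Layer{i}",
                "channels": ls.out_channels,
                "filter_size": "x".join(map(str, ls.kernel)),
                "stride": ls.stride,
                "parameters": ls.param_count,
                "capsules": None,
            }
        )
    kh, kw = spec.caps_kernel
    d = spec.primary_capsule_dim
    c = spec.conv_channels
    caps_params = 0
    for n_caps in (spec.primary_capsules_clb, spec.primary_capsules_sclb):
        caps_params += kh * kw * c * (n_caps * d) + n_caps * d
    rows.append(
        {
            "layer": "Primary Capsules",
            "channels": None,
            "filter_size": "x".join(map(str, spec.caps_kernel)),
            "stride": spec.caps_stride,
            "parameters": caps_params,
            "capsules": spec.total_primary_capsules,
        }
    )
    rows.append(
        {
            "layer": "Class Capsules",
            "channels": None,
            "filter_size": None,
            "stride": None,
            "parameters": spec.total_primary_capsules
            * spec.class_capsules
            * spec.primary_capsule_dim
            * spec.class_capsule_dim,
            "capsules": spec.class_capsules,
        }
    )
    return rows


def reference_parameter_table() -> dict[str, int]:
    """The published convolutional parameter counts of the default model."""
    return dict(REFERENCE_CONV_PARAMS)


def check_reference_counts(spec: ModelSpec) -> list[str]:
    """Compare count_parameters(spec) with the published reference counts.

    Returns a list of human-readable mismatch descriptions (empty = all
    convolutional rows and capsule counts agree).
    """
    rows = {r["layer"]: r for r in count_parameters(spec)}
    mismatches = []
    for name, expected in REFERENCE_CONV_PARAMS.items():
        got = rows.get(name, {}).get("parameters")
        if got != expected:
            mismatches.append(f"{name}: computed {got}, reference {expected}")
    n_prim = rows.get("Primary Capsules", {}).get("capsules")
    if n_prim != REFERENCE_PRIMARY_CAPSULES:
        mismatches.append(
            f"Primary Capsules: computed {n_prim}, reference {REFERENCE_PRIMARY_CAPSULES}"
        )
    n_cls = rows.get("Class Capsules", {}).get("capsules")
    if n_cls != REFERENCE_CLASS_CAPSULES:
        mismatches.append(
            f"Class Capsules: computed {n_cls}, reference {REFERENCE_CLASS_CAPSULES}"
        )
    return mismatches


# ---------------------------------------------------------------------------
# layers (NumPy forward/backward)
# ---------------------------------------------------------------------------

def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """'same' output size and asymmetric pad amounts for one axis."""
    out = math.ceil(size / stride)
    total = max((out - 1) * stride + kernel - size, 0)
    return out, total // 2, total - total // 2


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    """Extract (B, Ho, Wo, kh, kw, C) windows of a same-padded input."""
    b, h, w, c = x.shape
    ho, pt, pb = _same_pad(h, kh, stride)
    wo, pl, pr = _same_pad(w, kw, stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (B, Ho, Wo, C, kh, kw)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return cols, (ho, wo, pt, pb, pl, pr, xp.shape)


def _col2im(dcols: np.ndarray, x_shape, meta, stride: int) -> np.ndarray:
    """Scatter-add window gradients back onto the (unpadded) input."""
    b, h, w, c = x_shape
    ho, wo, pt, pb, pl, pr, xp_shape = meta[0], meta[1], meta[2], meta[3], meta[4], meta[5], meta[6]
    kh, kw = dcols.shape[3], dcols.shape[4]
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + (ho - 1) * stride + 1 : stride,
                j : j + (wo - 1) * stride + 1 : stride, :] += dcols[:, :, :, i, j, :]
    return dxp[:, pt : pt + h, pl : pl + w, :]


class _Layer:
    """Minimal trainable-layer protocol: params/grads dicts + fwd/bwd."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv2D(_Layer):
    """3x3-style convolution, 'same' padding, He-initialised, with bias."""

    def __init__(self, rng, kh, kw, cin, cout, stride=1, dtype=np.float32):
        super().__init__()
        fan_in = kh * kw * cin
        self.params["W"] = rng.normal(
            0.0, math.sqrt(2.0 / fan_in), (kh, kw, cin, cout)
        ).astype(dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)
        self.kh, self.kw, self.stride = kh, kw, stride

    def forward(self, x):
        cols, meta = _im2col(x, self.kh, self.kw, self.stride)
        b, ho, wo = cols.shape[0], cols.shape[1], cols.shape[2]
        cols2d = cols.reshape(b * ho * wo, -1)
        wm = self.params["W"].reshape(-1, self.params["W"].shape[-1])
        out = cols2d @ wm + self.params["b"]
        self._cache = (x.shape, cols2d, meta, (b, ho, wo))
        return out.reshape(b, ho, wo, -1)

    def backward(self, dout):
        x_shape, cols2d, meta, (b, ho, wo) = self._cache
        cout = dout.shape[-1]
        dout2d = dout.reshape(b * ho * wo, cout)
        wm = self.params["W"].reshape(-1, cout)
        self.grads["W"] = (cols2d.T @ dout2d).reshape(self.params["W"].shape)
        self.grads["b"] = dout2d.sum(axis=0)
        dcols = (dout2d @ wm.T).reshape(b, ho, wo, self.kh, self.kw, x_shape[-1])
        return _col2im(dcols, x_shape, meta, self.stride)


class SeparableConv2D(_Layer):
    """Depthwise 3x3 (no bias) followed by pointwise 1x1 (with bias)."""

    def __init__(self, rng, kh, kw, cin, cout, stride=1, dtype=np.float32):
        super().__init__()
        self.params["Wd"] = rng.normal(
            0.0, math.sqrt(2.0 / (kh * kw)), (kh, kw, cin)
        ).astype(dtype)
        self.params["Wp"] = rng.normal(
            0.0, math.sqrt(2.0 / cin), (cin, cout)
        ).astype(dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)
        self.kh, self.kw, self.stride = kh, kw, stride

    def forward(self, x):
        cols, meta = _im2col(x, self.kh, self.kw, self.stride)
        depth = np.einsum("bhwklc,klc->bhwc", cols, self.params["Wd"])
        b, ho, wo, c = depth.shape
        out = depth.reshape(-1, c) @ self.params["Wp"] + self.params["b"]
        self._cache = (x.shape, cols, depth, meta, (b, ho, wo))
        return out.reshape(b, ho, wo, -1)

    def backward(self, dout):
        x_shape, cols, depth, meta, (b, ho, wo) = self._cache
        cin, cout = self.params["Wp"].shape
        dout2d = dout.reshape(-1, cout)
        self.grads["Wp"] = depth.reshape(-1, cin).T @ dout2d
        self.grads["b"] = dout2d.sum(axis=0)
        ddepth = (dout2d @ self.params["Wp"].T).reshape(b, ho, wo, cin)
        self.grads["Wd"] = np.einsum("bhwklc,bhwc->klc", cols, ddepth)
        dcols = ddepth[:, :, :, None, None, :] * self.params["Wd"][None, None, None]
        return _col2im(dcols, x_shape, meta, self.stride)


class ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool(_Layer):
    """Mean over the spatial axes; collapses (B, H, W, C) to (B, C)."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        b, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :], self._shape) / (h * w)


class Squash(_Layer):
    """Capsule squashing on (B, N, D) with its exact Jacobian."""

    def forward(self, s):
        self._s = s
        return squash(s, axis=-1)

    def backward(self, dv):
        s = self._s
        sq = np.sum(s * s, axis=-1, keepdims=True)
        r = np.sqrt(np.maximum(sq, 1e-18))
        a = r / (1.0 + sq)                       # v = a(r) * s
        da = (1.0 - sq) / (1.0 + sq) ** 2        # da/dr
        dot = np.sum(dv * s, axis=-1, keepdims=True)
        return a * dv + da * dot / r * s


class ClassCapsules(_Layer):
    """Transform 48 primary capsules into votes and route to class capsules.

    The per-pair transform W (I, J, D, P) produces votes u_hat = W_ij u_i;
    dynamic routing assigns couplings.  The backward pass treats the final
    couplings as constants (exact when routing_iterations == 1, a standard
    approximation otherwise) and differentiates through the weighted sum and
    the squash.
    """

    def __init__(self, rng, n_in, n_out, d_in, d_out, iterations=3, dtype=np.float32):
        super().__init__()
        self.params["W"] = rng.normal(
            0.0, 0.1, (n_in, n_out, d_in, d_out)
        ).astype(dtype)
        self.iterations = iterations

    def forward(self, u):
        u_hat = np.einsum("ijdp,bid->bijp", self.params["W"], u)
        v, state = self._route(u_hat)
        self._cache = (u, u_hat, state)
        self.last_state = state
        return v

    def _route(self, u_hat):
        return dynamic_routing(u_hat, self.iterations)

    def backward(self, dv):
        u, u_hat, state = self._cache
        s = state.parent_inputs                    # (B, J, P)
        sq = np.sum(s * s, axis=-1, keepdims=True)
        r = np.sqrt(np.maximum(sq, 1e-18))
        a = r / (1.0 + sq)
        da = (1.0 - sq) / (1.0 + sq) ** 2
        dot = np.sum(dv * s, axis=-1, keepdims=True)
        ds = a * dv + da * dot / r * s
        du_hat = state.couplings[..., None] * ds[:, None, :, :]
        self.grads["W"] = np.einsum("bijp,bid->ijdp", du_hat, u)
        return np.einsum("bijp,ijdp->bid", du_hat, self.params["W"])


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def merge_features(clb: np.ndarray, sclb: np.ndarray) -> np.ndarray:
    """Concatenate the two stream feature maps along channels, CLB first."""
    if clb.shape[:-1] != sclb.shape[:-1]:
        raise ValueError(
            f"spatial shapes differ: {clb.shape[:-1]} vs {sclb.shape[:-1]}"
        )
    return np.concatenate([clb, sclb], axis=-1)


class CapsNet:
    """The dual-stream capsule model, trainable on NumPy alone."""

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        kh, kw = 3, 3

        def conv_block(layer_specs):
            layers = []
            for ls in layer_specs:
                if ls.kind == "conv":
                    layers.append(
                        Conv2D(rng, *ls.kernel, ls.in_channels, ls.out_channels,
                               ls.stride, dtype)
                    )
                else:
                    layers.append(
                        SeparableConv2D(rng, *ls.kernel, ls.in_channels,
                                        ls.out_channels, ls.stride, dtype)
                    )
                layers.append(ReLU())
            return layers

        self.clb_layers = conv_block(spec.clb)
        self.sclb_layers = conv_block(spec.sclb)
        ckh, ckw = spec.caps_kernel
        d = spec.primary_capsule_dim
        self.caps_conv_clb = Conv2D(
            rng, ckh, ckw, spec.conv_channels, spec.primary_capsules_clb * d,
            spec.caps_stride, dtype,
        )
        self.caps_conv_sclb = Conv2D(
            rng, ckh, ckw, spec.conv_channels, spec.primary_capsules_sclb * d,
            spec.caps_stride, dtype,
        )
        self.pool_clb = GlobalAvgPool()
        self.pool_sclb = GlobalAvgPool()
        self.squash_layer = Squash()
        self.class_caps = ClassCapsules(
            rng, spec.total_primary_capsules, spec.class_capsules, d,
            spec.class_capsule_dim, spec.routing_iterations, dtype,
        )

    # -- bookkeeping --------------------------------------------------------

    @property
    def layers(self) -> list[_Layer]:
        return (
            self.clb_layers
            + self.sclb_layers
            + [self.caps_conv_clb, self.caps_conv_sclb, self.class_caps]
        )

    def parameters(self):
        """Yield (key, layer, name) triples for every trainable array."""
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"layer{li}/{name}", layer, name

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    # -- forward / backward -------------------------------------------------

    def _prep_sclb_input(self, x_prep: np.ndarray) -> np.ndarray:
        want = self.spec.sclb_input_channels
        if x_prep.shape[-1] == want:
            return x_prep
        if want == 1 and x_prep.shape[-1] == 3:
            return x_prep.mean(axis=-1, keepdims=True)
        raise ValueError(
            f"SCLB expects {want} channels, got {x_prep.shape[-1]}"
        )

    def forward(self, x_orig: np.ndarray, x_prep: np.ndarray) -> np.ndarray:
        """Batched forward pass -> class-capsule vectors (B, J, P)."""
        if x_orig.shape[0] != x_prep.shape[0]:
            raise ValueError("the two input batches must have equal size")
        x_o = np.asarray(x_orig, dtype=self.dtype)
        x_p = self._prep_sclb_input(np.asarray(x_prep, dtype=self.dtype))
        for layer in self.clb_layers:
            x_o = layer.forward(x_o)
        for layer in self.sclb_layers:
            x_p = layer.forward(x_p)
        merged = merge_features(x_o, x_p)
        c = self.spec.conv_channels
        caps_a = self.pool_clb.forward(
            self.caps_conv_clb.forward(merged[..., :c])
        )
        caps_b = self.pool_sclb.forward(
            self.caps_conv_sclb.forward(merged[..., c:])
        )
        b = merged.shape[0]
        d = self.spec.primary_capsule_dim
        u = np.concatenate(
            [
                caps_a.reshape(b, self.spec.primary_capsules_clb, d),
                caps_b.reshape(b, self.spec.primary_capsules_sclb, d),
            ],
            axis=1,
        )
        u = self.squash_layer.forward(u)
        return self.class_caps.forward(u)

    def backward(self, dv: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the class-capsule vectors."""
        dv = np.asarray(dv, dtype=self.dtype)
        du = self.class_caps.backward(dv)
        du = self.squash_layer.backward(du)
        b = du.shape[0]
        d = self.spec.primary_capsule_dim
        n_a = self.spec.primary_capsules_clb
        dcaps_a = du[:, :n_a].reshape(b, n_a * d)
        dcaps_b = du[:, n_a:].reshape(b, -1)
        dm_a = self.caps_conv_clb.backward(self.pool_clb.backward(dcaps_a))
        dm_b = self.caps_conv_sclb.backward(self.pool_sclb.backward(dcaps_b))
        for layer in reversed(self.clb_layers):
            dm_a = layer.backward(dm_a)
        for layer in reversed(self.sclb_layers):
            dm_b = layer.backward(dm_b)

    def predict(self, x_orig: np.ndarray, x_prep: np.ndarray) -> np.ndarray:
        """Predicted class = argmax over class-capsule output norms."""
        v = self.forward(x_orig, x_prep)
        return np.argmax(np.linalg.norm(v, axis=-1), axis=-1)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        arrays = {key: layer.params[name] for key, layer, name in self.parameters()}
        np.savez(path, **arrays)

    def load(self, path) -> None:
        with np.load(path) as data:
            for key, layer, name in self.parameters():
                if data[key].shape != layer.params[name].shape:
                    raise ValueError(
                        f"checkpoint shape mismatch for {key}: "
                        f"{data[key].shape} vs {layer.params[name].shape}"
                    )
                layer.params[name] = data[key].astype(self.dtype)


def build_model(spec: ModelSpec | None = None, seed: int = 0, dtype=np.float32) -> CapsNet:
    """Instantiate the dual-stream capsule network with seeded weights."""
    return CapsNet(spec or ModelSpec(), seed=seed, dtype=dtype)


def forward(model: CapsNet, batch_original: np.ndarray, batch_preprocessed: np.ndarray) -> np.ndarray:
    """Functional alias for ``model.forward``."""
    return model.forward(batch_original, batch_preprocessed)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, model: CapsNet, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(l.params[n]) for k, l, n in model.parameters()}
        self.v = {k: np.zeros_like(l.params[n]) for k, l, n in model.parameters()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer, name in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            g = g.astype(layer.params[name].dtype, copy=False)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1**self.t)
            vhat = self.v[key] / (1 - b2**self.t)
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------

def model_summary(spec: ModelSpec | None = None) -> str:
    """Text table of layers, channels, filter sizes, strides and parameters."""
    spec = spec or ModelSpec()
    rows = count_parameters(spec)
    header = ("Layer", "Channels", "Filter Size", "Stride", "Parameters", "Capsules")
    table = [header]
    for r in rows:
        table.append(
            (
                r["layer"],
                str(r["channels"]) if r["channels"] is not None else "--",
                r["filter_size"] or "--",
                str(r["stride"]) if r["stride"] is not None else "--",
                f"{r['parameters']:,}",
                str(r["capsules"]) if r["capsules"] is not None else "--",
            )
        )
    widths = [max(len(row[i]) for row in table) for i in range(len(header))]
    lines = []
    for i, row in enumerate(table):
        lines.append("  ".join(cell.ljust(w) for cell, w in zip(row, widths)))
        if i == 0:
            lines.append("  ".join("-" * w for w in widths))
    total = sum(r["parameters"] for r in rows)
    lines.append(f"Total trainable parameters: {total:,}")
    return "\n".join(lines)


def write_summary_csv(path, spec: ModelSpec | None = None) -> None:
    """CSV version of the model summary table."""
    import csv

    spec = spec or ModelSpec()
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["layer", "channels", "filter_size", "stride", "parameters", "capsules"],
        )
        writer.writeheader()
        writer.writerows(count_parameters(spec))
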