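"""A modified V-Net in pure numpy, with hand-derived backpropagation.

The architecture follows the V-Net encoder-decoder: per encoder stage a
residual convolution block, then a strided 2x2x2 convolution that doubles the
filter count and halves every spatial dimension; the decoder mirrors the
encoder with transposed convolutions and skip concatenation; a final 1x1x1
convolution produces four-class logits (background + three leaflets).  All
trunk convolutions use 3x3x3 kernels and ReLU non-linearities, with instance
normalization inside the blocks.

Implementation notes: convolutions are evaluated by materialising sliding
windows and contracting with BLAS (im2col); the stride-2 down/up-sampling
convolutions are non-overlapping and reduce to block reshapes plus einsum.
Every layer caches what its backward pass needs; gradients are exact and are
verified against finite differences in the test suite.  Arrays are float32,
shaped ``(C, D, H, W)`` for a single sample.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ModelSpec", "VNet", "build_model", "forward_probs", "softmax", "save_checkpoint", "load_checkpoint"]

_EPS_NORM = 1e-5


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of the network topology."""

    in_channels: int = 1
    n_classes: int = 4
    base_filters: int = 16
    n_stages: int = 5          # 5 for the full 224^3 profile; 2 suffices at desk scale
    kernel_edge: int = 3
    nonlinearity: str = "relu"

    def __post_init__(self) -> None:
        if not (1 <= self.in_channels <= 15):
            raise ValueError("in_channels must be between 1 and 15")
        if self.kernel_edge != 3:
            raise ValueError("trunk kernels are fixed at 3x3x3")
        if self.nonlinearity != "relu":
            raise ValueError("only ReLU is supported")
        if self.n_stages < 1:
            raise ValueError("need at least one stage")

    def validate_shape(self, shape: tuple[int, ...]) -> None:
        div = 2 ** (self.n_stages - 1)
        if any(s % div for s in shape):
            raise ValueError(
                f"input spatial shape {shape} must be divisible by 2^(n_stages-1) = {div}"
            )


def desk_spec(in_channels: int) -> ModelSpec:
    """The desk-scale profile: 2 stages, 8 base filters."""
    return ModelSpec(in_channels=in_channels, base_filters=8, n_stages=2)


def full_spec(in_channels: int) -> ModelSpec:
    """The full-resolution profile used at 224^3."""
    return ModelSpec(in_channels=in_channels, base_filters=16, n_stages=5)


# ---------------------------------------------------------------------------
# layers


class _Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv3x3(_Layer):
    """3x3x3 convolution, stride 1, same padding."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["w"] = _he(rng, (cout, cin, 3, 3, 3), fan_in=cin * 27)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))  # (C, D, H, W, 3,3,3)
        return np.tensordot(w, win, axes=([1, 2, 3, 4], [0, 4, 5, 6]))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return self._conv(x, self.params["w"]) + self.params["b"][:, None, None, None]

    def backward(self, go: np.ndarray) -> np.ndarray:
        w = self.params["w"]
        cout = w.shape[0]
        cin, d, h, ww_ = self._x.shape
        n = d * h * ww_
        xp = np.pad(self._x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        go_f = go.reshape(cout, n)
        # weight gradient as 27 shifted-slice matmuls (avoids an im2col gather)
        gw = self.grads["w"]
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    sub = xp[:, a : a + d, b : b + h, c : c + ww_].reshape(cin, n)
                    gw[:, :, a, b, c] += go_f @ sub.T
        self.grads["b"] += go_f.sum(axis=1)
        w_t = np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        del self._x
        return self._conv(go, w_t)


class Conv1(_Layer):
    """1x1x1 convolution head."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["w"] = _he(rng, (cout, cin), fan_in=cin)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,cdhw->odhw", self.params["w"], x) + self.params["b"][:, None, None, None]

    def backward(self, go: np.ndarray) -> np.ndarray:
        self.grads["w"] += np.einsum("odhw,cdhw->oc", go, self._x)
        self.grads["b"] += go.sum(axis=(1, 2, 3))
        gx = np.einsum("oc,odhw->cdhw", self.params["w"], go)
        del self._x
        return gx


class DownConv(_Layer):
    """2x2x2 convolution with stride 2 (halves each spatial dimension)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["w"] = _he(rng, (cout, cin, 2, 2, 2), fan_in=cin * 8)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w_ = x.shape
        if d % 2 or h % 2 or w_ % 2:
            raise ValueError(f"spatial shape {x.shape[1:]} not divisible by 2")
        xb = x.reshape(c, d // 2, 2, h // 2, 2, w_ // 2, 2)
        self._xb = xb
        out = np.einsum("ocijk,cdiejfk->odef", self.params["w"], xb, optimize=True)
        return out + self.params["b"][:, None, None, None]

    def backward(self, go: np.ndarray) -> np.ndarray:
        self.grads["w"] += np.einsum("odef,cdiejfk->ocijk", go, self._xb, optimize=True)
        self.grads["b"] += go.sum(axis=(1, 2, 3))
        gxb = np.einsum("ocijk,odef->cdiejfk", self.params["w"], go, optimize=True)
        c = gxb.shape[0]
        d2, h2, w2 = go.shape[1:]
        del self._xb
        return np.ascontiguousarray(gxb).reshape(c, 2 * d2, 2 * h2, 2 * w2)


class UpConv(_Layer):
    """2x2x2 transposed convolution with stride 2 (doubles each spatial dimension)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["w"] = _he(rng, (cin, cout, 2, 2, 2), fan_in=cin)
        self.params["b"] = np.zeros(cout, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        ob = np.einsum("coijk,cdef->odiejfk", self.params["w"], x, optimize=True)
        o = ob.shape[0]
        d, h, w_ = x.shape[1:]
        out = np.ascontiguousarray(ob).reshape(o, 2 * d, 2 * h, 2 * w_)
        return out + self.params["b"][:, None, None, None]

    def backward(self, go: np.ndarray) -> np.ndarray:
        o, d2, h2, w2 = go.shape
        gob = go.reshape(o, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2)
        self.grads["w"] += np.einsum("cdef,odiejfk->coijk", self._x, gob, optimize=True)
        self.grads["b"] += go.sum(axis=(1, 2, 3))
        gx = np.einsum("coijk,odiejfk->cdef", self.params["w"], gob, optimize=True)
        del self._x
        return gx


class InstanceNorm(_Layer):
    def __init__(self, channels: int) -> None:
        super().__init__()
        self.params["g"] = np.ones(channels, dtype=np.float32)
        self.params["b"] = np.zeros(channels, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + _EPS_NORM)
        self._xhat = (x - mu) * self._inv
        return self.params["g"][:, None, None, None] * self._xhat + self.params["b"][:, None, None, None]

    def backward(self, go: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.grads["g"] += np.einsum("cdhw,cdhw->c", go, xhat)
        self.grads["b"] += go.sum(axis=(1, 2, 3))
        gxhat = go * self.params["g"][:, None, None, None]
        m1 = gxhat.mean(axis=(1, 2, 3), keepdims=True)
        m2 = (gxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
        gx = inv * (gxhat - m1 - xhat * m2)
        del self._xhat, self._inv
        return gx


class ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, go: np.ndarray) -> np.ndarray:
        g = go * self._mask
        del self._mask
        return g


class _Sequential:
    def __init__(self, layers: list) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class ConvBlock:
    """Residual convolution block: an entry conv changes the channel count,
    the remaining convs are wrapped in an identity skip (V-Net style)."""

    def __init__(self, cin: int, cout: int, n_convs: int, rng: np.random.Generator) -> None:
        self.entry = _Sequential([Conv3x3(cin, cout, rng), InstanceNorm(cout), ReLU()])
        tail = []
        for _ in range(max(0, n_convs - 1)):
            tail += [Conv3x3(cout, cout, rng), InstanceNorm(cout), ReLU()]
        self.tail = _Sequential(tail) if tail else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.entry.forward(x)
        if self.tail is None:
            return y
        return y + self.tail.forward(y)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.tail is not None:
            g = g + self.tail.backward(g)
        return self.entry.backward(g)

    @property
    def layers(self) -> list:
        return self.entry.layers + (self.tail.layers if self.tail else [])


class VNet:
    """Encoder-decoder with skip concatenation and four-class logits output."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = [spec.base_filters * 2**s for s in range(spec.n_stages)]
        n_convs = [min(s + 1, 3) for s in range(spec.n_stages)]

        self.enc = [ConvBlock(spec.in_channels, f[0], n_convs[0], rng)]
        self.down = []
        for s in range(spec.n_stages - 1):
            self.down.append(_Sequential([DownConv(f[s], f[s + 1], rng), InstanceNorm(f[s + 1]), ReLU()]))
            self.enc.append(ConvBlock(f[s + 1], f[s + 1], n_convs[s + 1], rng))
        self.up = []
        self.dec = []
        for s in reversed(range(spec.n_stages - 1)):
            self.up.append(_Sequential([UpConv(f[s + 1], f[s], rng), InstanceNorm(f[s]), ReLU()]))
            self.dec.append(ConvBlock(2 * f[s], f[s], n_convs[s], rng))
        self.head = Conv1(f[0], spec.n_classes, rng)

    # -- parameter bookkeeping ------------------------------------------------

    def _all_layers(self) -> list[_Layer]:
        out: list[_Layer] = []
        for block in self.enc:
            out += block.layers
        for seq in self.down + self.up:
            out += seq.layers
        for block in self.dec:
            out += block.layers
        out.append(self.head)
        return [layer for layer in out if isinstance(layer, _Layer)]

    def parameters(self) -> list[tuple[_Layer, str]]:
        return [(layer, name) for layer in self._all_layers() for name in layer.params]

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def zero_grad(self) -> None:
        for layer in self._all_layers():
            layer.zero_grad()

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (layer, name), w in zip(self.parameters(), weights):
            layer.params[name] = w.astype(np.float32).copy()

    # -- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits ``(n_classes, D, H, W)`` for one input sample ``(C, D, H, W)``."""
        x = np.asarray(x, dtype=self.head.params["w"].dtype)
        if x.shape[0] != self.spec.in_channels:
            raise ValueError(
                f"input has {x.shape[0]} channels, model expects {self.spec.in_channels}"
            )
        self.spec.validate_shape(x.shape[1:])
        skips = []
        h = self.enc[0].forward(x)
        for s in range(self.spec.n_stages - 1):
            skips.append(h)
            h = self.down[s].forward(h)
            h = self.enc[s + 1].forward(h)
        self._skip_channels = [sk.shape[0] for sk in skips]
        for i, s in enumerate(reversed(range(self.spec.n_stages - 1))):
            h = self.up[i].forward(h)
            h = np.concatenate([h, skips[s]], axis=0)
            h = self.dec[i].forward(h)
        return self.head.forward(h)

    def backward(self, g_logits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        g = self.head.backward(g_logits.astype(np.float32))
        skip_grads: dict[int, np.ndarray] = {}
        stages = list(reversed(range(self.spec.n_stages - 1)))
        for i in reversed(range(len(self.dec))):
            s = stages[i]
            g = self.dec[i].backward(g)
            c_up = g.shape[0] - self._skip_channels[s]
            g, g_skip = g[: -self._skip_channels[s]], g[-self._skip_channels[s]:]
            assert g.shape[0] == c_up
            skip_grads[s] = g_skip
            g = self.up[i].backward(g)
        for s in reversed(range(self.spec.n_stages - 1)):
            g = self.enc[s + 1].backward(g)
            g = self.down[s].backward(g)
            g = g + skip_grads[s]
        self.enc[0].backward(g)


def build_model(spec: ModelSpec, seed: int = 0) -> VNet:
    return VNet(spec, seed=seed)


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def forward_probs(model: VNet, stack) -> np.ndarray:
    """Per-voxel class probabilities ``(n_classes, D, H, W)`` for a channel stack."""
    channels = stack.channels if hasattr(stack, "channels") else np.asarray(stack)
    if channels.shape[0] != model.spec.in_channels:
        raise ValueError(
            f"stack has {channels.shape[0]} channels, model expects {model.spec.in_channels}"
        )
    return softmax(model.forward(channels), axis=0)


def save_checkpoint(model: VNet, path) -> None:
    """Single-file checkpoint with the ModelSpec embedded."""
    arrays = {f"p{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, spec=json.dumps(asdict(model.spec)), **arrays)


def load_checkpoint(path) -> VNet:
    data = np.load(path, allow_pickle=False)
    spec = ModelSpec(**json.loads(str(data["spec"])))
    model = VNet(spec)
    n = len(model.get_weights())
    model.set_weights([data[f"p{i}"] for i in range(n)])
    return model
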