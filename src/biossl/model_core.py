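"""Network assembly, forward pass with activation caching, checkpoints.

A network is an ordered list of :class:`LayerSpec`. Trainable layers
(``conv``, ``linear``) own a forward weight block ``W`` and an independently
initialised feedback block ``B`` (used by the random-feedback rules; plain
backprop reads the transpose of ``W`` instead). The final layer must apply
no nonlinearity: the top of the network is a linear projection into the
embedding space where the contrastive loss operates.

Parameter reads go through :meth:`Network.W` / :meth:`Network.B` so tests
can assert locality contracts ("updating layer l never reads the weights of
layer l+1") via :meth:`Network.trace_access`.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ops
from .ops import NumericError

TRAINABLE_KINDS = ("conv", "linear")
POOL_KINDS = ("maxpool", "avgpool")


class ConfigurationError(ValueError):
    """Raised when a network or run configuration is inconsistent."""


@dataclass
class LayerSpec:
    kind: str  # conv | linear | maxpool | avgpool | flatten
    activation: str = "none"  # none | hardtanh | tanh
    channels_out: int = 0  # conv channels or linear width
    kernel: int = 3
    stride: int = 1
    pool_size: int = 2

    def __post_init__(self):
        if self.kind not in ("conv", "linear", "maxpool", "avgpool", "flatten"):
            raise ConfigurationError(f"unknown layer kind {self.kind!r}")
        if self.activation not in ("none", "hardtanh", "tanh"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")
        if self.kind == "conv" and (self.kernel < 1 or self.stride < 1):
            raise ConfigurationError("conv kernel and stride must be >= 1")
        if self.kind in POOL_KINDS and self.pool_size < 1:
            raise ConfigurationError("pool_size must be >= 1")

    @property
    def trainable(self) -> bool:
        return self.kind in TRAINABLE_KINDS


@dataclass
class Trace:
    """Cached pre-activations ``h`` and post-activations ``x`` per layer.

    ``x_in`` is the activation entering layer ``start`` (the raw input when
    ``start == 0``). ``pool_idx`` caches max-pool argmax positions for the
    backward routing.
    """

    start: int
    stop: int
    x_in: np.ndarray
    h: dict = field(default_factory=dict)
    x: dict = field(default_factory=dict)
    pool_idx: dict = field(default_factory=dict)
    in_shapes: dict = field(default_factory=dict)

    def input_to(self, l: int) -> np.ndarray:
        """Activation entering layer ``l``."""
        return self.x_in if l == self.start else self.x[l - 1]

    @property
    def output(self) -> np.ndarray:
        return self.x[self.stop - 1] if self.stop > self.start else self.x_in


def _uniform_init(rng: np.random.Generator, shape, fan_in: int, dtype):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Network:
    """Feed-forward convolutional network with explicit parameter blocks."""

    def __init__(self, specs, input_shape, seed: int = 0, dtype=np.float32):
        self.specs = list(specs)
        self.input_shape = tuple(input_shape)
        self.seed = int(seed)
        self.dtype = dtype
        self.L = len(self.specs)
        if not self.specs:
            raise ConfigurationError("network needs at least one layer")
        if self.specs[-1].activation != "none":
            raise ConfigurationError(
                "top layer must apply no nonlinearity (activation 'none')"
            )
        self.shapes = self._infer_shapes()
        self._init_params()
        self._access_log: list | None = None
        self._access_mark = None

    # -- construction -------------------------------------------------

    def _infer_shapes(self):
        shapes = []
        cur = self.input_shape
        for l, s in enumerate(self.specs):
            name = f"layer {l} ({s.kind})"
            prev = f"layer {l-1}" if l else "input"
            if s.kind == "conv":
                if len(cur) != 3:
                    raise ConfigurationError(
                        f"{name} needs a (C,H,W) input but {prev} produces {cur}"
                    )
                c, h, w = cur
                pad = (s.kernel - 1) // 2
                oh = (h + 2 * pad - s.kernel) // s.stride + 1
                ow = (w + 2 * pad - s.kernel) // s.stride + 1
                if oh < 1 or ow < 1:
                    raise ConfigurationError(
                        f"{name} kernel {s.kernel} does not fit the {h}x{w} "
                        f"output of {prev}"
                    )
                cur = (s.channels_out, oh, ow)
            elif s.kind in POOL_KINDS:
                if len(cur) != 3:
                    raise ConfigurationError(
                        f"{name} needs a (C,H,W) input but {prev} produces {cur}"
                    )
                c, h, w = cur
                if h // s.pool_size < 1 or w // s.pool_size < 1:
                    raise ConfigurationError(
                        f"{name} pool {s.pool_size} larger than the {h}x{w} "
                        f"output of {prev}"
                    )
                cur = (c, h // s.pool_size, w // s.pool_size)
            elif s.kind == "flatten":
                cur = (int(np.prod(cur)),)
            elif s.kind == "linear":
                if len(cur) != 1:
                    raise ConfigurationError(
                        f"{name} needs a flat input but {prev} produces {cur}; "
                        "insert a flatten layer"
                    )
                cur = (s.channels_out,)
            shapes.append(cur)
        return shapes

    def _init_params(self):
        rng_w = np.random.default_rng([self.seed, 1])
        rng_b = np.random.default_rng([self.seed, 2])  # independent of W
        self.params: dict[int, np.ndarray] = {}
        self.feedback: dict[int, np.ndarray] = {}
        for l, s in enumerate(self.specs):
            if not s.trainable:
                continue
            in_shape = self.input_shape if l == 0 else self.shapes[l - 1]
            if s.kind == "conv":
                ci = in_shape[0]
                shape = (s.channels_out, ci, s.kernel, s.kernel)
                fan_in = ci * s.kernel * s.kernel
                self.params[l] = _uniform_init(rng_w, shape, fan_in, self.dtype)
                self.feedback[l] = _uniform_init(rng_b, shape, fan_in, self.dtype)
            else:  # linear
                fan_in = in_shape[0]
                self.params[l] = _uniform_init(
                    rng_w, (s.channels_out, fan_in), fan_in, self.dtype
                )
                # feedback block has the transposed shape of W
                self.feedback[l] = _uniform_init(
                    rng_b, (fan_in, s.channels_out), fan_in, self.dtype
                )

    # -- parameter access with optional tracing ------------------------

    @contextmanager
    def trace_access(self):
        """Record every parameter read as ``(mark, layer, block)`` tuples."""
        self._access_log = []
        try:
            yield self._access_log
        finally:
            self._access_log = None
            self._access_mark = None

    def access_mark(self, label) -> None:
        self._access_mark = label

    def W(self, l: int) -> np.ndarray:
        if self._access_log is not None:
            self._access_log.append((self._access_mark, l, "W"))
        return self.params[l]

    def B(self, l: int) -> np.ndarray:
        if self._access_log is not None:
            self._access_log.append((self._access_mark, l, "B"))
        return self.feedback[l]

    # -- forward -------------------------------------------------------

    def forward(self, x: np.ndarray, start: int = 0, stop: int | None = None) -> Trace:
        """Run layers ``start .. stop-1`` on ``x``, caching all activations."""
        stop = self.L if stop is None else stop
        x = np.asarray(x, dtype=self.dtype)
        if start == 0:
            if x.shape[1:] != self.input_shape:
                raise ConfigurationError(
                    f"batch shape {x.shape[1:]} does not match the configured "
                    f"input {self.input_shape}"
                )
        tr = Trace(start=start, stop=stop, x_in=x)
        cur = x
        for l in range(start, stop):
            s = self.specs[l]
            tr.in_shapes[l] = cur.shape
            if s.kind == "conv":
                h = ops.conv2d(cur, self.W(l), stride=s.stride)
            elif s.kind == "maxpool":
                h, idx = ops.maxpool(cur, s.pool_size)
                tr.pool_idx[l] = idx
            elif s.kind == "avgpool":
                h = ops.avgpool(cur, s.pool_size)
            elif s.kind == "flatten":
                h = cur.reshape(cur.shape[0], -1)
            else:  # linear
                h = cur @ self.W(l).T
            if s.trainable and not np.all(np.isfinite(h)):
                raise NumericError(f"non-finite activations at layer {l} ({s.kind})")
            xl = ops.activate(h, s.activation)
            tr.h[l] = h
            tr.x[l] = xl
            cur = xl
        return tr

    # -- conveniences ---------------------------------------------------

    @property
    def trainable_layers(self):
        return [l for l, s in enumerate(self.specs) if s.trainable]

    def flatten_index(self) -> int | None:
        for l, s in enumerate(self.specs):
            if s.kind == "flatten":
                return l
        return None

    def checksums(self) -> dict:
        out = {}
        for l in self.trainable_layers:
            out[("W", l)] = float(np.sum(self.params[l].astype(np.float64) ** 2))
            out[("B", l)] = float(np.sum(self.feedback[l].astype(np.float64) ** 2))
        return out

    def copy(self) -> "Network":
        net = Network(self.specs, self.input_shape, self.seed, self.dtype)
        for l in self.params:
            net.params[l] = self.params[l].copy()
            net.feedback[l] = self.feedback[l].copy()
        return net


def conv_stages(net: Network):
    """Group layers into trainable stages: each conv together with the
    pool/activation layers that follow it, plus a final head stage
    (flatten + linear) when present.

    Returns a list of ``(start, stop)`` half-open layer ranges.
    """
    stages = []
    l = 0
    while l < net.L:
        s = net.specs[l]
        if s.kind == "conv":
            j = l + 1
            while j < net.L and net.specs[j].kind in POOL_KINDS:
                j += 1
            stages.append((l, j))
            l = j
        elif s.kind == "flatten":
            stages.append((l, net.L))
            break
        elif s.kind == "linear":
            stages.append((l, l + 1))
            l += 1
        else:
            # leading pools without a preceding conv: attach to next stage
            stages.append((l, l + 1))
            l += 1
    return stages


# ---------------------------------------------------------------------------
# embeddings

def embed(net: Network, batch: np.ndarray, strip_head: bool = False) -> np.ndarray:
    """Embed a batch of images.

    With ``strip_head`` the projection head is removed and the flattened
    output of the last convolutional block is returned; otherwise the
    projection-head output.
    """
    tr = net.forward(batch)
    if strip_head:
        fi = net.flatten_index()
        if fi is not None:
            return tr.x[fi]
        # no explicit flatten: flatten the last non-linear layer's output
        last_conv = max(
            (l for l, s in enumerate(net.specs) if s.kind != "linear"), default=None
        )
        if last_conv is not None:
            out = tr.x[last_conv]
            return out.reshape(out.shape[0], -1)
    return tr.output


# ---------------------------------------------------------------------------
# declarative configs and checkpoints

def build_network(config: dict, seed: int = 0, dtype=np.float32) -> Network:
    """Build a network from a declarative config.

    ``config`` holds ``input_shape: [C, H, W]`` and ``layers``, a list of
    dicts such as ``{kind: conv, channels: 32, kernel: 3, stride: 1,
    activation: hardtanh}``.
    """
    try:
        input_shape = tuple(int(v) for v in config["input_shape"])
        layer_cfgs = config["layers"]
    except KeyError as e:
        raise ConfigurationError(f"config missing key {e}") from None
    specs = []
    for lc in layer_cfgs:
        lc = dict(lc)
        kind = lc.pop("kind")
        spec = LayerSpec(
            kind=kind,
            activation=lc.pop("activation", "none"),
            channels_out=int(lc.pop("channels", lc.pop("width", 0) or 0)),
            kernel=int(lc.pop("kernel", 3)),
            stride=int(lc.pop("stride", 1)),
            pool_size=int(lc.pop("pool_size", lc.pop("size", 2) or 2)),
        )
        if lc:
            raise ConfigurationError(f"unknown layer options {sorted(lc)}")
        specs.append(spec)
    return Network(specs, input_shape, seed=seed, dtype=dtype)


def save_checkpoint(net: Network, path, provenance: dict | None = None) -> None:
    """Write all parameter blocks plus a JSON manifest next to them."""
    path = Path(path)
    arrays = {}
    for l in net.trainable_layers:
        arrays[f"W_{l}"] = net.params[l]
        arrays[f"B_{l}"] = net.feedback[l]
    np.savez(path, **arrays)
    manifest = {
        "input_shape": list(net.input_shape),
        "seed": net.seed,
        "dtype": np.dtype(net.dtype).name,
        "layers": [vars(s) for s in net.specs],
        "provenance": provenance or {},
    }
    npz = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    npz.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path) -> Network:
    path = Path(path)
    npz = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    manifest = json.loads(npz.with_suffix(".manifest.json").read_text())
    specs = [LayerSpec(**d) for d in manifest["layers"]]
    net = Network(
        specs,
        tuple(manifest["input_shape"]),
        seed=manifest["seed"],
        dtype=np.dtype(manifest["dtype"]),
    )
    data = np.load(npz)
    for l in net.trainable_layers:
        net.params[l] = data[f"W_{l}"]
        net.feedback[l] = data[f"B_{l}"]
    return net
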