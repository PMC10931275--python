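"""The 3D-CNN quality grader: declarative configuration and construction.

The classifier maps a single-channel 3D volume to five independent
sigmoid scores, one per ordinal quality grade. The default architecture
is four convolutional stages with 16/32/64/125 channels, two 2x2x2 max
pools (after stages 2 and 3), a global average pool, and a fully
connected head of 50/25/5 units interleaved with 12.5% dropout; the final
5-unit layer is sigmoid-activated. This realizes roughly 100k trainable
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .layers import (
    Conv3D,
    Dense,
    Dropout,
    Flatten,
    GlobalAvgPool3D,
    Layer,
    MaxPool3D,
    ReLU,
    Sigmoid,
)

__all__ = [
    "NetworkConfig",
    "ModelSummary",
    "Model",
    "build_network",
    "count_parameters",
    "first_layer_responses",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Declarative description of the grader architecture.

    ``conv_channels`` lists the four stage widths; ``kernel_sizes`` the
    per-stage 3D kernel dims; ``pool_after`` the (1-indexed) stages that a
    2x2x2 max pool follows. ``global_pool_before_head`` selects a global
    average pool between the conv trunk and the head (the default); set
    it False for a literal flatten, which costs far more head parameters.
    """

    input_shape: tuple[int, int, int] = (24, 48, 48)
    conv_channels: tuple[int, int, int, int] = (16, 32, 64, 125)
    kernel_sizes: tuple[tuple[int, int, int], ...] = (
        (3, 3, 3), (3, 3, 3), (2, 2, 2), (2, 2, 2)
    )
    pool_after: tuple[int, int] = (2, 3)
    head_widths: tuple[int, int, int] = (50, 25, 5)
    dropout_rate: float = 0.125
    n_classes: int = 5
    global_pool_before_head: bool = True
    conv1_init: str = "derivative_bank"  # or "random"
    init_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 4:
            raise ValueError("exactly 4 convolutional stages are required")
        if len(self.kernel_sizes) != 4:
            raise ValueError("need one kernel size per conv stage")
        if len(self.pool_after) != 2:
            raise ValueError("exactly 2 pooling layers are required")
        if self.head_widths[-1] != self.n_classes:
            raise ValueError("last head width must equal n_classes")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        raw = json.loads(text)
        for key in ("input_shape", "conv_channels", "pool_after", "head_widths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "kernel_sizes" in raw:
            raw["kernel_sizes"] = tuple(tuple(k) for k in raw["kernel_sizes"])
        return cls(**raw)


@dataclass
class ModelSummary:
    n_parameters: int
    per_layer: list[tuple[str, str, int]] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [f"{'layer':<12} {'shape':<24} {'params':>8}"]
        for name, shape, count in self.per_layer:
            lines.append(f"{name:<12} {shape:<24} {count:>8}")
        lines.append(f"{'total':<12} {'':<24} {self.n_parameters:>8}")
        return "\n".join(lines)


class Model:
    """A sequential stack of layers with parameter access by flat list.

    Public input layout is (batch, channels, depth, height, width); feature
    maps run channels-last internally.
    """

    def __init__(self, layers: list[Layer], config: NetworkConfig):
        self.layers = layers
        self.config = config

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(np.moveaxis(x, 1, -1), dtype=np.float32)
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params.values())
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.grads.values())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError(
                f"weight count mismatch: model has {len(params)} arrays, "
                f"got {len(weights)}"
            )
        for i, (p, w) in enumerate(zip(params, weights)):
            if p.shape != w.shape:
                name = self._param_names()[i]
                raise ValueError(
                    f"shape mismatch at {name}: model {p.shape} vs weights {w.shape}"
                )
            p[...] = w

    def _param_names(self) -> list[str]:
        names = []
        for layer in self.layers:
            for key in layer.params:
                names.append(f"{layer.name}.{key}")
        return names

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng


def _derivative_bank(
    k: tuple[int, int, int], cout: int, rng: np.random.Generator
) -> np.ndarray:
    """Oriented derivative filters for the first layer, (kd,kh,kw,1,cout).

    Motion smearing is directional, and trained graders converge to edge
    and boundary detectors in their first layer; seeding that layer with a
    bank of first/second directional derivatives under a Gaussian envelope
    (plus a low-pass and small symmetry-breaking noise) gives the same
    representation without spending scarce update steps discovering it.
    Each filter is scaled to the L2 norm that fan-in-scaled random init
    would have in expectation.
    """
    grids = np.meshgrid(
        *[np.arange(d) - (d - 1) / 2.0 for d in k], indexing="ij"
    )
    envelope = np.exp(-0.5 * sum(g**2 for g in grids))
    dirs = []
    for v in ((1, 0, 0), (0, 1, 0), (0, 0, 1),
              (1, 1, 0), (1, -1, 0), (1, 0, 1),
              (1, 0, -1), (0, 1, 1), (0, 1, -1),
              (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)):
        dirs.append(np.array(v, dtype=float) / np.linalg.norm(v))
    filters = []
    for i in range(cout):
        if i < len(dirs):  # first directional derivatives
            u = dirs[i]
            f = (grids[0] * u[0] + grids[1] * u[1] + grids[2] * u[2]) * envelope
        elif i < len(dirs) + 2:  # second directional derivatives
            u = dirs[i - len(dirs)]
            p = grids[0] * u[0] + grids[1] * u[1] + grids[2] * u[2]
            f = (p**2) * envelope
            f = f - f.mean()
        else:  # low-pass
            f = envelope.copy()
        f = f / np.linalg.norm(f) * np.sqrt(2.0)
        f = f + rng.normal(0.0, 0.05, f.shape)
        filters.append(f)
    bank = np.stack(filters, axis=-1)[..., None, :]  # (kd,kh,kw,1,cout)
    return bank.astype(np.float32)


def config_uses_bank(cfg: NetworkConfig) -> bool:
    if cfg.conv1_init not in ("derivative_bank", "random"):
        raise ValueError(f"unknown conv1_init {cfg.conv1_init!r}")
    return cfg.conv1_init == "derivative_bank"


def build_network(config: NetworkConfig | None = None) -> Model:
    """Instantiate the grader from a config, validating stage geometry."""
    cfg = config or NetworkConfig()
    rng = np.random.default_rng(cfg.init_seed)
    layers: list[Layer] = []
    shape: tuple[int, ...] = (*cfg.input_shape, 1)  # channels-last
    cin = 1
    for stage, (cout, k) in enumerate(zip(cfg.conv_channels, cfg.kernel_sizes), start=1):
        conv = Conv3D(cin, cout, k, rng=rng, name=f"conv{stage}",
                      skip_input_grad=(stage == 1))
        if stage == 1 and cin == 1 and config_uses_bank(cfg):
            conv.W = _derivative_bank(k, cout, rng)
        try:
            shape = conv.out_shape(shape)
        except ValueError as exc:
            raise ValueError(f"geometry underflow at stage {stage}: {exc}") from exc
        layers.append(conv)
        layers.append(ReLU(name=f"relu{stage}"))
        if stage in cfg.pool_after:
            pool = MaxPool3D(name=f"pool{stage}")
            try:
                shape = pool.out_shape(shape)
            except ValueError as exc:
                raise ValueError(f"geometry underflow at stage {stage}: {exc}") from exc
            layers.append(pool)
        cin = cout
    if cfg.global_pool_before_head:
        gap = GlobalAvgPool3D()
        shape = gap.out_shape(shape)
        layers.append(gap)
    else:
        flat = Flatten()
        shape = flat.out_shape(shape)
        layers.append(flat)
    n_in = shape[-1] if len(shape) > 1 else shape[0]
    w50, w25, w5 = cfg.head_widths
    layers.append(Dense(n_in, w50, rng=rng, name="fc1"))
    layers.append(ReLU(name="relu_fc1"))
    layers.append(Dropout(cfg.dropout_rate, name="drop1"))
    layers.append(Dense(w50, w25, rng=rng, name="fc2"))
    layers.append(ReLU(name="relu_fc2"))
    layers.append(Dropout(cfg.dropout_rate, name="drop2"))
    layers.append(Dense(w25, w5, rng=rng, name="fc3"))
    layers.append(Sigmoid(name="out"))
    return Model(layers, cfg)


def count_parameters(model: Model) -> ModelSummary:
    """Exact trainable-parameter count, per layer and total."""
    per_layer: list[tuple[str, str, int]] = []
    total = 0
    for layer in model.layers:
        for key, p in layer.params.items():
            count = int(p.size)
            per_layer.append((f"{layer.name}.{key}", str(p.shape), count))
            total += count
    return ModelSummary(n_parameters=total, per_layer=per_layer)


def first_layer_responses(model: Model, volume_data: np.ndarray) -> list[np.ndarray]:
    """Response maps of the first convolutional stage's filters.

    Returns one 3D array per filter; these are what the network "sees"
    first — after training they typically act as edge and boundary
    detectors on the cortical shell and trabeculae.
    """
    conv1 = next(l for l in model.layers if isinstance(l, Conv3D))
    x = np.asarray(volume_data, dtype=np.float32)[None, ..., None]
    y = conv1.forward(x, train=False)[0]  # (D', H', W', C)
    return [np.ascontiguousarray(y[..., c]) for c in range(y.shape[-1])]


def save_weights(weights: list[np.ndarray], path: str) -> None:
    np.savez(path if path.endswith(".npz") else path + ".npz",
             **{f"arr{i}": w for i, w in enumerate(weights)})


def load_weights(path: str) -> list[np.ndarray]:
    with np.load(path) as data:
        return [data[f"arr{i}"] for i in range(len(data.files))]
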