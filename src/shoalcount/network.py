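"""The hybrid counting network: multi-column front end + dilated back end.

Architecture
------------
Three parallel convolutional columns with different kernel-size ladders
(large / medium / small receptive fields) each downsample the input by 8
via three 2x2 stride-2 max-pool operations; their feature maps — spatially
aligned because every column uses "same" padding and stride 1 — are fused
by channel concatenation.  A deeper, wider back end of 3x3 convolutions
with dilation rate 2 aggregates context without further resolution loss,
and a 1x1 convolution (not a fully-connected layer, so any input size
works) produces the single-channel density map at 1/8 of the input
resolution.  Every convolution is followed by a ReLU; the head's ReLU
guarantees a nonnegative density whose sum is the estimated count.

Dilated convolutions trade pooling for receptive field: a k x k kernel at
dilation rate r covers ``k*r - r + 1`` pixels per side while still touching
only k^2 input positions.  :func:`effective_kernel_size` and
:func:`dilated_kernel_footprint` expose that arithmetic, and because the
network is plain NumPy the same numbers can be verified empirically from
the input-gradient footprint of a single output unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from ._nn import Adam, Conv2D, maxpool2, maxpool2_backward, relu, relu_backward
from .density import DensityMap

__all__ = [
    "ConvLayerSpec",
    "ColumnSpec",
    "HybridConfig",
    "HybridModel",
    "effective_kernel_size",
    "dilated_kernel_footprint",
    "default_config",
    "reduced_config",
    "build",
    "predict_density",
    "save_model",
    "load_model",
]

DOWNSAMPLE = 8  # three 2x2 pools per column


def effective_kernel_size(k: int, r: int) -> int:
    """Side length of the receptive field of a k x k kernel at dilation r.

    The taps of a dilated kernel sit r pixels apart, so the bounding box
    spans k*r - r + 1 pixels per side; with r = 1 this is the ordinary k.
    """
    if k < 1 or k % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    if r < 1:
        raise ValueError("dilation rate must be >= 1")
    return k * r - r + 1


def dilated_kernel_footprint(k: int, r: int) -> set[tuple[int, int]]:
    """The k^2 tap offsets {(i*r, j*r)} of a dilated kernel.

    Only these positions carry nonzero weight; the rest of the
    effective_kernel_size(k, r) box is skipped.
    """
    effective_kernel_size(k, r)  # validates k, r
    return {(i * r, j * r) for i in range(k) for j in range(k)}


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolution: "(kernel size)-(number of filters)-(dilation rate)"."""

    kernel_size: int
    filters: int
    dilation_rate: int = 1

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 1")
        if self.filters < 1 or self.dilation_rate < 1:
            raise ValueError("filters and dilation_rate must be >= 1")


@dataclass(frozen=True)
class ColumnSpec:
    """A front-end column: conv layers with 2x2 max pools after some of them."""

    layers: tuple[ConvLayerSpec, ...]
    pool_after: frozenset[int] = frozenset({0, 1, 2})

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        object.__setattr__(self, "pool_after", frozenset(self.pool_after))
        if len(self.pool_after) != 3:
            raise ValueError("each column must contain exactly three pooling operations")
        if any(i < 0 or i >= len(self.layers) for i in self.pool_after):
            raise ValueError("pool_after indices out of range")


# kernel-size ladders and filter widths of the three-column front end,
# following the multi-column counting network this model extends
_FRONT_KERNELS = ((9, 7, 7, 7), (7, 5, 5, 5), (5, 3, 3, 3))
_FRONT_FILTERS = ((16, 32, 16, 8), (20, 40, 20, 10), (24, 48, 24, 12))
_BACKEND_FILTERS = (64, 64, 64, 32, 32, 16)


@dataclass(frozen=True)
class HybridConfig:
    """Structural description of the full model."""

    columns: tuple[ColumnSpec, ColumnSpec, ColumnSpec]
    backend: tuple[ConvLayerSpec, ...]
    head: ConvLayerSpec = ConvLayerSpec(kernel_size=1, filters=1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", tuple(self.columns))
        object.__setattr__(self, "backend", tuple(self.backend))
        if len(self.columns) != 3:
            raise ValueError("the front end has exactly three columns")
        for spec in self.backend:
            if spec.kernel_size != 3 or spec.dilation_rate != 2:
                raise ValueError("backend kernels are 3 x 3 with dilation rate 2")
        if self.head.filters != 1 or self.head.kernel_size != 1:
            raise ValueError("head is a 1 x 1 convolution to one channel")

    def to_dict(self) -> dict:
        return {
            "columns": [
                {
                    "layers": [
                        [s.kernel_size, s.filters, s.dilation_rate] for s in col.layers
                    ],
                    "pool_after": sorted(col.pool_after),
                }
                for col in self.columns
            ],
            "backend": [[s.kernel_size, s.filters, s.dilation_rate] for s in self.backend],
        }

    @staticmethod
    def from_dict(d: dict) -> "HybridConfig":
        cols = tuple(
            ColumnSpec(
                layers=tuple(ConvLayerSpec(*row) for row in col["layers"]),
                pool_after=frozenset(col["pool_after"]),
            )
            for col in d["columns"]
        )
        backend = tuple(ConvLayerSpec(*row) for row in d["backend"])
        return HybridConfig(columns=cols, backend=backend)


def default_config() -> HybridConfig:
    """The full-width model."""
    return reduced_config(1.0)


def reduced_config(width_scale: float = 0.25) -> HybridConfig:
    """Same topology with every filter count scaled (minimum 1 per layer).

    Useful for CPU-scale experiments; ``width_scale=1`` is the full model.
    """
    if width_scale <= 0:
        raise ValueError("width_scale must be positive")

    def w(n: int) -> int:
        return max(1, round(n * width_scale))

    columns = tuple(
        ColumnSpec(
            layers=tuple(
                ConvLayerSpec(k, w(f)) for k, f in zip(kernels, filters)
            ),
            pool_after=frozenset({0, 1, 2}),
        )
        for kernels, filters in zip(_FRONT_KERNELS, _FRONT_FILTERS)
    )
    backend = tuple(
        ConvLayerSpec(3, w(f), dilation_rate=2) for f in _BACKEND_FILTERS
    )
    return HybridConfig(columns=columns, backend=backend)


class HybridModel:
    """A built (possibly trained) hybrid model; construct via :func:`build`."""

    downsample_factor = DOWNSAMPLE

    def __init__(
        self, config: HybridConfig, seed: int = 0, init_std: float | str = 0.01
    ) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        self.columns: list[list[Conv2D]] = []
        fused_channels = 0
        for col in config.columns:
            layers = []
            in_ch = 3
            for spec in col.layers:
                layers.append(
                    Conv2D(in_ch, spec.filters, spec.kernel_size, spec.dilation_rate, rng, init_std)
                )
                in_ch = spec.filters
            self.columns.append(layers)
            fused_channels += in_ch
        self.backend: list[Conv2D] = []
        in_ch = fused_channels
        for spec in config.backend:
            self.backend.append(
                Conv2D(in_ch, spec.filters, spec.kernel_size, spec.dilation_rate, rng, init_std)
            )
            in_ch = spec.filters
        self.head = Conv2D(in_ch, 1, 1, 1, rng, init_std)
        # the head's inputs are post-ReLU (nonnegative), so nonnegative head
        # weights keep the rectified output in its linear region at init --
        # otherwise an unlucky draw can make every density zero with zero
        # gradient, and the head never recovers
        self.head.w = np.abs(self.head.w)

    # -- parameter plumbing -------------------------------------------------

    def _layers(self) -> list[Conv2D]:
        return [l for col in self.columns for l in col] + self.backend + [self.head]

    def params(self) -> list[np.ndarray]:
        return [p for layer in self._layers() for p in layer.params()]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (H, W, 3) float in [0, 1], H and W divisible by 8.

        Returns the (H/8, W/8) density grid, plus a cache when training.
        """
        h, w, _ = x.shape
        if h % DOWNSAMPLE or w % DOWNSAMPLE:
            raise ValueError(f"input sides must be divisible by {DOWNSAMPLE}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        cache: dict = {"columns": []}
        feats = []
        for col_spec, layers in zip(self.config.columns, self.columns):
            t = x
            col_cache = []
            for i, layer in enumerate(layers):
                t, conv_c = layer.forward(t)
                t, relu_c = relu(t)
                pool_c = None
                if i in col_spec.pool_after:
                    t, pool_c = maxpool2(t)
                col_cache.append((conv_c, relu_c, pool_c))
            feats.append(t)
            cache["columns"].append(col_cache)
        fused = np.concatenate(feats, axis=2)
        cache["split"] = np.cumsum([f.shape[2] for f in feats])[:-1]
        t = fused
        back_cache = []
        for layer in self.backend:
            t, conv_c = layer.forward(t)
            t, relu_c = relu(t)
            back_cache.append((conv_c, relu_c))
        cache["backend"] = back_cache
        t, conv_c = self.head.forward(t)
        out, relu_c = relu(t)
        cache["head"] = (conv_c, relu_c)
        density = out[:, :, 0]
        if want_cache:
            return density, cache
        return density

    def backward(self, dout: np.ndarray, cache: dict) -> list[np.ndarray]:
        """Gradient of a scalar loss w.r.t. all parameters, given dLoss/dDensity."""
        grads: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        conv_c, relu_c = cache["head"]
        d = relu_backward(dout[:, :, None].astype(np.float32), relu_c)
        d, dw, db = self.head.backward(d, conv_c)
        grads[id(self.head)] = (dw, db)
        for layer, (conv_c, relu_c) in zip(reversed(self.backend), reversed(cache["backend"])):
            d = relu_backward(d, relu_c)
            d, dw, db = layer.backward(d, conv_c)
            grads[id(layer)] = (dw, db)
        parts = np.split(d, cache["split"], axis=2)
        for layers, col_cache, dcol in zip(self.columns, cache["columns"], parts):
            d = np.ascontiguousarray(dcol)
            for layer, (conv_c, relu_c, pool_c) in zip(reversed(layers), reversed(col_cache)):
                if pool_c is not None:
                    d = maxpool2_backward(d, pool_c)
                d = relu_backward(d, relu_c)
                d, dw, db = layer.backward(d, conv_c)
                grads[id(layer)] = (dw, db)
        out = []
        for layer in self._layers():
            dw, db = grads[id(layer)]
            out.extend([dw, db])
        return out

    def make_optimizer(self, lr: float = 1e-5) -> Adam:
        return Adam(self.params(), lr=lr)


def build(
    config: HybridConfig | None = None, seed: int = 0, init_std: float | str = 0.01
) -> HybridModel:
    """Construct a model, deterministic per seed.

    The default draws every convolution weight from N(0, 0.01), the
    counting model's published recipe.  ``init_std="he"`` selects
    variance-preserving initialization (std = sqrt(2 / fan_in)), which
    reaches useful accuracy in far fewer optimizer steps and is what the
    CPU-scale experiments use.
    """
    return HybridModel(config or default_config(), seed=seed, init_std=init_std)


def predict_density(model: HybridModel, image: np.ndarray) -> DensityMap:
    """Run the model on an 8-bit RGB image; density grid at 1/8 resolution.

    Sides not divisible by 8 are zero-padded bottom/right before the
    forward pass and the output is cropped to ceil(H/8) x ceil(W/8).
    """
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    if arr.max() > 1.5:  # 8-bit input: rescale to [0, 1]
        arr = arr / 255.0
    h, w, _ = arr.shape
    ph = (-h) % DOWNSAMPLE
    pw = (-w) % DOWNSAMPLE
    if ph or pw:
        arr = np.pad(arr, ((0, ph), (0, pw), (0, 0)))
    grid = model.forward(arr)
    grid = grid[: -(-h // DOWNSAMPLE), : -(-w // DOWNSAMPLE)]
    return DensityMap(np.asarray(grid, dtype=np.float64), scale=1.0 / DOWNSAMPLE)


def save_model(model: HybridModel, path) -> None:
    """Checkpoint: config (YAML) + all weight arrays in one .npz."""
    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    arrays["config_yaml"] = np.frombuffer(
        yaml.safe_dump(model.config.to_dict()).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> HybridModel:
    with np.load(path) as data:
        cfg = HybridConfig.from_dict(
            yaml.safe_load(bytes(data["config_yaml"]).decode())
        )
        model = HybridModel(cfg, seed=0)
        for i, p in enumerate(model.params()):
            p[...] = data[f"p{i}"]
    return model
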