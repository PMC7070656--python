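"""Training loop and counting-evaluation suite.

Training follows the recipe of the counting model: Adam at learning rate
1e-5, mean-squared error between predicted and ground-truth density maps,
batch size 1 (online learning), 100 epochs, weights initialized from
N(0, 0.01), with 10 % of the training set held out for validation.  The
ground-truth maps are rendered at full resolution and block-sum downsampled
by 8 to the network's output grid, which preserves the count exactly.

Evaluation reports, over per-image (estimate, truth) count pairs:

    MAE   = mean |z_i - z_i^GT|
    RMSE  = sqrt(mean (z_i - z_i^GT)^2)
    MAPE  = mean(100 * |z_i - z_i^GT| / z_i^GT)        [percent]
    Accuracy = 100 - MAPE                              [percent]

plus the Pearson correlation between estimates and truths, a per-image
signed error series with histogram, and per-range accuracy buckets
(<60, [60,100), [100,140), [140,180), >=180 fish).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from .density import DensityMap
from .network import HybridModel

__all__ = [
    "TrainConfig",
    "History",
    "MetricsReport",
    "RangeBucket",
    "density_mse",
    "evaluate",
    "range_report",
    "error_series",
    "train",
]

RANGE_EDGES = (60.0, 100.0, 140.0, 180.0)
RANGE_NAMES = ("Fewer", "Few", "Medium", "Many", "Large")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults mirror the counting model's recipe)."""

    learning_rate: float = 1e-5
    epochs: int = 100
    batch_size: int = 1
    validation_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in [0, 1)")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 (online learning) is supported")


@dataclass
class History:
    """Per-epoch training loss and validation counting metrics."""

    train_loss: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    val_mape: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    rmse: float
    mape: float  # percent
    accuracy: float  # percent, = 100 - mape
    pearson: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "mape": self.mape,
            "accuracy": self.accuracy,
            "pearson": self.pearson,
            "n": self.n,
        }


@dataclass(frozen=True)
class RangeBucket:
    name: str
    lower: float  # inclusive
    upper: float | None  # exclusive; None = open-ended
    n: int
    accuracy: float | None  # percent; None for an empty bucket


def density_mse(pred: DensityMap | np.ndarray, truth: DensityMap | np.ndarray) -> float:
    """Mean over cells of squared density differences (the training loss)."""
    a = pred.grid if isinstance(pred, DensityMap) else np.asarray(pred, dtype=np.float64)
    b = truth.grid if isinstance(truth, DensityMap) else np.asarray(truth, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"density map shapes differ: {a.shape} vs {b.shape}")
    diff = a.astype(np.float64) - b.astype(np.float64)
    return float(np.mean(diff * diff))


def _paired(estimates, truths) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(estimates, dtype=np.float64).ravel()
    zgt = np.asarray(truths, dtype=np.float64).ravel()
    if z.size != zgt.size:
        raise ValueError("estimates and truths must have equal length")
    if z.size == 0:
        raise ValueError("at least one (estimate, truth) pair is required")
    return z, zgt


def evaluate(estimates, truths) -> MetricsReport:
    """MAE, RMSE, MAPE, accuracy and Pearson over per-image count pairs."""
    z, zgt = _paired(estimates, truths)
    if np.any(zgt <= 0):
        raise ValueError("MAPE/accuracy require strictly positive ground-truth counts")
    err = z - zgt
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err * err)))
    mape = float(np.mean(100.0 * np.abs(err) / zgt))
    if z.size < 2 or np.ptp(z) == 0 or np.ptp(zgt) == 0:
        corr = 1.0 if np.allclose(z, zgt) else float("nan")
    else:
        corr = float(pearsonr(z, zgt).statistic)
    return MetricsReport(
        mae=mae, rmse=rmse, mape=mape, accuracy=100.0 - mape, pearson=corr, n=z.size
    )


def range_report(
    estimates, truths, edges: tuple[float, ...] = RANGE_EDGES
) -> list[RangeBucket]:
    """Per-range accuracy: buckets of truth counts with half-open intervals."""
    z, zgt = _paired(estimates, truths)
    if np.any(zgt <= 0):
        raise ValueError("per-range accuracy requires positive ground-truth counts")
    bounds = (float("-inf"),) + tuple(edges) + (float("inf"),)
    names = RANGE_NAMES if len(edges) == 4 else tuple(
        f"range{i}" for i in range(len(edges) + 1)
    )
    buckets = []
    for i, name in enumerate(names):
        lo, hi = bounds[i], bounds[i + 1]
        mask = (zgt >= lo) & (zgt < hi)
        n = int(mask.sum())
        acc = None
        if n:
            acc = 100.0 - float(np.mean(100.0 * np.abs(z[mask] - zgt[mask]) / zgt[mask]))
        buckets.append(
            RangeBucket(
                name=name,
                lower=0.0 if np.isinf(lo) else lo,
                upper=None if np.isinf(hi) else hi,
                n=n,
                accuracy=acc,
            )
        )
    return buckets


def error_series(
    estimates, truths, bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed per-image errors (estimate - truth) and their histogram.

    Returns (errors, hist_counts, bin_edges); bins cover the error range in
    steps of ``bin_width`` centred on zero.
    """
    z, zgt = _paired(estimates, truths)
    errors = z - zgt
    lim = max(bin_width, float(np.ceil(np.abs(errors).max() / bin_width)) * bin_width)
    edges = np.arange(-lim, lim + bin_width / 2, bin_width)
    hist, edges = np.histogram(errors, bins=edges)
    return errors, hist, edges


def _val_metrics(model: HybridModel, samples) -> tuple[float, float, float]:
    est, tru = [], []
    for x, gt in samples:
        pred = model.forward(x)
        est.append(float(pred.sum()))
        tru.append(float(gt.sum()))
    z = np.array(est)
    zgt = np.array(tru)
    err = z - zgt
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err * err)))
    with np.errstate(divide="ignore", invalid="ignore"):
        mape = float(np.mean(np.where(zgt > 0, 100.0 * np.abs(err) / zgt, np.nan)))
    return mae, rmse, mape


def train(
    model: HybridModel,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig | None = None,
) -> tuple[HybridModel, History]:
    """Online (batch-size-1) MSE training of the density regressor.

    ``dataset`` pairs each input image — (H, W, 3) float in [0, 1], sides
    divisible by 8 — with its ground-truth density grid at the model's
    output resolution (H/8, W/8).  The validation split is the last 10 %
    after a seeded shuffle.  Fully deterministic per config.seed.
    """
    config = config or TrainConfig()
    if not dataset:
        raise ValueError("dataset must be nonempty")
    for x, gt in dataset:
        eh = x.shape[0] // model.downsample_factor
        ew = x.shape[1] // model.downsample_factor
        if gt.shape != (eh, ew):
            raise ValueError(
                f"ground-truth grid {gt.shape} does not match model output ({eh}, {ew})"
            )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(dataset))
    n_val = int(round(config.validation_fraction * len(dataset)))
    val_idx = order[len(dataset) - n_val :]
    train_idx = order[: len(dataset) - n_val]
    if train_idx.size == 0:
        raise ValueError("validation split leaves no training samples")
    val_samples = [dataset[i] for i in val_idx]
    opt = model.make_optimizer(lr=config.learning_rate)
    history = History()
    for _ in range(config.epochs):
        epoch_losses = []
        for i in rng.permutation(train_idx):
            x, gt = dataset[i]
            pred, cache = model.forward(x, want_cache=True)
            diff = (pred - gt).astype(np.float32)
            epoch_losses.append(float(np.mean(diff**2)))
            dout = (2.0 / diff.size) * diff
            grads = model.backward(dout, cache)
            opt.step(grads)
        history.train_loss.append(float(np.mean(epoch_losses)))
        if val_samples:
            mae, rmse, mape = _val_metrics(model, val_samples)
        else:
            mae = rmse = mape = float("nan")
        history.val_mae.append(mae)
        history.val_rmse.append(rmse)
        history.val_mape.append(mape)
    return model, history
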