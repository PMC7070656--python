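"""Geometry-adaptive Gaussian density maps from point annotations.

A labelled image with N fish-center points is turned into a density map
F = sum_i G_{sigma_i}(. - x_i) whose integral equals N, the supervision
target for counting-by-regression.  The bandwidth of each point's kernel
adapts to local crowding: sigma_i = beta * dbar_i, where dbar_i is the mean
Euclidean distance from point i to its k nearest neighbouring points.  In a
shoal imaged in perspective, nearby fish are large and sparse (large dbar,
wide kernel) while distant fish are small and dense (small dbar, narrow
kernel), so the kernel width tracks apparent fish size without an explicit
perspective map.

Kernels are truncated at ``truncation_radius_sigmas * sigma`` and each
point's in-frame mass is renormalized to exactly 1, so the map's sum equals
the point count even for border-touching points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "AnnotationSet",
    "KernelParams",
    "DensityMap",
    "knn_mean_distance",
    "adaptive_sigmas",
    "render_density_map",
    "block_sum_downsample",
    "count_from_density",
    "read_annotations",
    "write_annotations",
]

#: sentinel mean-distance for a point with no neighbour (single-point image)
ISOLATED = float("nan")


@dataclass
class AnnotationSet:
    """Point annotations (one (x, y) per fish center) tied to one image.

    Coordinates are 0-based pixels, x = column, y = row.
    """

    image_id: str
    points: np.ndarray  # (N, 2) float array of (x, y)
    width: int
    height: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        self.points = pts
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        bad = (
            (pts[:, 0] < 0)
            | (pts[:, 0] >= self.width)
            | (pts[:, 1] < 0)
            | (pts[:, 1] >= self.height)
        )
        if bad.any():
            i = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"point {i} at ({pts[i, 0]}, {pts[i, 1]}) outside "
                f"{self.width} x {self.height} image '{self.image_id}'"
            )

    @property
    def count(self) -> int:
        return int(self.points.shape[0])


@dataclass(frozen=True)
class KernelParams:
    """Adaptive-kernel settings: sigma_i = beta * (mean distance to k nearest)."""

    beta: float = 0.3
    k_neighbors: int = 3
    truncation_radius_sigmas: float = 4.0
    fallback_sigma: float = 15.0

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.truncation_radius_sigmas <= 0 or self.fallback_sigma <= 0:
            raise ValueError("beta, truncation radius and fallback sigma must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class DensityMap:
    """Nonnegative grid whose sum is the (possibly fractional) object count.

    ``scale`` is the ratio of grid resolution to source-image resolution
    (1 for full resolution, 1/8 for the network's output grid).
    """

    grid: np.ndarray
    scale: float = 1.0
    image_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2:
            raise ValueError("density grid must be 2-D")


def knn_mean_distance(points: np.ndarray, k: int = 3) -> np.ndarray:
    """Mean Euclidean distance from each point to its k nearest other points.

    Fewer than k neighbours available: averages over all of them.  A point
    with no neighbour at all yields NaN (the isolated-point sentinel).
    Empty input yields an empty array.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    n = pts.shape[0]
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.array([ISOLATED])
    kk = min(k, n - 1)
    tree = cKDTree(pts)
    # first neighbour is the point itself at distance 0
    dists, _ = tree.query(pts, k=kk + 1)
    return dists[:, 1:].mean(axis=1)


def adaptive_sigmas(mean_distances: np.ndarray, params: KernelParams | None = None) -> np.ndarray:
    """sigma_i = beta * dbar_i; the isolated-point sentinel maps to fallback_sigma."""
    params = params or KernelParams()
    d = np.asarray(mean_distances, dtype=np.float64)
    if np.any(d[~np.isnan(d)] < 0):
        raise ValueError("mean distances must be nonnegative")
    sig = params.beta * d
    sig[np.isnan(d)] = params.fallback_sigma
    return sig


def render_density_map(
    annotations: AnnotationSet, params: KernelParams | None = None
) -> DensityMap:
    """Sum of per-point truncated, renormalized isotropic Gaussians.

    Each point contributes total in-frame mass exactly 1 (renormalized over
    the truncated window clipped to the image), so the grid sum equals the
    annotation count to machine precision.
    """
    params = params or KernelParams()
    h, w = annotations.height, annotations.width
    grid = np.zeros((h, w))
    pts = annotations.points
    if pts.shape[0] == 0:
        return DensityMap(grid, scale=1.0, image_id=annotations.image_id)
    sigmas = adaptive_sigmas(knn_mean_distance(pts, params.k_neighbors), params)
    for (x, y), sigma in zip(pts, sigmas):
        r = params.truncation_radius_sigmas * sigma
        x0, x1 = max(0, int(np.floor(x - r))), min(w - 1, int(np.ceil(x + r)))
        y0, y1 = max(0, int(np.floor(y - r))), min(h - 1, int(np.ceil(y + r)))
        xs = np.arange(x0, x1 + 1) - x
        ys = np.arange(y0, y1 + 1) - y
        d2 = ys[:, None] ** 2 + xs[None, :] ** 2
        patch = np.exp(-d2 / (2.0 * sigma**2))
        patch[d2 > r * r] = 0.0
        total = patch.sum()
        if total == 0.0:  # sub-pixel sigma: all mass on the nearest pixel
            grid[int(round(y)), int(round(x))] += 1.0
            continue
        grid[y0 : y1 + 1, x0 : x1 + 1] += patch / total
    return DensityMap(grid, scale=1.0, image_id=annotations.image_id)


def block_sum_downsample(density: DensityMap, factor: int) -> DensityMap:
    """Sum-pool the grid over factor x factor blocks, preserving total count.

    Dimensions not divisible by ``factor`` are zero-padded bottom/right
    first, which cannot change the sum.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return DensityMap(density.grid.copy(), density.scale, density.image_id)
    g = density.grid
    h, w = g.shape
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        g = np.pad(g, ((0, ph), (0, pw)))
    h, w = g.shape
    out = g.reshape(h // factor, factor, w // factor, factor).sum(axis=(1, 3))
    return DensityMap(out, density.scale / factor, density.image_id)


def count_from_density(density: DensityMap) -> float:
    """The count is the integral (grid sum) of the density map."""
    if np.any(density.grid < 0):
        raise ValueError("density map has negative entries")
    return float(density.grid.sum())


# --------------------------------------------------------------------------
# annotation I/O: CSV (image_id, x, y) or the same triples in JSON


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "image_id": annotations.image_id,
            "width": annotations.width,
            "height": annotations.height,
            "points": annotations.points.tolist(),
        }
        path.write_text(json.dumps(payload))
        return
    df = pd.DataFrame(
        {
            "image_id": annotations.image_id,
            "x": annotations.points[:, 0],
            "y": annotations.points[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_annotations(
    path: str | Path, width: int | None = None, height: int | None = None
) -> AnnotationSet:
    """Read one image's annotations from CSV or JSON.

    CSV carries no image dimensions, so ``width``/``height`` are required
    there; JSON stores them.  Malformed or out-of-range rows raise with the
    offending line number.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return AnnotationSet(
            image_id=str(payload["image_id"]),
            points=np.asarray(payload["points"], dtype=np.float64).reshape(-1, 2),
            width=int(payload["width"]),
            height=int(payload["height"]),
        )
    if width is None or height is None:
        raise ValueError("width and height are required when reading CSV annotations")
    df = pd.read_csv(path)
    for col in ("image_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"annotation CSV {path} lacks column '{col}'")
    xy = df[["x", "y"]].to_numpy(dtype=np.float64)
    bad = ~np.isfinite(xy).all(axis=1) | (xy[:, 0] < 0) | (xy[:, 1] < 0)
    bad |= (xy[:, 0] >= width) | (xy[:, 1] >= height)
    if bad.any():
        line = int(np.nonzero(bad)[0][0]) + 2  # 1-based, after header
        raise ValueError(f"invalid annotation at {path}:{line}")
    ids = df["image_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"annotation file {path} mixes image ids {list(ids)}")
    image_id = str(ids[0]) if len(ids) else path.stem
    return AnnotationSet(image_id=image_id, points=xy, width=width, height=height)
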