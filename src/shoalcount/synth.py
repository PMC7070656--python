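"""Synthetic underwater fish-shoal scenes with point labels.

Generates the kind of imagery the counting pipeline is built for — a shoal
photographed from below through water — as a fully seeded stand-in dataset:

* a blue-green background with smooth spatial variation and an attenuated
  red channel (red light is absorbed fastest in water);
* N silver-grey elliptical fish bodies at random positions and headings,
  with N drawn uniformly from the configured count range (default 30–214,
  the span of shoal sizes the method targets);
* a vertical size gradient emulating perspective: fish near the top (far
  side) of the frame render smaller than fish near the bottom;
* overlap between fish allowed, as in a real shoal; the annotation stays
  at each fish's true center;
* a global Gaussian blur standing in for water scatter.

Fish are deliberately simple blurred ellipses, not textured sprites: enough
structure for a counting model to learn from, and nothing that a density
map could not represent.  The two dataset-expansion noise models are also
here: additive Gaussian noise with variance 0.001 on the [0, 1] intensity
scale, and salt-and-pepper noise corrupting a 0.001 fraction of pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .density import (
    AnnotationSet,
    KernelParams,
    block_sum_downsample,
    render_density_map,
    write_annotations,
)
from .enhance import EnhancementParams, enhance

__all__ = [
    "SceneConfig",
    "NoiseConfig",
    "generate_scene",
    "add_gaussian_noise",
    "add_salt_pepper",
    "make_dataset",
    "training_pairs",
]


@dataclass(frozen=True)
class SceneConfig:
    """Knobs of the scene generator (pixel units unless noted)."""

    width: int = 256
    height: int = 256
    count_range: tuple[int, int] = (30, 214)
    fish_length_range: tuple[float, float] = (10.0, 22.0)
    aspect_ratio_range: tuple[float, float] = (0.30, 0.50)
    size_gradient: float = 0.5  # far-side (top) shrink factor in [0, 1)
    red_attenuation: float = 0.35  # multiplier on the red channel
    blur_sigma: float = 1.0
    overlap_allowed: bool = True

    def __post_init__(self) -> None:
        if self.count_range[0] < 0 or self.count_range[1] < self.count_range[0]:
            raise ValueError("count_range must be a nonnegative (min, max) pair")
        if self.fish_length_range[0] <= 0:
            raise ValueError("fish lengths must be positive")
        if not 0 <= self.size_gradient < 1:
            raise ValueError("size_gradient must lie in [0, 1)")


@dataclass(frozen=True)
class NoiseConfig:
    """Dataset-expansion noise levels, both on normalized scales."""

    gaussian_variance: float = 0.001  # on the [0, 1] intensity scale
    salt_pepper_amount: float = 0.001  # fraction of corrupted pixels

    def __post_init__(self) -> None:
        if not 0 < self.gaussian_variance < 1 or not 0 < self.salt_pepper_amount < 1:
            raise ValueError("noise levels must lie in (0, 1)")


def _background(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.height, config.width
    base = np.array([40.0, 130.0, 145.0])  # murky blue-green
    canvas = np.empty((h, w, 3))
    # low-frequency luminance variation: coarse noise field, smoothly zoomed
    coarse = rng.normal(0.0, 1.0, (6, 6))
    fieldzoom = ndimage.zoom(coarse, (h / 6, w / 6), order=3, mode="nearest")
    fieldzoom = fieldzoom[:h, :w]
    for c in range(3):
        canvas[:, :, c] = base[c] * (1.0 + 0.12 * fieldzoom)
    canvas[:, :, 0] *= config.red_attenuation / 0.35  # scale red by config
    return canvas


def _paint_fish(
    canvas: np.ndarray,
    cx: float,
    cy: float,
    length: float,
    width: float,
    angle: float,
    color: np.ndarray,
) -> None:
    h, w, _ = canvas.shape
    a, b = length / 2.0, width / 2.0
    r = length / 2.0 + 1.5
    x0, x1 = max(0, int(cx - r)), min(w - 1, int(np.ceil(cx + r)))
    y0, y1 = max(0, int(cy - r)), min(h - 1, int(np.ceil(cy + r)))
    if x1 < x0 or y1 < y0:
        return
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    dx = xs - cx
    dy = ys - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = (dx * ca + dy * sa) / a
    v = (-dx * sa + dy * ca) / b
    dist = np.sqrt(u * u + v * v)
    mask = np.clip(1.5 * (1.0 - dist) + 0.5, 0.0, 1.0)  # soft ellipse edge
    patch = canvas[y0 : y1 + 1, x0 : x1 + 1]
    patch *= (1.0 - mask[..., None])
    patch += mask[..., None] * color


def generate_scene(
    config: SceneConfig | None = None,
    seed: int = 0,
    return_meta: bool = False,
):
    """Render one scene; returns (uint8 RGB image, AnnotationSet).

    With ``return_meta=True`` a dict with the per-fish geometry (lengths,
    widths, angles) is appended, for distributional checks.
    """
    config = config or SceneConfig()
    h, w = config.height, config.width
    if config.fish_length_range[1] > min(h, w):
        raise ValueError("fish larger than the image")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(config.count_range[0], config.count_range[1] + 1))
    canvas = _background(config, rng)

    centers = np.column_stack(
        [rng.uniform(0, w, size=n), rng.uniform(0, h, size=n)]
    )
    base_len = rng.uniform(*config.fish_length_range, size=n)
    aspects = rng.uniform(*config.aspect_ratio_range, size=n)
    angles = rng.uniform(0, np.pi, size=n)
    # perspective: top of frame (y = 0) is far away, fish appear smaller
    scale = 1.0 - config.size_gradient * (1.0 - centers[:, 1] / h)
    lengths = base_len * scale
    widths = lengths * aspects

    brightness = rng.uniform(150.0, 220.0, size=n)
    order = np.argsort(centers[:, 1])  # paint far (small) fish first
    for i in order:
        color = brightness[i] * np.array([config.red_attenuation, 0.95, 0.90])
        _paint_fish(
            canvas, centers[i, 0], centers[i, 1], lengths[i], widths[i], angles[i], color
        )
    for c in range(3):
        canvas[:, :, c] = ndimage.gaussian_filter(canvas[:, :, c], config.blur_sigma)
    image = np.clip(np.floor(canvas + 0.5), 0, 255).astype(np.uint8)
    # annotation coordinates must be strictly inside the frame
    pts = np.clip(centers, 0, [w - 1e-6, h - 1e-6])
    annotations = AnnotationSet(
        image_id=f"scene{seed:06d}", points=pts, width=w, height=h
    )
    if return_meta:
        meta = {"lengths": lengths, "widths": widths, "angles": angles, "areas": np.pi * lengths * widths / 4.0}
        return image, annotations, meta
    return image, annotations


def add_gaussian_noise(
    image: np.ndarray, cfg: NoiseConfig | None = None, seed: int = 0
) -> np.ndarray:
    """Zero-mean Gaussian noise of the configured variance on the [0,1] scale."""
    cfg = cfg or NoiseConfig()
    rng = np.random.default_rng(seed)
    x = np.asarray(image, dtype=np.float64) / 255.0
    x = x + rng.normal(0.0, np.sqrt(cfg.gaussian_variance), size=x.shape)
    return np.clip(np.floor(x * 255.0 + 0.5), 0, 255).astype(np.uint8)


def add_salt_pepper(
    image: np.ndarray, cfg: NoiseConfig | None = None, seed: int = 0
) -> np.ndarray:
    """Set ~amount of pixels to 0 or 255 (equal probability), rest untouched."""
    cfg = cfg or NoiseConfig()
    rng = np.random.default_rng(seed)
    out = np.asarray(image).copy()
    h, w = out.shape[:2]
    mask = rng.random((h, w)) < cfg.salt_pepper_amount
    salt = rng.random((h, w)) < 0.5
    out[mask & salt] = 255
    out[mask & ~salt] = 0
    return out


def training_pairs(
    n_scenes: int,
    scene_cfg: SceneConfig | None = None,
    kernel_params: KernelParams | None = None,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """In-memory (image, ground-truth grid) pairs ready for training.

    Images are float32 in [0, 1]; ground truth is the full-resolution
    adaptive-kernel density map block-sum downsampled by 8 so counts are
    preserved on the network's output grid.
    """
    scene_cfg = scene_cfg or SceneConfig()
    pairs = []
    for i in range(n_scenes):
        image, ann = generate_scene(scene_cfg, seed=seed + i)
        dmap = block_sum_downsample(render_density_map(ann, kernel_params), 8)
        pairs.append((image.astype(np.float32) / 255.0, dmap.grid.astype(np.float32)))
    return pairs


def make_dataset(
    n_scenes: int,
    out_dir: str | Path,
    scene_cfg: SceneConfig | None = None,
    noise_cfg: NoiseConfig | None = None,
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    enhancement: EnhancementParams | None = None,
) -> dict[str, list[dict]]:
    """Write a 4x-expanded dataset and its train/val/test manifests.

    Every scene yields four image variants — original, enhanced, Gaussian
    noise, salt-and-pepper noise — sharing one annotation file, and all
    four land in the same split so no fish distribution leaks across
    splits.  Returns {"train": [...], "val": [...], "test": [...]} where
    each entry lists the scene id, annotation path and variant paths.
    """
    if abs(sum(split) - 1.0) > 1e-9 or any(s < 0 for s in split):
        raise ValueError("split fractions must be nonnegative and sum to 1")
    scene_cfg = scene_cfg or SceneConfig()
    noise_cfg = noise_cfg or NoiseConfig()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_scenes)
    order = rng.permutation(n_scenes)
    n_train = int(round(split[0] * n_scenes))
    n_val = int(round(split[1] * n_scenes))
    assignment = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            assignment[idx] = "train"
        elif rank < n_train + n_val:
            assignment[idx] = "val"
        else:
            assignment[idx] = "test"

    manifests: dict[str, list[dict]] = {"train": [], "val": [], "test": []}
    for i in range(n_scenes):
        sseed = int(scene_seeds[i])
        image, ann = generate_scene(scene_cfg, seed=sseed)
        ann.image_id = f"scene{i:05d}"
        ann_path = out_dir / "annotations" / f"{ann.image_id}.json"
        write_annotations(ann, ann_path)
        variants = {
            "original": image,
            "enhanced": enhance(image, enhancement),
            "gaussian": add_gaussian_noise(image, noise_cfg, seed=sseed + 1),
            "salt_pepper": add_salt_pepper(image, noise_cfg, seed=sseed + 2),
        }
        paths = {}
        for name, arr in variants.items():
            p = out_dir / "images" / f"{ann.image_id}_{name}.png"
            Image.fromarray(arr).save(p)
            paths[name] = str(p.relative_to(out_dir))
        manifests[assignment[i]].append(
            {
                "scene_id": ann.image_id,
                "annotations": str(ann_path.relative_to(out_dir)),
                "count": ann.count,
                "images": paths,
            }
        )
    for name, entries in manifests.items():
        (out_dir / f"{name}.json").write_text(json.dumps(entries, indent=1))
    return manifests
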