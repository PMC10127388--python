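"""Synthetic field-plot scenes with known cluster centroids.

Real plot imagery shows a green canopy dotted with yellow, roughly circular,
partially overlapping flower clusters — anywhere from a handful to over a
thousand per plot at peak flowering. The generator emulates exactly those
features (textured green background, soft-edged yellow elliptical blobs with
jittered color, optional clustered placement, sensor noise) and returns the
blob centers as ground truth, so every downstream stage — annotation I/O,
loss, training, metrics — can be exercised end to end with a known answer.

It makes no attempt at photorealism: no leaf geometry, shadows, perspective
or growth-stage phenology. What it preserves is the *counting structure* of
the task: compact colored blobs of varying size and eccentricity on a
cluttered background, with overlap and near-adjacency controlled by
``occlusion_prob`` and ``min_center_distance``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv

from .annotations import (
    BoxAnnotationSet,
    PointAnnotationSet,
    write_points,
    write_voc_boxes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SceneConfig", "small_scene_config", "generate_scene", "hsv_augment",
    "generate_dataset", "PlacementError",
]


class PlacementError(RuntimeError):
    """Could not place the requested number of centers at the given spacing."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic plot scene.

    Defaults mimic a 512x1024 plot canvas with the box-labeled dataset's
    count range (8-686 clusters per plot); ``small_scene_config`` gives the
    128x128 desk-scale profile used for CPU training runs.
    """

    height: int = 512
    width: int = 1024
    count_range: tuple[int, int] = (8, 686)
    blob_radius_range: tuple[float, float] = (4.0, 11.0)
    min_center_distance: float = 6.0
    background_green: tuple[float, float, float] = (0.28, 0.42, 0.18)
    cluster_yellow: tuple[float, float, float] = (0.92, 0.84, 0.25)
    occlusion_prob: float = 0.3
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.count_range, self.blob_radius_range):
            if lo > hi:
                raise ValueError("range minimum exceeds maximum")
        if self.min_center_distance < 0:
            raise ValueError("min_center_distance must be non-negative")
        if not 0.0 <= self.occlusion_prob <= 1.0:
            raise ValueError("occlusion_prob must lie in [0, 1]")


def small_scene_config(seed: int = 0, **kw) -> SceneConfig:
    """128x128 profile with 5-40 clusters: the CPU-scale test bed."""
    defaults = dict(
        height=128, width=128, count_range=(5, 40),
        blob_radius_range=(3.0, 7.0), min_center_distance=5.0, seed=seed,
    )
    defaults.update(kw)
    return SceneConfig(**defaults)


def _place_centers(cfg: SceneConfig, k: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample k centers with pairwise spacing >= min_center_distance.

    With probability ``occlusion_prob`` a new center is proposed near an
    existing one (clustered growth, emulating adhering clusters); otherwise
    uniformly over the plot.
    """
    margin = cfg.blob_radius_range[0]
    centers: list[tuple[float, float]] = []
    budget = 200 * k + 1000
    d2 = cfg.min_center_distance**2
    while len(centers) < k and budget > 0:
        budget -= 1
        if centers and rng.random() < cfg.occlusion_prob:
            cx, cy = centers[rng.integers(len(centers))]
            r = cfg.min_center_distance + rng.exponential(cfg.blob_radius_range[1])
            theta = rng.uniform(0, 2 * np.pi)
            x, y = cx + r * np.cos(theta), cy + r * np.sin(theta)
        else:
            x = rng.uniform(margin, cfg.width - margin)
            y = rng.uniform(margin, cfg.height - margin)
        if not (margin <= x <= cfg.width - margin
                and margin <= y <= cfg.height - margin):
            continue
        ok = all((x - cx) ** 2 + (y - cy) ** 2 >= d2 for cx, cy in centers)
        if ok:
            centers.append((float(x), float(y)))
    if len(centers) < k:
        raise PlacementError(
            f"placed only {len(centers)}/{k} centers at spacing "
            f"{cfg.min_center_distance}; reduce the count or the distance"
        )
    return np.asarray(centers)


def _render(cfg: SceneConfig, blobs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Render float RGB in [0, 1] from blob rows (cx, cy, rx, ry, theta, jitter)."""
    h, w = cfg.height, cfg.width
    img = np.empty((h, w, 3), dtype=float)
    # textured canopy: smooth multiplicative field over the base green
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=6.0)
    texture = 1.0 + 0.35 * texture / max(texture.std(), 1e-9)
    for ch, base in enumerate(cfg.background_green):
        img[:, :, ch] = base * texture
    yellow = np.asarray(cfg.cluster_yellow)
    yy, xx = np.mgrid[0:h, 0:w]
    for cx, cy, rx, ry, theta, jit in blobs:
        pad = int(np.ceil(3 * max(rx, ry))) + 1
        x0, x1 = max(int(cx) - pad, 0), min(int(cx) + pad + 1, w)
        y0, y1 = max(int(cy) - pad, 0), min(int(cy) + pad + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        u = xx[y0:y1, x0:x1] - cx
        v = yy[y0:y1, x0:x1] - cy
        ct, st = np.cos(theta), np.sin(theta)
        a = (u * ct + v * st) / rx
        b = (-u * st + v * ct) / ry
        # soft-edged elliptical profile: ~1 inside, Gaussian falloff at rim
        alpha = np.exp(-0.5 * (a**2 + b**2) ** 2)
        color = np.clip(yellow * (1.0 + 0.12 * jit), 0, 1)
        patch = img[y0:y1, x0:x1]
        patch += alpha[:, :, None] * (color - patch)
    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_scene(
    cfg: SceneConfig,
    *,
    rng: np.random.Generator | None = None,
    return_blobs: bool = False,
):
    """Generate one scene: (uint8 RGB image, PointAnnotationSet[, blob array]).

    Fully determined by ``cfg.seed`` (or the supplied generator). Blob rows
    are ``(cx, cy, rx, ry, theta, color_jitter)``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    k = int(rng.integers(cfg.count_range[0], cfg.count_range[1] + 1))
    centers = _place_centers(cfg, k, rng)
    r_lo, r_hi = cfg.blob_radius_range
    rx = rng.uniform(r_lo, r_hi, size=k)
    ecc = rng.uniform(0.6, 1.0, size=k)  # ry/rx: mildly elliptical
    ry = np.clip(rx * ecc, r_lo * 0.5, None)
    theta = rng.uniform(0, np.pi, size=k)
    jitter = rng.normal(0.0, 1.0, size=k)
    blobs = np.column_stack([centers, rx, ry, theta, jitter])
    img = (_render(cfg, blobs, rng) * 255).round().astype(np.uint8)
    pts = PointAnnotationSet.from_array(f"scene_{cfg.seed}", centers)
    if return_blobs:
        return img, pts, blobs
    return img, pts


def hsv_augment(image: np.ndarray, brightness_factor: float,
                contrast_factor: float) -> np.ndarray:
    """Brightness/contrast jitter in HSV space (the +-10% augmentation).

    The value channel is scaled by ``1 + brightness_factor``; contrast is
    applied about the value-channel mean, scaled by ``1 + contrast_factor``.
    Factors are limited to [-0.5, 0.5]; channels are clipped and the image
    returned in the input dtype (uint8 round-trips within +-1 level).
    """
    for name, f in (("brightness", brightness_factor), ("contrast", contrast_factor)):
        if not -0.5 <= f <= 0.5:
            raise ValueError(f"{name}_factor {f} outside [-0.5, 0.5]")
    arr = np.asarray(image)
    was_uint8 = arr.dtype == np.uint8
    hsv = rgb2hsv(arr.astype(float) / 255.0 if was_uint8 else arr)
    v = hsv[:, :, 2] * (1.0 + brightness_factor)
    v = v.mean() + (v - v.mean()) * (1.0 + contrast_factor)
    hsv[:, :, 2] = np.clip(v, 0.0, 1.0)
    out = hsv2rgb(hsv)
    if was_uint8:
        return (out * 255).round().astype(np.uint8)
    return np.clip(out, 0.0, 1.0)


def _blob_boxes(image_id: str, blobs: np.ndarray,
                bounds: tuple[int, int]) -> BoxAnnotationSet:
    """Tight axis-aligned bounding boxes of the rendered (rotated) ellipses."""
    w, h = bounds
    rows = []
    for cx, cy, rx, ry, theta, _ in blobs:
        ct, st = np.cos(theta), np.sin(theta)
        hw = float(np.sqrt((rx * ct) ** 2 + (ry * st) ** 2))
        hh = float(np.sqrt((rx * st) ** 2 + (ry * ct) ** 2))
        rows.append((max(cx - hw, 0.0), max(cy - hh, 0.0),
                     min(cx + hw, w - 1.0), min(cy + hh, h - 1.0)))
    return BoxAnnotationSet(image_id, tuple(rows))


def generate_dataset(cfg: SceneConfig, n_images: int, out_dir: str | Path,
                     label_style: str = "points") -> pd.DataFrame:
    """Write ``n_images`` scenes + annotations + a manifest CSV; return it.

    ``label_style`` is ``points`` (centroid CSV, emulating dot labeling) or
    ``boxes`` (Pascal VOC XML of tight blob boxes, emulating box labeling).
    Deterministic given ``cfg.seed``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if label_style not in ("points", "boxes"):
        raise ValueError("label_style must be 'points' or 'boxes'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg.seed)
    rows = []
    for i in range(n_images):
        scene_cfg = replace(cfg, seed=int(master.integers(2**31)))
        img, pts, blobs = generate_scene(scene_cfg, return_blobs=True)
        stem = f"scene_{i:04d}"
        img_path = out_dir / f"{stem}.png"
        Image.fromarray(img).save(img_path)
        if label_style == "points":
            ann_path = out_dir / f"{stem}.csv"
            write_points(PointAnnotationSet(stem, pts.points), ann_path)
        else:
            ann_path = out_dir / f"{stem}.xml"
            write_voc_boxes(
                _blob_boxes(stem, blobs, (cfg.width, cfg.height)),
                ann_path, image_size=(cfg.width, cfg.height),
            )
        rows.append({"image": img_path.name, "annotation": ann_path.name,
                     "count": pts.n})
    manifest = pd.DataFrame(rows, columns=["image", "annotation", "count"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
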