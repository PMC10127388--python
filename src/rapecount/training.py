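"""Dataset splitting, the point-supervised training loop, and evaluation.

Training follows the published recipe: SGD at a fixed learning rate, batch
size 1, the Bayesian point-supervision loss on the density grid, an
85/15 train+val / test split with the training pool further divided 9:1
into train and validation, and checkpoint selection by lowest validation
MAE. The per-sample posterior matrices depend only on the annotation
geometry and the loss hyperparameters, so they are precomputed once per
sample and reused every epoch.

512x1024 canvases contribute their eight 256x256 tiles as independent
samples (annotations are assigned to tiles by centroid location); smaller
images train as single samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .annotations import (
    PointAnnotationSet, boxes_to_centroids, read_points, read_voc_boxes,
)
from .density_loss import (
    LossConfig, bayes_loss_and_grad, make_pixel_grid, posterior_from_points,
)
from .inference import TILE_SIZE, _image_to_input, predict_count
from .metrics import CountMetrics, EvaluationSet, evaluate_counts
from .model import NetworkConfig, RapeNet, build_model
from .nn import SGD

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "split_dataset", "load_manifest_samples", "train",
           "evaluate_model", "desk_protocol", "make_scene_samples"]


@dataclass
class TrainConfig:
    """Training hyperparameters (published defaults; desk runs override).

    lr 1e-5, 1000 epochs, batch size 1, 15% test, 10% of the remaining pool
    for validation; sigma and background_ratio sit mid-range of the
    published search intervals ([0.1, 10] and [0, 1]).
    """

    lr: float = 1e-5
    epochs: int = 1000
    batch_size: int = 1
    test_fraction: float = 0.15
    val_fraction_of_pool: float = 0.1
    sigma: float = 8.0
    background_ratio: float = 0.15
    use_background: bool = True
    momentum: float = 0.9
    lr_schedule: str = "constant"  # or "cosine" (decay to 0 over epochs)
    scale_factors: tuple[float, ...] = ()  # multi-scale training resample set
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0
                and 0.0 < self.val_fraction_of_pool < 1.0):
            raise ValueError("fractions must lie in (0, 1)")
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid optimizer settings")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")

    def loss_config(self) -> LossConfig:
        return LossConfig(sigma=self.sigma, background_ratio=self.background_ratio,
                          use_background=self.use_background)


def split_dataset(items, cfg: TrainConfig):
    """Deterministic (seeded) shuffled split into (train, val, test).

    test = round(test_fraction * n); of the remaining pool,
    val = floor(val_fraction_of_pool * pool) and train is the rest. The
    three partitions are disjoint and exhaustive; an empty partition is a
    configuration error.
    """
    items = list(items)
    n = len(items)
    if n < 3:
        raise ValueError("need at least 3 items to split")
    order = np.random.default_rng(cfg.seed).permutation(n)
    n_test = int(round(cfg.test_fraction * n))
    n_pool = n - n_test
    n_val = int(math.floor(cfg.val_fraction_of_pool * n_pool))
    n_train = n_pool - n_val
    if min(n_test, n_val, n_train) < 1:
        raise ValueError(
            f"split of {n} items leaves an empty partition "
            f"(train={n_train}, val={n_val}, test={n_test})"
        )
    test = [items[i] for i in order[:n_test]]
    val = [items[i] for i in order[n_test:n_test + n_val]]
    train_part = [items[i] for i in order[n_test + n_val:]]
    return train_part, val, test


def _read_annotation(path: Path) -> PointAnnotationSet:
    if path.suffix.lower() == ".xml":
        return boxes_to_centroids(read_voc_boxes(path))
    return read_points(path)


@dataclass
class Sample:
    """One training sample: a CHW float image and its centroid annotations."""

    image_id: str
    image: np.ndarray  # (3, H, W) float32 in [0, 1]
    points: PointAnnotationSet


def load_manifest_samples(manifest: pd.DataFrame | str | Path,
                          root: str | Path | None = None) -> list[Sample]:
    """Load (image, points) pairs from a generate_dataset-style manifest.

    ``manifest`` is the CSV path or a DataFrame with columns
    image/annotation/count; relative paths resolve against ``root`` (default:
    the manifest's directory).
    """
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        root = root if root is not None else path.parent
        manifest = pd.read_csv(path)
    root = Path(root) if root is not None else Path(".")
    samples = []
    for _, row in manifest.iterrows():
        img_path = root / str(row["image"])
        ann_path = root / str(row["annotation"])
        arr = np.asarray(Image.open(img_path).convert("RGB"))
        pts = _read_annotation(ann_path)
        samples.append(Sample(img_path.stem, _image_to_input(arr), pts))
    return samples


def _tile_samples(samples: list[Sample], tile: int = TILE_SIZE) -> list[Sample]:
    """Split canvas-sized samples into independent tile samples."""
    out: list[Sample] = []
    for s in samples:
        _, h, w = s.image.shape
        if h % tile == 0 and w % tile == 0 and (h > tile or w > tile):
            pts = s.points.asarray()
            for ti, y0 in enumerate(range(0, h, tile)):
                for tj, x0 in enumerate(range(0, w, tile)):
                    mask = ((pts[:, 0] >= x0) & (pts[:, 0] < x0 + tile)
                            & (pts[:, 1] >= y0) & (pts[:, 1] < y0 + tile))
                    local = pts[mask] - np.array([x0, y0])
                    out.append(Sample(
                        f"{s.image_id}_t{ti}{tj}",
                        np.ascontiguousarray(s.image[:, y0:y0 + tile, x0:x0 + tile]),
                        PointAnnotationSet.from_array(s.image_id, local),
                    ))
        else:
            out.append(s)
    return out


def _rescale_sample(s: Sample, factor: float, stride: int) -> Sample:
    """Bilinearly resample a sample's image (and points) by ``factor``.

    Output dims snap to the nearest stride multiple; the annotation count
    is preserved (points are clamped to the new bounds).
    """
    _, h, w = s.image.shape
    nh = max(stride, int(round(h * factor / stride)) * stride)
    nw = max(stride, int(round(w * factor / stride)) * stride)
    if (nh, nw) == (h, w):
        return s
    hwc = (np.clip(s.image, 0, 1) * 255).round().astype(np.uint8).transpose(1, 2, 0)
    resized = np.asarray(Image.fromarray(hwc).resize((nw, nh), Image.BILINEAR))
    from .annotations import rescale_points

    pts = rescale_points(s.points, nw / w, nh / h, bounds=(nw, nh))
    return Sample(f"{s.image_id}@{factor:g}", _image_to_input(resized), pts)


def _val_mae(model: RapeNet, val: list[Sample]) -> float:
    errs = []
    for s in val:
        count, _, _ = predict_count(s.image.transpose(1, 2, 0), model)
        errs.append(abs(count - s.points.n))
    return float(np.mean(errs))


def train(
    model_cfg: NetworkConfig,
    samples: list[Sample] | pd.DataFrame | str | Path,
    cfg: TrainConfig,
    *,
    val_samples: list[Sample] | None = None,
    log_path: str | Path | None = None,
    val_every: int = 10,
) -> tuple[RapeNet, pd.DataFrame]:
    """Train a RapeNet-family model with the Bayesian loss.

    ``samples`` may be a manifest (path/DataFrame) or preloaded samples.
    Canvas-sized images are tiled into eight independent samples first. Per
    epoch, samples are visited in a seeded shuffled order; each step runs a
    forward pass, forms the Bayes/Bayes+ loss from that image's posterior,
    and takes one SGD step. When ``cfg.scale_factors`` is non-empty each
    step trains on a randomly chosen rescaled variant of the sample
    (count-preserving multi-scale augmentation; the count target N does not
    change with resolution). Validation MAE is measured every ``val_every``
    epochs (and at the end); the returned model carries the weights of the
    best validation epoch (or the final weights when no validation set is
    given). Returns ``(model, log)`` with per-epoch mean loss rows.
    """
    if not isinstance(samples, list):
        samples = load_manifest_samples(samples)
    samples = _tile_samples(samples)
    if not samples:
        raise ValueError("empty training set")
    loss_cfg = cfg.loss_config()
    model = build_model(replace(model_cfg, seed=model_cfg.seed or cfg.seed))
    stride = model.cfg.output_stride
    factors = tuple(cfg.scale_factors) or (1.0,)
    if any(f <= 0 for f in factors):
        raise ValueError("scale factors must be positive")
    # per sample: one variant per training scale, each with its posterior
    # (posterior geometry is fixed per variant, so it is built once)
    variants: list[list[tuple[Sample, object]]] = []
    for s in samples:
        vs = []
        for f in factors:
            sv = _rescale_sample(s, f, stride) if f != 1.0 else s
            _, h, w = sv.image.shape
            grid = make_pixel_grid(h, w, stride)
            post = posterior_from_points(grid, sv.points, loss_cfg)
            if post is None:
                logger.info("%s has no annotations; loss targets an empty map",
                            sv.image_id)
            vs.append((sv, post))
        variants.append(vs)
    opt = SGD(model.params(), lr=cfg.lr, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    best = (math.inf, None)
    for epoch in range(1, cfg.epochs + 1):
        if cfg.lr_schedule == "cosine":
            opt.lr = 0.5 * cfg.lr * (1 + math.cos(math.pi * (epoch - 1) / cfg.epochs))
        order = rng.permutation(len(samples))
        losses = []
        for i in order:
            s, post = variants[i][rng.integers(len(variants[i]))] \
                if len(variants[i]) > 1 else variants[i][0]
            dm = model.forward(s.image, train=True)
            loss, grad = bayes_loss_and_grad(post, dm, loss_cfg)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss on {s.image_id} at epoch {epoch} "
                    f"(sigma={cfg.sigma}, background_ratio={cfg.background_ratio})"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "val_mae": math.nan}
        if val_samples and (epoch % val_every == 0 or epoch == cfg.epochs):
            vmae = _val_mae(model, val_samples)
            row["val_mae"] = vmae
            if vmae < best[0]:
                # snapshot weights AND normalization running stats together
                best = (vmae, model.get_state())
        rows.append(row)
    if best[1] is not None:
        model.set_state(best[1])
    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return model, log


def make_scene_samples(n_images: int, seed: int, **scene_kw) -> list[Sample]:
    """Generate in-memory synthetic 128x128 samples for desk-scale studies."""
    from .synthetic import generate_scene, small_scene_config

    master = np.random.default_rng(seed)
    samples = []
    for i in range(n_images):
        cfg = small_scene_config(seed=int(master.integers(2**31)), **scene_kw)
        img, pts = generate_scene(cfg)
        samples.append(Sample(f"scene_{i:04d}", _image_to_input(img), pts))
    return samples


def desk_protocol(seed: int = 0) -> tuple[NetworkConfig, TrainConfig]:
    """The reduced-width CPU training protocol for synthetic recovery runs.

    A quarter-width RapeNet trained for 100 epochs on 128x128 scenes. The
    loss bandwidth is half a density-grid cell (4 input pixels, the scale
    of a single blob) to keep label assignment sharp; lr is raised to 3e-4
    with momentum 0.9 and cosine decay so the short schedule converges and
    the l1-oscillation count floor collapses — the published full-scale
    recipe (1e-5, 1000 epochs, constant) remains the TrainConfig default.
    See docs/methods.md for the calibration rationale.
    """
    from .model import default_rapenet_config

    net_cfg = default_rapenet_config(width_multiplier=0.25, seed=seed)
    train_cfg = TrainConfig(lr=3e-4, epochs=100, sigma=0.5,
                            background_ratio=0.3, momentum=0.9,
                            lr_schedule="cosine", seed=seed)
    return net_cfg, train_cfg


def evaluate_model(
    model: RapeNet,
    samples: list[Sample] | pd.DataFrame | str | Path,
    *,
    r2_denominator: str = "inferred",
    round_counts: bool = False,
) -> tuple[CountMetrics, pd.DataFrame]:
    """Run tiled prediction on a test set and score it against annotations.

    Manual count = annotation N; inferred count = predicted density sum.
    Returns the metric bundle and the per-image DataFrame.
    """
    if not isinstance(samples, list):
        samples = load_manifest_samples(samples)
    if not samples:
        raise ValueError("empty test set")
    rows = []
    for s in samples:
        count, _, _ = predict_count(s.image.transpose(1, 2, 0), model)
        rows.append({"image_id": s.image_id, "manual": float(s.points.n),
                     "inferred": count})
    df = pd.DataFrame(rows)
    ev = EvaluationSet.from_pairs(df["manual"], df["inferred"], df["image_id"])
    metrics = evaluate_counts(ev, r2_denominator=r2_denominator,
                              round_counts=round_counts)
    return metrics, df
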