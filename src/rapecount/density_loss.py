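"""Bayesian point-supervision loss for density-map counting regression.

Ground truth is one dot per flower cluster. Instead of rasterizing the dots
into a fixed Gaussian density target, the loss forms, for every density-map
cell ``x_m``, a posterior over which annotation ``y_n`` the density at that
cell belongs to, and penalizes the deviation of each annotation's *expected
count* ``E_n = sum_m p(y_n | x_m) D(x_m)`` from 1.

The per-annotation likelihood is an isotropic 2-D Gaussian centered on the
annotation::

    p(x_m | y_n) = N(x_m; z_n, sigma^2 I)

and with equal priors the posterior is the column-normalized likelihood
matrix. The background-augmented variant adds a dummy label ``y_0`` whose
likelihood at cell ``x_m`` is a 1-D Gaussian in the distance to the nearest
annotation, peaked at a fixed margin ``d`` beyond it; density assigned to the
background label is driven to a target count of 0.

All posterior arithmetic is done in log space with a per-column max shift:
sigma as small as 0.1 grid cells underflows the naive Gaussian on any
realistically sized grid.

Coordinates here live on the *density grid* (input pixels divided by the
network stride), so the cell count M matches the density map the network
emits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .annotations import PointAnnotationSet

logger = logging.getLogger(__name__)

__all__ = [
    "PixelGrid",
    "DensityMap",
    "PosteriorMatrix",
    "LossConfig",
    "make_pixel_grid",
    "likelihood_matrix",
    "log_likelihood_matrix",
    "background_point",
    "background_likelihood",
    "log_background_likelihood",
    "posterior_matrix",
    "posterior_from_points",
    "bayes_loss",
    "bayes_plus_loss",
    "bayes_loss_and_grad",
]


@dataclass(frozen=True)
class PixelGrid:
    """The density-map lattice: M = height*width cell-center locations.

    Cell (i, j) sits at (j + 0.5, i + 0.5) in grid units; ``stride`` records
    how many input pixels one cell covers per axis.
    """

    height: int
    width: int
    stride: int
    locations: np.ndarray  # (M, 2) float, (x, y) row-major by cell

    @property
    def m(self) -> int:
        return self.height * self.width


@dataclass
class DensityMap:
    """Non-negative density grid; its sum is the predicted count."""

    values: np.ndarray  # (H, W) float, all >= 0
    stride: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("density map must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValueError("density map contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("density map contains negative values")

    def count(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class PosteriorMatrix:
    """Per-cell label posteriors; columns sum to 1.

    ``has_background`` marks that row 0 is the dummy background label and
    rows 1..N are the annotations.
    """

    probs: np.ndarray  # (N or N+1, M)
    has_background: bool = False

    @property
    def n_annotations(self) -> int:
        return self.probs.shape[0] - (1 if self.has_background else 0)

    @property
    def m(self) -> int:
        return self.probs.shape[1]


def _abs_penalty(v: np.ndarray) -> np.ndarray:
    return np.abs(v)


@dataclass
class LossConfig:
    """Loss hyperparameters.

    sigma
        Gaussian bandwidth of the annotation likelihoods, in density-grid
        cells. The useful range is about 0.1-10.
    background_ratio
        In [0, 1]; sets the background margin as a fraction of the tile's
        shorter side: ``d = background_ratio * min(tile_h, tile_w) / stride``
        (grid units). ``d_absolute`` overrides this with an explicit d.
    use_background
        Whether training adds the dummy background label (Bayes+).
    penalty
        The per-term penalty F; default is the absolute value (l1).
    """

    sigma: float = 8.0
    background_ratio: float = 0.15
    use_background: bool = True
    d_absolute: float | None = None
    penalty: Callable[[np.ndarray], np.ndarray] = field(default=_abs_penalty)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not 0.0 <= self.background_ratio <= 1.0:
            raise ValueError("background_ratio must lie in [0, 1]")

    def background_distance(self, tile_height_px: int, tile_width_px: int,
                            stride: int) -> float:
        """The margin d in grid units for a given tile geometry."""
        if self.d_absolute is not None:
            return float(self.d_absolute)
        return self.background_ratio * min(tile_height_px, tile_width_px) / stride


def make_pixel_grid(height_px: int, width_px: int, stride: int) -> PixelGrid:
    """Build the density-grid lattice for a tile of the given pixel size."""
    if height_px % stride or width_px % stride:
        raise ValueError(
            f"tile size {height_px}x{width_px} not divisible by stride {stride}"
        )
    h, w = height_px // stride, width_px // stride
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    locations = np.stack([jj.ravel() + 0.5, ii.ravel() + 0.5], axis=1).astype(float)
    return PixelGrid(h, w, stride, locations)


def points_to_grid(pts: PointAnnotationSet, stride: int) -> np.ndarray:
    """Annotation pixel coordinates -> density-grid units ((N, 2) array)."""
    return pts.asarray() / float(stride)


def _sq_distances(grid: PixelGrid, z: np.ndarray) -> np.ndarray:
    """(N, M) squared euclidean distances from each point to each cell center."""
    diff = z[:, None, :] - grid.locations[None, :, :]
    return np.einsum("nmk,nmk->nm", diff, diff)


def log_likelihood_matrix(grid: PixelGrid, z: np.ndarray, sigma: float) -> np.ndarray:
    """(N, M) log of the 2-D Gaussian likelihoods p(x_m | y_n)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = np.asarray(z, dtype=float).reshape(-1, 2)
    sq = _sq_distances(grid, z)
    return -sq / (2.0 * sigma**2) - np.log(2.0 * np.pi * sigma**2)


def likelihood_matrix(
    grid: PixelGrid, pts: PointAnnotationSet | np.ndarray, sigma: float
) -> np.ndarray:
    """(N, M) Gaussian likelihood p(x_m | y_n); points already in grid units.

    N = 0 yields an empty (0, M) matrix — the loss functions decide what an
    unannotated image means.
    """
    z = pts.asarray() if isinstance(pts, PointAnnotationSet) else np.asarray(pts)
    z = z.reshape(-1, 2)
    if len(z) == 0:
        return np.empty((0, grid.m))
    return np.exp(log_likelihood_matrix(grid, z, sigma))


def background_point(x: np.ndarray, z_near: np.ndarray, d: float) -> np.ndarray:
    """The dummy background point: distance d beyond z_near along the ray to x.

    Degenerate case x == z_near (a cell center exactly on an annotation) has
    no defined direction; the annotation itself is returned with a log note.
    """
    x = np.asarray(x, dtype=float)
    z_near = np.asarray(z_near, dtype=float)
    if d <= 0:
        raise ValueError("d must be positive")
    delta = x - z_near
    norm = float(np.linalg.norm(delta))
    if norm == 0.0:
        logger.debug("background_point: pixel coincides with annotation %s", z_near)
        return z_near.copy()
    return z_near + d * delta / norm


def log_background_likelihood(
    grid: PixelGrid, z: np.ndarray, sigma: float, d: float
) -> np.ndarray:
    """(M,) log background likelihood: 1-D Gaussian in distance, peaked at d.

    For each cell the nearest annotation is found; the likelihood is
    ``(1/(sqrt(2 pi) sigma)) exp(-(d - dist)^2 / (2 sigma^2))`` — maximal for
    cells sitting exactly at the margin d beyond their nearest annotation.
    """
    z = np.asarray(z, dtype=float).reshape(-1, 2)
    if len(z) == 0:
        raise ValueError("background likelihood needs at least one annotation")
    if sigma <= 0 or d <= 0:
        raise ValueError("sigma and d must be positive")
    dist = np.sqrt(_sq_distances(grid, z)).min(axis=0)
    return -((d - dist) ** 2) / (2.0 * sigma**2) - 0.5 * np.log(2.0 * np.pi) - np.log(sigma)


def background_likelihood(
    grid: PixelGrid, pts: PointAnnotationSet | np.ndarray, sigma: float, d: float
) -> np.ndarray:
    """(M,) background likelihood row (linear scale)."""
    z = pts.asarray() if isinstance(pts, PointAnnotationSet) else np.asarray(pts)
    return np.exp(log_background_likelihood(grid, z, sigma, d))


def _posterior_from_log(loglik: np.ndarray) -> np.ndarray:
    """Column-normalize exp(loglik) with a per-column max shift (no underflow)."""
    shift = loglik.max(axis=0, keepdims=True)
    bad = ~np.isfinite(shift).ravel()
    if bad.any():
        raise FloatingPointError(
            f"posterior underflow: no label has support at cell(s) "
            f"{np.flatnonzero(bad)[:5].tolist()}"
        )
    p = np.exp(loglik - shift)
    return p / p.sum(axis=0, keepdims=True)


def posterior_matrix(
    lik: np.ndarray, bg: np.ndarray | None = None
) -> PosteriorMatrix:
    """Posterior p(y_n | x_m): column-normalized likelihoods, equal priors.

    If a background row ``bg`` is supplied it becomes row 0 and normalization
    runs over N+1 labels (the uniform priors cancel either way). A column
    whose likelihoods are all exactly zero raises, naming the cell.
    """
    lik = np.asarray(lik, dtype=float)
    if lik.ndim != 2 or lik.shape[0] == 0:
        raise ValueError("likelihood matrix must have at least one row")
    if (lik < 0).any():
        raise ValueError("likelihoods must be non-negative")
    rows = lik
    if bg is not None:
        bg = np.asarray(bg, dtype=float).reshape(1, -1)
        if bg.shape[1] != lik.shape[1]:
            raise ValueError("background row length does not match M")
        rows = np.vstack([bg, lik])
    with np.errstate(divide="ignore"):
        probs = _posterior_from_log(np.log(rows))
    return PosteriorMatrix(probs, has_background=bg is not None)


def posterior_from_points(
    grid: PixelGrid,
    pts: PointAnnotationSet | np.ndarray,
    cfg: LossConfig,
    *,
    points_in_pixels: bool = True,
) -> PosteriorMatrix | None:
    """Build the (background-augmented) posterior for one tile, in log space.

    This is the training-path entry point: coordinates are divided by the
    grid stride when ``points_in_pixels``, likelihoods never leave log scale,
    and sigma = 0.1 on large grids is safe. Returns None for an image with no
    annotations (the loss then targets an empty map).
    """
    z = pts.asarray() if isinstance(pts, PointAnnotationSet) else np.asarray(pts, float).reshape(-1, 2)
    if points_in_pixels:
        z = z / float(grid.stride)
    if len(z) == 0:
        return None
    loglik = log_likelihood_matrix(grid, z, cfg.sigma)
    if cfg.use_background:
        d = cfg.background_distance(
            grid.height * grid.stride, grid.width * grid.stride, grid.stride
        )
        if d > 0:
            logbg = log_background_likelihood(grid, z, cfg.sigma, d)
            loglik = np.vstack([logbg[None, :], loglik])
            return PosteriorMatrix(_posterior_from_log(loglik), has_background=True)
    return PosteriorMatrix(_posterior_from_log(loglik), has_background=False)


def _check_shapes(post: PosteriorMatrix, D: DensityMap) -> np.ndarray:
    dvec = D.values.ravel()
    if post.m != dvec.size:
        raise ValueError(
            f"posterior has M={post.m} cells but density map has {dvec.size}"
        )
    return dvec


def bayes_loss(post: PosteriorMatrix, D: DensityMap, cfg: LossConfig) -> float:
    """Bayes loss: sum_n F(1 - E_n) with E_n the expected count of point n."""
    if post.has_background:
        raise ValueError("bayes_loss expects a posterior without background row")
    dvec = _check_shapes(post, D)
    expected = post.probs @ dvec
    return float(cfg.penalty(1.0 - expected).sum())


def bayes_plus_loss(post: PosteriorMatrix, D: DensityMap, cfg: LossConfig) -> float:
    """Bayes+ loss: annotation terms target 1, the background term targets 0.

    ``sum_{n>=1} F(1 - E_n) + F(0 - E_0)`` where E_0 is the density mass the
    posterior assigns to the dummy background label.
    """
    if not post.has_background:
        raise ValueError("bayes_plus_loss expects a background-augmented posterior")
    dvec = _check_shapes(post, D)
    expected = post.probs @ dvec  # row 0 = background
    fg = cfg.penalty(1.0 - expected[1:]).sum()
    bg = cfg.penalty(np.asarray(0.0 - expected[0]))
    return float(fg + np.sum(bg))


def bayes_loss_and_grad(
    post: PosteriorMatrix | None, D: DensityMap, cfg: LossConfig
) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the density map (l1 penalty).

    ``post is None`` encodes an image with no annotations: the loss becomes
    F(0 - total density), pushing the network toward an empty map.
    """
    dvec = D.values.ravel()
    if post is None:
        total = dvec.sum()
        grad = np.sign(total) * np.ones_like(D.values)
        return float(abs(total)), grad
    dvec = _check_shapes(post, D)
    expected = post.probs @ dvec
    targets = np.ones_like(expected)
    if post.has_background:
        targets[0] = 0.0
    residual = targets - expected
    loss = float(np.abs(residual).sum())
    # d|t_n - p_n . D|/dD = -sign(t_n - p_n . D) p_n
    grad = -(np.sign(residual) @ post.probs).reshape(D.values.shape)
    return loss, grad
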