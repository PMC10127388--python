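"""Anatomy of the Bayesian point-supervision loss on a tiny grid.

Shows the per-cell label posterior, the expected count per annotation, and
how the Bayes/Bayes+ losses react to an empty map, a perfect map, and a
map with stray background mass.
"""

import numpy as np

from rapecount import (
    DensityMap,
    LossConfig,
    bayes_plus_loss,
    make_pixel_grid,
    posterior_from_points,
)

grid = make_pixel_grid(8, 8, 1)  # 8x8 density grid, stride 1
points = np.array([[2.0, 2.0], [6.0, 5.0]])  # two annotated clusters
cfg = LossConfig(sigma=1.0, background_ratio=0.5, use_background=True)
post = posterior_from_points(grid, points, cfg, points_in_pixels=False)

print(f"posterior: {post.probs.shape[0]} labels (background + 2 points) "
      f"x {post.m} cells; every column sums to "
      f"{post.probs.sum(axis=0).round(12).max()}")

empty = DensityMap(np.zeros((8, 8)))
print(f"\nempty map        -> loss {bayes_plus_loss(post, empty, cfg):.3f}"
      "   (= N: each annotation claims count 1, gets 0)")

perfect = np.zeros((8, 8))
perfect[2, 2] = 1.0  # row y, col x
perfect[5, 6] = 1.0
print(f"one unit at each -> loss "
      f"{bayes_plus_loss(post, DensityMap(perfect), cfg):.3f}"
      "   (mass lands where the posterior is ~pure foreground)")

stray = perfect.copy()
stray[7, 0] += 1.0  # far from both annotations: background-owned mass
print(f"plus stray mass  -> loss "
      f"{bayes_plus_loss(post, DensityMap(stray), cfg):.3f}"
      "   (the background term bills the extra unit)")
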