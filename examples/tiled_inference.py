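"""Canvas tiling and count aggregation on a full-size synthetic plot.

A 512x1024 plot canvas is split into eight 256x256 tiles, each tile is
predicted separately, and the per-tile counts add up to the total exactly.
The (untrained) model here demonstrates the plumbing; see
train_and_evaluate.py for a model that actually counts.
"""

from pathlib import Path

from PIL import Image

from rapecount import (
    SceneConfig,
    build_model,
    default_rapenet_config,
    generate_scene,
    predict_count,
    render_heatmap,
)

img, pts = generate_scene(SceneConfig(seed=3, count_range=(150, 150)))
model = build_model(default_rapenet_config(width_multiplier=0.25, seed=0))

count, density, per_tile = predict_count(img, model)
print(f"canvas {img.shape[0]}x{img.shape[1]} -> {len(per_tile)} tiles")
print("per-tile counts:", [round(c, 1) for c in per_tile])
print(f"total {count:.1f} = sum of tiles {sum(per_tile):.1f} "
      f"(true blob count {pts.n}; the model is untrained, so only the "
      "additivity is meaningful here)")

out = Path("scratch/example_overlay.png")
out.parent.mkdir(exist_ok=True)
Image.fromarray(render_heatmap(img, density, alpha=0.6)).save(out)
print(f"heat-map overlay -> {out}")
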