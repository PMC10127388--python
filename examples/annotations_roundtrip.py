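"""Box annotations to centroids: the low-cost-labeling conversion.

Rectangular boxes (LabelImg/Pascal VOC) are converted to the centroid dots
that density-map training consumes; rescaling shows how annotations follow
an image resize without changing the count.
"""

from rapecount import BoxAnnotationSet, boxes_to_centroids, rescale_points

boxes = BoxAnnotationSet(
    "plot_demo",
    ((10, 20, 30, 40), (100, 50, 140, 90), (200, 200, 230, 224)),
)
points = boxes_to_centroids(boxes)
print(f"{len(boxes)} boxes -> {points.n} centroids:")
for box, pt in zip(boxes.boxes, points.points):
    print(f"  box {box} -> center {pt}")

halved = rescale_points(points, 0.5, 0.5)
print(f"\nafter a 0.5x resize: {halved.points}")
print(f"count preserved: {halved.n} == {points.n}")
print("\nThe midpoint of each box is the dot a human annotator would have"
      " placed; N (the count) is invariant under conversion and rescaling.")
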