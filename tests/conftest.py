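import numpy as np
import pytest

from rapecount.synthetic import generate_scene, small_scene_config


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128x128 scene with its ground-truth centroids."""
    cfg = small_scene_config(seed=11)
    img, pts = generate_scene(cfg)
    return cfg, img, pts


@pytest.fixture()
def voc_xml(tmp_path):
    """A hand-written LabelImg-style VOC file with one box (10,20,30,40)."""
    text = """<annotation>
  <filename>plot_001.png</filename>
  <object><name>cluster</name>
    <bndbox><xmin>10</xmin><ymin>20</ymin><xmax>30</xmax><ymax>40</ymax></bndbox>
  </object>
</annotation>"""
    path = tmp_path / "plot_001.xml"
    path.write_text(text)
    return path
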