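import numpy as np
import pandas as pd
import pytest

import scenecue as s


@pytest.fixture
def toy_corpus():
    """Hand-enumerable corpus: kitchen = {sink,table},{sink,chair};
    bedroom = {bed,table},{bed,sink}; sink is an anchor in kitchens only."""
    scenes = pd.DataFrame({
        "scene_id": ["k1", "k2", "b1", "b2"],
        "category": ["kitchen", "kitchen", "bedroom", "bedroom"]})
    objects = pd.DataFrame([
        ("k1", "kitchen", "sink", True),
        ("k1", "kitchen", "table", False),
        ("k2", "kitchen", "sink", True),
        ("k2", "kitchen", "chair", False),
        ("b1", "bedroom", "bed", True),
        ("b1", "bedroom", "table", False),
        ("b2", "bedroom", "bed", True),
        ("b2", "bedroom", "sink", False),
    ], columns=["scene_id", "category", "object", "is_anchor"])
    return s.LabeledCorpus(scenes, objects)


@pytest.fixture
def toy_table(toy_corpus):
    return s.compute_score_table(toy_corpus)


def make_image_table(seed: int, n_img: int = 300) -> pd.DataFrame:
    """Stimulus image table at paper scale with z-scored scene scores."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "image_id": [f"i{i:04d}" for i in range(n_img)],
        "condition": ["real"] * (n_img // 2) + ["generated"] * (n_img // 2),
        "duration": ([50, 500] * (n_img // 2))[:n_img],
        "z_anchor": s.z_transform(rng.normal(size=n_img)),
        "z_diag": s.z_transform(rng.normal(size=n_img)),
    })


@pytest.fixture
def image_table():
    return make_image_table(0)
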