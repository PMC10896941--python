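import numpy as np
import pytest

from gasmil.staging import SlideGrades
from gasmil.tiling import Patch, TileRef


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_patch(pixels, mpp=0.5, row=0, col=0, slide_id="s0"):
    return Patch(TileRef(slide_id, mpp, row, col), pixels.astype(np.uint8))


@pytest.fixture
def pink_patch():
    """Uniform saturated pink tile: clearly tissue."""
    px = np.zeros((224, 224, 3), dtype=np.uint8)
    px[..., 0], px[..., 1], px[..., 2] = 230, 120, 170
    return make_patch(px)


@pytest.fixture
def white_patch():
    return make_patch(np.full((224, 224, 3), 255, dtype=np.uint8))


def feature_mil_bags(n_bags=60, n_instances=24, lesion_frac=0.15, dim=16, seed=3,
                     n_train=36, n_val=12):
    """Small embedding-space bags wrapped as gasmil Bags with splits."""
    from gasmil.mil import Bag
    from gasmil.synthetic import generate_feature_bags

    xs, labels, masks = generate_feature_bags(
        n_bags=n_bags, n_instances=n_instances, lesion_frac=lesion_frac,
        dim=dim, seed=seed)
    bags = []
    for i, (x, y) in enumerate(zip(xs, labels)):
        split = "train" if i < n_train else ("val" if i < n_train + n_val else "test")
        refs = [TileRef(f"b{i}", 0.5, j // 8, j % 8) for j in range(len(x))]
        bags.append(Bag(f"b{i}", x, refs, SlideGrades(0, 0, int(y), 0), split))
    return bags, masks
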