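import numpy as np
import pytest

import seedvision as sv


def region_from_mask(mask: np.ndarray, color=(200, 200, 200)) -> sv.SeedRegion:
    """Wrap a boolean mask into a single SeedRegion with a flat color."""
    frame = np.zeros(mask.shape + (3,), dtype=np.uint8)
    frame[mask] = color
    regions = sv.extract_regions(frame, mask, min_area=1)
    assert len(regions) == 1
    return regions[0]


def disk_mask(r: int, pad: int = 5) -> np.ndarray:
    n = 2 * (r + pad) + 1
    yy, xx = np.mgrid[:n, :n] - (r + pad)
    return yy ** 2 + xx ** 2 <= r * r


def rect_mask(h: int, w: int, pad: int = 5) -> np.ndarray:
    m = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    m[pad:pad + h, pad:pad + w] = True
    return m


def ellipse_mask(a: int, b: int, pad: int = 5) -> np.ndarray:
    yy, xx = np.mgrid[:2 * (b + pad) + 1, :2 * (a + pad) + 1]
    yy = yy - (b + pad)
    xx = xx - (a + pad)
    return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def small_dataset():
    """A small labeled feature table rendered through the real pipeline."""
    return sv.make_feature_dataset(30, 30, rng_seed=101)


@pytest.fixture(scope="session")
def trained_models(small_dataset):
    """Full-pool shape and color-texture nets for pipeline-level tests."""
    from seedvision.bpnn import TrainConfig, train_classifier
    from seedvision.features import COLORTEX_POOL, SHAPE_POOL

    df = small_dataset
    cfg = TrainConfig(rng_seed=7, max_epochs=2000)
    shape_cols = [SHAPE_POOL[i] for i in sorted(SHAPE_POOL)]
    ct_cols = [COLORTEX_POOL[i] for i in sorted(COLORTEX_POOL)]
    shape_model = train_classifier(
        df[shape_cols].to_numpy(float),
        ["good" if ok else "ng" for ok in df["shape_ok"]],
        cfg, feature_columns=shape_cols)
    ct_model = train_classifier(
        df[ct_cols].to_numpy(float),
        ["good" if ok else "ng" for ok in df["colortex_ok"]],
        cfg, feature_columns=ct_cols)
    return shape_model, ct_model
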