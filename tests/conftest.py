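"""Shared fixtures: small synthetic datasets and their wavelet features.

Session-scoped because feature extraction over a dataset is the expensive
step shared by the classifier and pipeline tests.
"""

import numpy as np
import pytest

import wavederm as wd


def extract_features(dataset, wavelet_id=1):
    base = wd.get_wavelet_base(wavelet_id)
    X = np.array([wd.feature_vector(img, base) for img, _ in dataset])
    y = np.array([label for _, label in dataset], dtype=int)
    return X, y


@pytest.fixture(scope="session")
def separable_dataset():
    """Strong band-limited class signal: effect size 8, 30 images per class."""
    spec = wd.TextureSpec(
        image_height=64, image_width=64, n_pos=30, n_neg=30, effect_size=8.0, seed=11
    )
    return wd.make_texture_dataset(spec)


@pytest.fixture(scope="session")
def separable_features(separable_dataset):
    return extract_features(separable_dataset)


@pytest.fixture(scope="session")
def null_dataset():
    """No class signal: effect size 0, identical sampling distributions."""
    spec = wd.TextureSpec(
        image_height=64, image_width=64, n_pos=25, n_neg=25, effect_size=0.0, seed=13
    )
    return wd.make_texture_dataset(spec)


@pytest.fixture(scope="session")
def null_features(null_dataset):
    return extract_features(null_dataset)
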