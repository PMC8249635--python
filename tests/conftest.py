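import numpy as np
import pytest

from tfts_lstm import features_from_image, generate_dataset
from tfts_lstm.synthetic import default_two_class_specs


@pytest.fixture(scope="session")
def two_grating_features():
    """Feature sequences for the default two-grating dataset (seed 7).

    40 images per class at 64 x 64 px; computed once per session since the
    end-to-end tests share them.
    """
    ds = generate_dataset(default_two_class_specs(), n_per_class=40, size=64, seed=7)
    return [
        features_from_image(img, label=lab, source_id=f"img{i}")
        for i, (img, lab) in enumerate(zip(ds.images, ds.labels))
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
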