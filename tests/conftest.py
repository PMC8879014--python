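import numpy as np
import pytest

from aquametal.preprocessing import fit_normalizer, normalize_frame, split_dataset
from aquametal.specs import FEATURES
from aquametal.synthetic import make_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def campaign():
    """One dry-season surface-water campaign, normalized and split."""
    dataset = make_dataset("dry", "surface", 80, seed=12345)
    frame = dataset.frame()
    split = split_dataset(80, seed=3)
    specs = fit_normalizer(frame)
    norm = normalize_frame(frame, specs)
    return {
        "dataset": dataset,
        "frame": frame,
        "split": split,
        "specs": specs,
        "norm": norm,
        "x": norm[list(FEATURES)].to_numpy(),
    }
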