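import numpy as np
import pytest

from qcnv import BinarySample, GenomicWindows


@pytest.fixture
def windows4() -> GenomicWindows:
    return GenomicWindows.tiles(4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def random_instance(rng: np.random.Generator, n_features: int, w: int):
    """Random binary test + equal-W two-class training set.

    The test avoids the all-zero profile (the AIP encoding of an empty
    profile is degenerate) and each class avoids an all-zero column sum.
    """
    while True:
        test = rng.integers(0, 2, size=n_features)
        if test.any():
            break
    classes = []
    for k in range(2):
        while True:
            bits = rng.integers(0, 2, size=(w, n_features))
            if bits.sum(axis=0).any():
                break
        classes.append([BinarySample(f"s{k}_{i}", b, label=k) for i, b in enumerate(bits)])
    return BinarySample("test", test), classes
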