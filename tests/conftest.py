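import numpy as np
import pandas as pd
import pytest

from msikit.dataset import MSIDataset, grid_pixels
from msikit.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """12x12 phantom with 3 segments + background, mild noise, no drift."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture()
def random_dataset():
    """Dense random 50-feature x 200-pixel continuous dataset."""
    rng = np.random.default_rng(7)
    mz = np.linspace(100.0, 200.0, 50)
    X = rng.gamma(2.0, 1.0, size=(50, 200))
    pixels = grid_pixels(20, 10)
    return MSIDataset(intensities=X, mz=mz, pixels=pixels)


def make_dataset(X, mz=None, width=None, run="run0", centroided=False,
                 pixels=None):
    X = np.asarray(X, dtype=float)
    if mz is None:
        mz = np.arange(1, X.shape[0] + 1, dtype=float)
    if pixels is None:
        n = X.shape[1]
        width = width or n
        height = int(np.ceil(n / width))
        pixels = grid_pixels(width, height).iloc[:n].reset_index(drop=True)
    return MSIDataset(intensities=X, mz=np.asarray(mz, float), pixels=pixels,
                      centroided=centroided)
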