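from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import erpsnn


@dataclass(frozen=True)
class ToyMontage:
    """Minimal montage stand-in for reservoir unit tests."""

    channels: tuple
    coords: np.ndarray


@pytest.fixture(scope="session")
def montage():
    return erpsnn.load_montage()


@pytest.fixture(scope="session")
def grid_full():
    return erpsnn.NeuronGrid.from_fixture()


@pytest.fixture(scope="session")
def grid_small(grid_full):
    return grid_full.subsample(200, seed=0)


@pytest.fixture(scope="session")
def swc_small():
    """Wiring settings matched to the coarser subsampled lattice."""
    return erpsnn.SWCConfig(radius_mm=40.0, base_prob=0.3, seed=1)


def toy_montage(coords, labels=None):
    coords = np.asarray(coords, dtype=float)
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(len(coords)))
    return ToyMontage(channels=tuple(labels), coords=coords)


@pytest.fixture
def toy_regions():
    """Two-channel region map: one left-frontal, one right-occipitoparietal."""
    return pd.DataFrame(
        {"site": ["frontal", "occipitoparietal"], "hemisphere": ["left", "right"]},
        index=pd.Index(["ch0", "ch1"], name="label"),
    )
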