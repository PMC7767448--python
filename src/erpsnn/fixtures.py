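"""Packaged, versioned fixtures: neuron grid, electrode montage, region map.

Three text fixtures ship with the package:

``grid1471``
    A synthetic 1 cm cubic lattice of 1471 sites filling a brain-proportioned
    ellipsoid in a Talairach-like frame (x right, y anterior, z superior, mm).
    It stands in for the published 1471-site Talairach atlas grid used by
    NeuCube-style models, which is not redistributable here; only the site
    count and the 1 cm spacing are reproduced, not the atlas geometry.
``montage62``
    The 62-channel 10-20/10-10 cap (FP1 ... CB2) with 3D scalp coordinates in
    the same frame, exported from a standard 10-05 electrode table. CB1/CB2
    (NeuroScan cap names) take the PO9/PO10 positions.
``regions_fig5``
    The five-site x hemisphere scalp parcellation used for the connectivity
    statistics: frontal, frontocentral, temporal, centroparietal and
    occipitoparietal, split left/right, with the 8 midline channels
    (FPZ, FZ, FCZ, CZ, CPZ, PZ, POZ, OZ) marked ``midline``.

Every load verifies the file's SHA-256 against the packaged manifest.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FixtureIntegrityError",
    "MontageFixture",
    "load_fixture",
    "load_grid",
    "load_montage",
    "load_regions",
]

_FIXTURES = ("grid1471", "montage62", "regions_fig5")


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture does not match its manifest checksum."""


@dataclass(frozen=True)
class MontageFixture:
    """The 62-channel montage bundled with its region map.

    Attributes
    ----------
    channels : list of str
        Channel labels in the canonical acquisition order.
    coords : ndarray, shape (62, 3)
        Scalp coordinates in mm (x right, y anterior, z superior).
    regions : pandas.DataFrame
        Indexed by channel label, columns ``site`` and ``hemisphere``.
    """

    channels: tuple
    coords: np.ndarray
    regions: pd.DataFrame

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def coord_of(self, label: str) -> np.ndarray:
        return self.coords[self.channels.index(label)]


def _read_bytes(filename: str) -> bytes:
    return resources.files("erpsnn.data").joinpath(filename).read_bytes()


def _manifest() -> dict:
    return json.loads(_read_bytes("manifest.json"))


def load_fixture(name: str):
    """Load a packaged fixture by name, verifying its checksum.

    Parameters
    ----------
    name : {"grid1471", "montage62", "regions_fig5"}

    Returns
    -------
    ndarray or pandas.DataFrame
        ``grid1471`` -> (1471, 3) float array of mm coordinates;
        ``montage62`` -> DataFrame with label index and x/y/z columns;
        ``regions_fig5`` -> DataFrame with label index, site, hemisphere.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {_FIXTURES}")
    entry = _manifest()["files"][name]
    raw = _read_bytes(entry["file"])
    digest = hashlib.sha256(raw).hexdigest()
    if digest != entry["sha256"]:
        raise FixtureIntegrityError(
            f"fixture {name!r} ({entry['file']}) checksum mismatch: "
            f"expected {entry['sha256']}, got {digest}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), sep="\t")
    if name == "grid1471":
        return df.to_numpy(dtype=float)
    return df.set_index("label")


def load_grid() -> np.ndarray:
    """The 1471-site neuron lattice as an (n, 3) mm coordinate array."""
    return load_fixture("grid1471")


def load_regions() -> pd.DataFrame:
    return load_fixture("regions_fig5")


def load_montage() -> MontageFixture:
    """Load channels, coordinates and region map as one object."""
    mont = load_fixture("montage62")
    regions = load_regions()
    channels = tuple(mont.index)
    return MontageFixture(
        channels=channels,
        coords=mont[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        regions=regions.loc[list(channels)],
    )
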