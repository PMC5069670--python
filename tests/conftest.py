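"""Shared fixtures: small phantoms and projection sets reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

import slotkit as sk
from slotkit.core import Volume3D


@pytest.fixture(scope="session")
def lobe_phantom():
    """A 64^3 fibrotic lobe phantom (fast; ~0.5 s)."""
    params = sk.PhantomParams(
        shape=(64, 64, 64), voxel_size=30.0, fibrosis_fraction=0.1, seed=11
    )
    return sk.make_lobe_phantom(params)


@pytest.fixture(scope="session")
def disk_volume():
    """A centred uniform disk (radius = field/4) as a 2-row volume."""
    n = 128
    c = (n - 1) / 2
    zz, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    disk = ((zz**2 + xx**2) <= (n / 4) ** 2).astype(np.float32)
    return Volume3D(disk[:, None, :].repeat(2, axis=1), (1, 1, 1), "fluorescence")


@pytest.fixture(scope="session")
def blob_volume():
    """A smooth random blob confined to the inscribed circle (64^2 x 3 rows)."""
    from scipy import ndimage

    rng = np.random.default_rng(7)
    n = 64
    blob = ndimage.gaussian_filter(rng.random((n, 3, n)), (3, 0, 3)).astype(np.float32)
    zz, xx = np.meshgrid(np.arange(n) - (n - 1) / 2, np.arange(n) - (n - 1) / 2, indexing="ij")
    blob *= ((zz**2 + xx**2) <= (n / 2 - 6) ** 2)[:, None, :]
    return Volume3D(blob, (1.5, 1.5, 1.5), "fluorescence")


def nrmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error normalized by the dynamic range of b."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean((a - b) ** 2)) / (b.max() - b.min()))
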