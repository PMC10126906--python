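"""Shared fixtures: small phantoms and hand-built surface tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mechanostat import BinaryVolume, ScalarVolume
from mechanostat.remodel import TABLE_COLUMNS


def make_table(rows: list[tuple]) -> pd.DataFrame:
    """Surface table from (z, y, x, event, distance_vox, cluster_id, signal)."""
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def random_binary_pair(rng):
    """A random registered 8x8x8 baseline/follow-up pair with full mask."""
    baseline = (rng.random((8, 8, 8)) < 0.4).astype(np.uint8)
    followup = baseline.copy()
    flip = rng.random((8, 8, 8)) < 0.1
    followup[flip] = 1 - followup[flip]
    mask = np.ones((8, 8, 8), np.uint8)
    return (
        BinaryVolume(baseline, 10.5),
        BinaryVolume(followup, 10.5),
        BinaryVolume(mask, 10.5),
    )


@pytest.fixture
def slab_pair():
    """Flat slab (z < 6) with marrow above, full-domain mask."""
    shape = (16, 12, 12)
    bone = np.zeros(shape, np.uint8)
    bone[:6] = 1
    mask = np.ones(shape, np.uint8)
    return BinaryVolume(bone, 10.5), BinaryVolume(mask, 10.5)


def brute_force_taxicab(bone: np.ndarray) -> np.ndarray:
    """O(n^2) L1 distance to the nearest background voxel (OOB = background)."""
    fg = np.argwhere(bone)
    bg = np.argwhere(~bone.astype(bool))
    out = np.zeros(bone.shape, dtype=float)
    for p in fg:
        d_oob = min(
            min(p[a] + 1, bone.shape[a] - p[a]) for a in range(3)
        )
        if len(bg):
            d_bg = np.abs(bg - p).sum(axis=1).min()
            out[tuple(p)] = min(d_bg, d_oob)
        else:
            out[tuple(p)] = d_oob
    return out
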