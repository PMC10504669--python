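from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the brute oracle module

from spotdecode.core import Codebook, SpotTable


@pytest.fixture
def simple_codebook() -> Codebook:
    """4 rounds x 3 channels, 6 targets incl. 2 blanks, pairwise Hamming >= 2."""
    barcodes = np.array(
        [
            [0, 0, 0, 0],
            [1, 1, 1, 1],
            [2, 2, 2, 2],
            [0, 1, 2, 0],
            [1, 2, 0, 1],
            [2, 0, 1, 2],
        ]
    )
    names = ("geneA", "geneB", "geneC", "geneD", "blank_0", "blank_1")
    off = np.array([False, False, False, False, True, True])
    return Codebook(names, barcodes, off, n_channels=3)


@pytest.fixture
def tiny_spots() -> SpotTable:
    """Four co-located spots spelling geneD's barcode (0,1,2,0)."""
    df = pd.DataFrame(
        {
            "spot_id": [0, 1, 2, 3],
            "r": [0, 1, 2, 3],
            "c": [0, 1, 2, 0],
            "x": [5.0] * 4,
            "y": [5.0] * 4,
            "z": [0.0] * 4,
            "intensity": [1.0] * 4,
        }
    )
    return SpotTable(df, 10.0, 10.0)


def random_instance(rng, n_spots=10, n_rounds=4, n_channels=3, box=4.0):
    """A random small spot table as both row-dicts (for oracles) and SpotTable."""
    rows = []
    for sid in range(n_spots):
        rows.append(
            {
                "spot_id": sid,
                "r": int(rng.integers(0, n_rounds)),
                "c": int(rng.integers(0, n_channels)),
                "x": float(rng.uniform(0, box)),
                "y": float(rng.uniform(0, box)),
                "z": 0.0,
                "intensity": float(rng.uniform(0.2, 1.0)),
            }
        )
    # per-(r,c) max-normalized intensities, mirroring the decoder's convention
    maxes = {}
    for row in rows:
        key = (row["r"], row["c"])
        maxes[key] = max(maxes.get(key, 0.0), row["intensity"])
    for row in rows:
        row["intensity"] = row["intensity"] / maxes[(row["r"], row["c"])]
    table = SpotTable(pd.DataFrame(rows), box, box)
    return rows, table


def random_codebook(rng, n_rounds=4, n_channels=3, n_entries=5) -> Codebook:
    seen = set()
    while len(seen) < n_entries:
        seen.add(tuple(int(v) for v in rng.integers(0, n_channels, size=n_rounds)))
    rows = sorted(seen)
    names = tuple(f"t{i}" for i in range(len(rows)))
    return Codebook(names, np.array(rows), np.zeros(len(rows), bool), n_channels)
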