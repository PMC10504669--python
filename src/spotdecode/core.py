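"""Domain types and I/O: codebooks, spot tables, pseudoround remapping.

Coordinates are continuous physical units with the origin at the field-of-view
corner; ``z`` may be constant for 2D experiments.  Channel and round indices
are 0-based everywhere, in memory and on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SPOT_COLUMNS = ["spot_id", "r", "c", "x", "y", "z", "intensity"]

TRANSCRIPT_COLUMNS = [
    "target",
    "x",
    "y",
    "z",
    "rounds_used",
    "source_spot_ids",
    "is_off_target",
    "cell_id",
]


# ---------------------------------------------------------------------------
# Codebook
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Codebook:
    """A mapping from target names to per-round channel sequences.

    Parameters
    ----------
    targets
        Target names, one per entry.
    barcodes
        Integer array of shape ``(n_entries, n_rounds)``; ``barcodes[i, r]``
        is the channel lit in round ``r`` for target ``i``.  Every round of
        every barcode has a channel assigned (no "off" rounds).
    is_off_target
        Boolean flags; ``True`` marks blank/off-target entries that have no
        physical probe — any call to them is a false positive by construction.
    n_channels
        Number of fluorescence channels per round.
    """

    targets: tuple[str, ...]
    barcodes: np.ndarray
    is_off_target: np.ndarray
    n_channels: int

    def __post_init__(self) -> None:
        barcodes = np.asarray(self.barcodes, dtype=np.int64)
        off = np.asarray(self.is_off_target, dtype=bool)
        object.__setattr__(self, "targets", tuple(str(t) for t in self.targets))
        object.__setattr__(self, "barcodes", barcodes)
        object.__setattr__(self, "is_off_target", off)
        if barcodes.ndim != 2 or barcodes.shape[0] != len(self.targets):
            raise ValueError("barcodes must be (n_entries, n_rounds)")
        if off.shape != (len(self.targets),):
            raise ValueError("is_off_target must have one flag per entry")
        if len(self.targets) != len(set(self.targets)):
            raise ValueError("duplicate target names in codebook")
        if barcodes.size and (barcodes.min() < 0 or barcodes.max() >= self.n_channels):
            raise ValueError("channel indices must lie in [0, n_channels)")
        seen = {tuple(row) for row in barcodes}
        if len(seen) != barcodes.shape[0]:
            raise ValueError("barcodes are not unique across entries")

    @property
    def n_rounds(self) -> int:
        return self.barcodes.shape[1]

    def __len__(self) -> int:
        return len(self.targets)

    def barcode_of(self, target: str) -> tuple[int, ...]:
        idx = self.targets.index(target)
        return tuple(int(v) for v in self.barcodes[idx])

    def exact_lookup(self) -> dict[tuple[int, ...], int]:
        """Map each full-length channel sequence to its entry index."""
        return {tuple(int(v) for v in row): i for i, row in enumerate(self.barcodes)}

    def partial_lookup(self) -> dict[tuple[int, tuple[int, ...]], int]:
        """Map ``(dropped_round, partial sequence)`` to an entry index.

        Only partial sequences consistent with exactly one codebook entry are
        retained; a partial seen from two entries cannot identify either and
        is removed.
        """
        table: dict[tuple[int, tuple[int, ...]], int | None] = {}
        for i, row in enumerate(self.barcodes):
            full = tuple(int(v) for v in row)
            for dropped in range(self.n_rounds):
                key = (dropped, full[:dropped] + full[dropped + 1 :])
                table[key] = i if key not in table else None
        return {k: v for k, v in table.items() if v is not None}

    # -- serialization ------------------------------------------------------

    def to_spacetx_json(self, path) -> None:
        mappings = []
        for name, row, off in zip(self.targets, self.barcodes, self.is_off_target):
            codeword = [{"r": int(r), "c": int(c), "v": 1} for r, c in enumerate(row)]
            mappings.append(
                {"codeword": codeword, "target": name, "off_target": bool(off)}
            )
        doc = {
            "version": "0.0.0",
            "n_rounds": int(self.n_rounds),
            "n_channels": int(self.n_channels),
            "mappings": mappings,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_spacetx_json(cls, path) -> "Codebook":
        with open(path) as fh:
            doc = json.load(fh)
        mappings = doc["mappings"]
        n_rounds = int(
            doc.get(
                "n_rounds",
                max(e["r"] for m in mappings for e in m["codeword"]) + 1,
            )
        )
        n_channels = int(
            doc.get(
                "n_channels",
                max(e["c"] for m in mappings for e in m["codeword"]) + 1,
            )
        )
        targets, rows, off = [], [], []
        for m in mappings:
            row = np.full(n_rounds, -1, dtype=np.int64)
            for entry in m["codeword"]:
                if entry.get("v", 1):
                    row[int(entry["r"])] = int(entry["c"])
            if (row < 0).any():
                raise ValueError(
                    f"target {m['target']!r} has an off round; "
                    "every round must have a channel assigned"
                )
            targets.append(m["target"])
            rows.append(row)
            off.append(bool(m.get("off_target", False)))
        return cls(tuple(targets), np.array(rows), np.array(off), n_channels)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("target\tbarcode\toff_target\n")
            for name, row, off in zip(self.targets, self.barcodes, self.is_off_target):
                seq = ",".join(str(int(c)) for c in row)
                fh.write(f"{name}\t{seq}\t{int(off)}\n")

    @classmethod
    def from_tsv(cls, path, n_channels: int | None = None) -> "Codebook":
        df = pd.read_csv(path, sep="\t", dtype={"target": str})
        rows = [
            np.array([int(v) for v in seq.split(",")], dtype=np.int64)
            for seq in df["barcode"]
        ]
        barcodes = np.array(rows)
        if n_channels is None:
            n_channels = int(barcodes.max()) + 1
        return cls(
            tuple(df["target"]),
            barcodes,
            df["off_target"].astype(bool).to_numpy(),
            n_channels,
        )


def hamming_distance(a: Sequence[int], b: Sequence[int]) -> int:
    """Number of rounds at which two barcodes assign different channels."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"barcode length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


def min_pairwise_hamming(codebook: Codebook) -> int:
    """Minimum Hamming distance over all unordered pairs of entries."""
    n = len(codebook)
    if n < 2:
        raise ValueError("need at least 2 codebook entries")
    barcodes = codebook.barcodes
    best = codebook.n_rounds
    for i in range(n - 1):
        diff = np.count_nonzero(barcodes[i + 1 :] != barcodes[i], axis=1)
        best = min(best, int(diff.min()))
        if best == 0:
            break
    return best


def insert_off_target_barcodes(
    codebook: Codebook,
    count: int,
    min_distance: int,
    seed: int,
    max_tries_per_code: int = 10_000,
) -> Codebook:
    """Append ``count`` blank barcodes at Hamming distance >= ``min_distance``.

    Candidates are sampled uniformly at random with rejection; the constraint
    applies against the existing codes and against previously inserted blanks.
    Deterministic under ``seed``.
    """
    if count == 0:
        return codebook
    if count < 0:
        raise ValueError("count must be non-negative")
    rng = np.random.default_rng(seed)
    existing = [row.copy() for row in codebook.barcodes]
    inserted: list[np.ndarray] = []
    for k in range(count):
        placed = False
        for _ in range(max_tries_per_code):
            cand = rng.integers(0, codebook.n_channels, size=codebook.n_rounds)
            pool = existing + inserted
            dists = np.count_nonzero(np.array(pool) != cand, axis=1)
            if dists.min() >= min_distance:
                inserted.append(cand.astype(np.int64))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {count} off-target barcodes at distance "
                f">={min_distance}; only {k} fit in the remaining space"
            )
    names = _fresh_names("blank", count, set(codebook.targets))
    return Codebook(
        codebook.targets + tuple(names),
        np.vstack([codebook.barcodes] + inserted),
        np.concatenate([codebook.is_off_target, np.ones(count, dtype=bool)]),
        codebook.n_channels,
    )


def _fresh_names(prefix: str, count: int, taken: set[str]) -> list[str]:
    names, i = [], 0
    while len(names) < count:
        name = f"{prefix}_{i:03d}"
        if name not in taken:
            names.append(name)
        i += 1
    return names


# ---------------------------------------------------------------------------
# Spot table
# ---------------------------------------------------------------------------


@dataclass
class SpotTable:
    """Detected fluorescent spots plus the field-of-view extent.

    ``data`` holds one row per spot with columns ``spot_id, r, c, x, y, z,
    intensity``.  Intensities may be raw on input; :func:`normalize_intensities`
    rescales them to [0, 1] per (round, channel).
    """

    data: pd.DataFrame
    fov_width: float
    fov_height: float

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SPOT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"spot table missing columns: {missing}")
        if df["spot_id"].duplicated().any():
            raise ValueError("spot_id values must be unique")
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(coords).all():
            raise ValueError("spot coordinates must be finite")
        if self.fov_width <= 0 or self.fov_height <= 0:
            raise ValueError("field-of-view dimensions must be positive")
        self.data = df[SPOT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_rounds(self) -> int:
        return int(self.data["r"].max()) + 1 if len(self.data) else 0

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fov_width={self.fov_width} fov_height={self.fov_height}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path, fov_width: float | None = None, fov_height: float | None = None) -> "SpotTable":
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                meta = dict(
                    tok.split("=") for tok in first.lstrip("#").split() if "=" in tok
                )
                fov_width = float(meta.get("fov_width", fov_width or 0))
                fov_height = float(meta.get("fov_height", fov_height or 0))
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        if not fov_width or not fov_height:
            raise ValueError("field-of-view dimensions not in file header or arguments")
        return cls(df, fov_width, fov_height)


def normalize_intensities(spots: SpotTable) -> SpotTable:
    """Divide each intensity by the per-(round, channel) maximum, clamp to [0,1].

    Idempotent: a table whose per-(round, channel) maxima are already 1 is
    returned unchanged.  Groups whose maximum is 0 are left at 0.
    """
    df = spots.data.copy()
    maxes = df.groupby(["r", "c"])["intensity"].transform("max")
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(maxes > 0, df["intensity"] / maxes, 0.0)
    df["intensity"] = np.clip(norm, 0.0, 1.0)
    return SpotTable(df, spots.fov_width, spots.fov_height)


# ---------------------------------------------------------------------------
# Pseudoround / pseudochannel remapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PseudoMap:
    """Injective relabeling of physical (round, channel) to (pseudoround, pseudochannel)."""

    mapping: Mapping[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        mapping = {tuple(k): tuple(v) for k, v in dict(self.mapping).items()}
        if len(set(mapping.values())) != len(mapping):
            raise ValueError("pseudomap must be injective")
        object.__setattr__(self, "mapping", mapping)

    @classmethod
    def identity(cls, pairs: Iterable[tuple[int, int]]) -> "PseudoMap":
        return cls({p: p for p in pairs})

    @classmethod
    def from_json(cls, path) -> "PseudoMap":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            {
                (int(e["r"]), int(e["c"])): (int(e["pr"]), int(e["pc"]))
                for e in doc["mapping"]
            }
        )

    def to_json(self, path) -> None:
        doc = {
            "mapping": [
                {"r": r, "c": c, "pr": pr, "pc": pc}
                for (r, c), (pr, pc) in sorted(self.mapping.items())
            ]
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def apply_pseudomap(spots: SpotTable, pmap: PseudoMap) -> SpotTable:
    """Relabel rounds/channels; ids, coordinates and intensities are untouched."""
    df = spots.data
    pairs = set(zip(df["r"].astype(int), df["c"].astype(int)))
    unmapped = sorted(pairs - set(pmap.mapping))
    if unmapped:
        raise ValueError(f"pseudomap does not cover (round, channel) pairs: {unmapped}")
    out = df.copy()
    keys = list(zip(df["r"].astype(int), df["c"].astype(int)))
    out["r"] = [pmap.mapping[k][0] for k in keys]
    out["c"] = [pmap.mapping[k][1] for k in keys]
    return SpotTable(out, spots.fov_width, spots.fov_height)


# ---------------------------------------------------------------------------
# Decoded transcript table helpers
# ---------------------------------------------------------------------------


def write_transcripts(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["source_spot_ids"] = [
        ";".join(str(int(s)) for s in sorted(ids)) for ids in out["source_spot_ids"]
    ]
    out.to_csv(path, index=False)


def read_transcripts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["source_spot_ids"] = [
        tuple(int(tok) for tok in str(v).split(";")) if not pd.isna(v) and str(v) else ()
        for v in df["source_spot_ids"]
    ]
    return df
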