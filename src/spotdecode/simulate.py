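"""Synthetic multiplexed-FISH spot data with known ground truth.

Each simulated transcript is placed in the field of view and emits one spot
per imaging round at its barcode's channel, displaced by isotropic Gaussian
drift; rounds drop out independently, intensities are noisy, and spurious
background spots are added per round at a Poisson rate.  Everything is
deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from spotdecode.core import Codebook, SpotTable


def generate_codebook(
    n_targets: int,
    n_rounds: int,
    n_channels: int,
    min_hamming: int = 1,
    seed: int = 0,
    include_off_target: int = 0,
    max_tries: int = 200_000,
) -> Codebook:
    """Random codebook with pairwise Hamming distance >= ``min_hamming``.

    ``include_off_target`` extra entries are generated under the same
    constraint and flagged as blanks.
    """
    total = n_targets + include_off_target
    if total > n_channels**n_rounds:
        raise ValueError(
            f"cannot fit {total} unique barcodes in {n_channels}^{n_rounds} codes"
        )
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    tries = 0
    while len(rows) < total:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"codebook generation stalled after {max_tries} tries; "
                f"placed {len(rows)}/{total} codes at distance >={min_hamming}"
            )
        cand = rng.integers(0, n_channels, size=n_rounds)
        if rows:
            dists = np.count_nonzero(np.array(rows) != cand, axis=1)
            if dists.min() < min_hamming:
                continue
        rows.append(cand.astype(np.int64))
    names = [f"gene_{i:03d}" for i in range(n_targets)] + [
        f"blank_{i:03d}" for i in range(include_off_target)
    ]
    flags = np.array([False] * n_targets + [True] * include_off_target)
    return Codebook(tuple(names), np.array(rows), flags, n_channels)


@dataclass
class SimulationConfig:
    """Parameters for one synthetic field of view."""

    n_transcripts: int
    fov_width: float
    fov_height: float
    seed: int
    drift_sigma: float = 0.0
    dropout_rate: float = 0.0
    noise_spot_rate: float = 0.0  # spurious spots per round per unit area
    intensity_mean: float = 0.8
    intensity_sd: float = 0.1
    clustering: str = "none"  # "none" | "gaussian"
    n_clusters: int = 5
    cluster_sigma: float = 5.0
    n_cells_x: int = 0  # >0 enables grid-of-cells id assignment
    n_cells_y: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.noise_spot_rate < 0 or self.drift_sigma < 0:
            raise ValueError("rates and sigmas must be non-negative")
        if self.fov_width <= 0 or self.fov_height <= 0:
            raise ValueError("field-of-view dimensions must be positive")
        if self.clustering not in ("none", "gaussian"):
            raise ValueError("clustering must be 'none' or 'gaussian'")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


@dataclass
class GroundTruth:
    """Per-transcript truth: target, true position, emitted spots, dropped rounds."""

    records: pd.DataFrame  # transcript_id, target, x, y, z, dropped_rounds
    spot_origin: dict[int, int]  # spot_id -> transcript_id (noise spots absent)

    def write_csv(self, path) -> None:
        out = self.records.copy()
        out["dropped_rounds"] = [
            ";".join(str(r) for r in rounds) for rounds in out["dropped_rounds"]
        ]
        spot_ids = {tid: [] for tid in out["transcript_id"]}
        for sid, tid in self.spot_origin.items():
            spot_ids[tid].append(sid)
        out["spot_ids"] = [
            ";".join(str(s) for s in sorted(spot_ids[tid]))
            for tid in out["transcript_id"]
        ]
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "GroundTruth":
        df = pd.read_csv(path)
        spot_origin = {}
        dropped = []
        for _, row in df.iterrows():
            ids = str(row["spot_ids"]) if not pd.isna(row["spot_ids"]) else ""
            for tok in ids.split(";"):
                if tok:
                    spot_origin[int(tok)] = int(row["transcript_id"])
            d = str(row["dropped_rounds"]) if not pd.isna(row["dropped_rounds"]) else ""
            dropped.append(tuple(int(t) for t in d.split(";") if t))
        df = df.drop(columns=["spot_ids"])
        df["dropped_rounds"] = dropped
        return cls(df, spot_origin)


def simulate(codebook: Codebook, config: SimulationConfig) -> tuple[SpotTable, GroundTruth]:
    """Generate a spot table and its ground truth from a codebook."""
    rng = np.random.default_rng(config.seed)
    n_rounds, n_channels = codebook.n_rounds, codebook.n_channels
    on_target = np.flatnonzero(~codebook.is_off_target)
    if on_target.size == 0:
        raise ValueError("codebook has no on-target entries to simulate")

    # transcript placement
    n = config.n_transcripts
    if config.clustering == "gaussian":
        centers = rng.uniform(
            [0, 0], [config.fov_width, config.fov_height], size=(config.n_clusters, 2)
        )
        which = rng.integers(0, config.n_clusters, size=n)
        xy = centers[which] + rng.normal(0.0, config.cluster_sigma, size=(n, 2))
        xy[:, 0] = np.clip(xy[:, 0], 0, config.fov_width)
        xy[:, 1] = np.clip(xy[:, 1], 0, config.fov_height)
    else:
        xy = rng.uniform([0, 0], [config.fov_width, config.fov_height], size=(n, 2))
    entry_idx = on_target[rng.integers(0, on_target.size, size=n)]

    spot_rows = []
    truth_rows = []
    spot_origin: dict[int, int] = {}
    next_id = 0
    for tid in range(n):
        barcode = codebook.barcodes[entry_idx[tid]]
        dropped = []
        for rnd in range(n_rounds):
            if rng.random() < config.dropout_rate:
                dropped.append(rnd)
                continue
            drift = (
                rng.normal(0.0, config.drift_sigma, size=2)
                if config.drift_sigma > 0
                else np.zeros(2)
            )
            intensity = float(
                np.clip(rng.normal(config.intensity_mean, config.intensity_sd), 0, 1)
            )
            spot_rows.append(
                (
                    next_id,
                    rnd,
                    int(barcode[rnd]),
                    float(xy[tid, 0] + drift[0]),
                    float(xy[tid, 1] + drift[1]),
                    0.0,
                    intensity,
                )
            )
            spot_origin[next_id] = tid
            next_id += 1
        truth_rows.append(
            {
                "transcript_id": tid,
                "target": codebook.targets[entry_idx[tid]],
                "x": float(xy[tid, 0]),
                "y": float(xy[tid, 1]),
                "z": 0.0,
                "dropped_rounds": tuple(dropped),
            }
        )

    # spurious background spots
    area = config.fov_width * config.fov_height
    for rnd in range(n_rounds):
        k = rng.poisson(config.noise_spot_rate * area)
        for _ in range(k):
            spot_rows.append(
                (
                    next_id,
                    rnd,
                    int(rng.integers(0, n_channels)),
                    float(rng.uniform(0, config.fov_width)),
                    float(rng.uniform(0, config.fov_height)),
                    0.0,
                    float(
                        np.clip(
                            rng.normal(config.intensity_mean, config.intensity_sd), 0, 1
                        )
                    ),
                )
            )
            next_id += 1

    spots = SpotTable(
        pd.DataFrame(
            spot_rows, columns=["spot_id", "r", "c", "x", "y", "z", "intensity"]
        ),
        config.fov_width,
        config.fov_height,
    )
    truth = GroundTruth(pd.DataFrame(truth_rows), spot_origin)
    return spots, truth


def assign_cells_grid(
    table: pd.DataFrame, fov_width: float, fov_height: float, nx: int, ny: int
) -> pd.DataFrame:
    """Assign cell ids from an nx-by-ny grid over the field of view."""
    out = table.copy()
    ix = np.clip((out["x"] / fov_width * nx).astype(int), 0, nx - 1)
    iy = np.clip((out["y"] / fov_height * ny).astype(int), 0, ny - 1)
    out["cell_id"] = (iy * nx + ix).astype(float)
    return out


def evaluate_decoding(
    decoded: pd.DataFrame,
    truth: GroundTruth,
    match_radius: float,
    n_rounds: int | None = None,
) -> dict:
    """Precision/recall of a decoded table against ground truth.

    A decoded record is a true positive iff an unmatched ground-truth
    transcript of the same target lies within ``match_radius`` (greedy
    nearest matching, processed in increasing match-distance order).  An
    empty decoded table reports precision 1.0 with ``zero_calls=True``.
    """
    truth_df = truth.records
    n_truth = len(truth_df)
    if len(decoded) == 0:
        return {
            "precision": 1.0,
            "recall": 0.0,
            "tp": 0,
            "fp": 0,
            "n_truth": n_truth,
            "zero_calls": True,
        }
    pairs = []  # (distance, decoded_idx, truth_idx)
    for d_idx, drow in decoded.reset_index(drop=True).iterrows():
        same = truth_df[truth_df["target"] == drow["target"]]
        if same.empty:
            continue
        d = np.hypot(same["x"] - drow["x"], same["y"] - drow["y"])
        for t_idx, dist in zip(same.index, d):
            if dist <= match_radius:
                pairs.append((float(dist), int(d_idx), int(t_idx)))
    pairs.sort()
    matched_decoded: set[int] = set()
    matched_truth: set[int] = set()
    for dist, d_idx, t_idx in pairs:
        if d_idx in matched_decoded or t_idx in matched_truth:
            continue
        matched_decoded.add(d_idx)
        matched_truth.add(t_idx)
    tp = len(matched_decoded)
    fp = len(decoded) - tp
    out = {
        "precision": tp / len(decoded),
        "recall": tp / n_truth if n_truth else 0.0,
        "tp": tp,
        "fp": fp,
        "n_truth": n_truth,
        "zero_calls": False,
    }
    if n_rounds is not None and "rounds_used" in decoded:
        full = decoded["rounds_used"] == n_rounds
        out["n_non_corrected"] = int(full.sum())
        out["n_corrected"] = int((~full).sum())
    return out


def add_multiplicative_gaussian_noise(
    values: Sequence[float],
    mean: float = 1.5,
    variance: float = 3.0,
    seed: int = 0,
    clamp: bool = True,
) -> np.ndarray:
    """v -> v + n*v with n ~ Normal(mean, sqrt(variance)), elementwise.

    With ``clamp`` (the default) negative outputs are set to 0, as negative
    intensities are meaningless; disable it to study the raw noise moments.
    """
    if variance < 0:
        raise ValueError("variance must be non-negative")
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("inputs must be finite")
    rng = np.random.default_rng(seed)
    n = rng.normal(mean, np.sqrt(variance), size=values.shape)
    out = values + n * values
    return np.clip(out, 0.0, None) if clamp else out


def drop_one_round_per_transcript(
    spots: SpotTable, truth: GroundTruth, seed: int = 0
) -> tuple[SpotTable, GroundTruth]:
    """Delete exactly one emitted spot (one round) from every transcript.

    Produces the canonical error-correction scenario: every transcript is
    left with a partial barcode missing a single round.  Transcripts that
    already dropped rounds are left untouched.
    """
    rng = np.random.default_rng(seed)
    by_transcript: dict[int, list[int]] = {}
    for sid, tid in truth.spot_origin.items():
        by_transcript.setdefault(tid, []).append(sid)
    doomed = set()
    for tid in sorted(by_transcript):
        if tuple(truth.records.loc[truth.records["transcript_id"] == tid, "dropped_rounds"].iloc[0]):
            continue
        doomed.add(int(rng.choice(sorted(by_transcript[tid]))))
    keep = ~spots.data["spot_id"].isin(doomed)
    new_spots = SpotTable(spots.data[keep], spots.fov_width, spots.fov_height)
    lookup = spots.data.set_index("spot_id")["r"]
    records = truth.records.copy()
    dropped_col = []
    for _, row in records.iterrows():
        extra = [
            int(lookup.at[sid])
            for sid in by_transcript.get(int(row["transcript_id"]), [])
            if sid in doomed
        ]
        dropped_col.append(tuple(sorted(tuple(row["dropped_rounds"]) + tuple(extra))))
    records["dropped_rounds"] = dropped_col
    origin = {s: t for s, t in truth.spot_origin.items() if s not in doomed}
    return new_spots, GroundTruth(records, origin)
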