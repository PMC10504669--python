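"""Automated quality-control metrics for decoded transcript tables.

Metrics operate on a decoded transcript table (see
:func:`spotdecode.decoder.decode`), the spot table it was decoded from, and
the codebook.  All count metrics are computed per field of view and for all
fields combined; records lacking a cell assignment are excluded from the
per-cell metrics only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import pdist
from scipy.stats import skew

from spotdecode.core import Codebook, SpotTable

# upper end of a two-tailed 95% normal confidence interval
Z_95 = 1.959964


def _sd(values: np.ndarray, sample: bool = True) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1 if sample else 0))


# ---------------------------------------------------------------------------
# 1. off-target count threshold
# ---------------------------------------------------------------------------


def offtarget_count_threshold(
    transcripts: pd.DataFrame, codebook: Codebook, sample_sd: bool = True
) -> dict:
    """Suggested on-target count cutoff from the off-target count distribution.

    The cutoff is mean + 1.959964*sd of the per-off-target-barcode counts,
    computed once over non-corrected calls only and once over non-corrected
    plus error-corrected calls.  Codebook entries with zero calls count as 0.
    """
    off_targets = [t for t, o in zip(codebook.targets, codebook.is_off_target) if o]
    if len(off_targets) < 2:
        raise ValueError("need at least 2 off-target codebook entries")
    n_rounds = codebook.n_rounds

    def counts(frame: pd.DataFrame) -> np.ndarray:
        tally = frame["target"].value_counts()
        return np.array([tally.get(t, 0) for t in off_targets], dtype=float)

    nc = transcripts[transcripts["rounds_used"] == n_rounds]
    out = {}
    for label, frame in (("nc", nc), ("nc_ec", transcripts)):
        c = counts(frame)
        out[f"threshold_{label}"] = float(c.mean() + Z_95 * _sd(c, sample_sd))
        out[f"offtarget_counts_{label}"] = {t: int(v) for t, v in zip(off_targets, c)}
    on_targets = [t for t, o in zip(codebook.targets, codebook.is_off_target) if not o]
    tally = transcripts["target"].value_counts()
    out["on_target_above_cutoff"] = {
        t: bool(tally.get(t, 0) > out["threshold_nc_ec"]) for t in on_targets
    }
    return out


# ---------------------------------------------------------------------------
# 2. per-cell false-positive rate
# ---------------------------------------------------------------------------


def false_positive_rate_per_cell(transcripts: pd.DataFrame) -> dict:
    """Per cell, FPR = off-target calls / all calls; cells with no calls excluded."""
    assigned = transcripts.dropna(subset=["cell_id"])
    if assigned.empty:
        raise ValueError("no transcripts carry a cell assignment")
    per_cell = {}
    for cell_id, grp in assigned.groupby("cell_id"):
        n_off = int(grp["is_off_target"].sum())
        per_cell[int(cell_id)] = n_off / len(grp)
    values = np.array(list(per_cell.values()))
    return {
        "per_cell": per_cell,
        "mean": float(values.mean()),
        "median": float(np.median(values)),
    }


# ---------------------------------------------------------------------------
# 3-6. tally moments over rounds / channels
# ---------------------------------------------------------------------------


def _tally_stats(counts: pd.Series, n_bins: int) -> dict:
    tally = np.array([int(counts.get(i, 0)) for i in range(n_bins)])
    if len(tally) > 2 and np.ptp(tally) > 0:
        skewness = float(skew(tally, bias=False))
    else:
        skewness = 0.0  # constant tallies: skew defined as 0
    return {
        "counts": tally.tolist(),
        "std": _sd(tally),
        "skew": skewness,
    }


def spots_per_round_stats(spots: SpotTable, n_rounds: int) -> dict:
    if len(spots) == 0:
        raise ValueError("empty spot table")
    return _tally_stats(spots.data["r"].value_counts(), n_rounds)


def spots_per_channel_stats(spots: SpotTable, n_channels: int) -> dict:
    if len(spots) == 0:
        raise ValueError("empty spot table")
    return _tally_stats(spots.data["c"].value_counts(), n_channels)


def _source_spot_labels(
    transcripts: pd.DataFrame, spots: SpotTable, column: str
) -> pd.Series:
    lookup = spots.data.set_index("spot_id")[column]
    labels = []
    for ids in transcripts["source_spot_ids"]:
        for sid in ids:
            if sid not in lookup.index:
                raise ValueError(f"source spot id {sid} not present in spot table")
            labels.append(int(lookup.at[sid]))
    return pd.Series(labels, dtype=int)


def source_spot_round_stats(
    transcripts: pd.DataFrame, spots: SpotTable, n_rounds: int
) -> dict:
    """Tally of the rounds contributing member spots to decoded transcripts."""
    labels = _source_spot_labels(transcripts, spots, "r")
    return _tally_stats(labels.value_counts(), n_rounds)


def source_spot_channel_stats(
    transcripts: pd.DataFrame, spots: SpotTable, n_channels: int
) -> dict:
    labels = _source_spot_labels(transcripts, spots, "c")
    return _tally_stats(labels.value_counts(), n_channels)


# ---------------------------------------------------------------------------
# 7. transcripts per cell
# ---------------------------------------------------------------------------


def transcripts_per_cell_cutoff(transcripts: pd.DataFrame) -> dict:
    """Flag cells with counts below median - 1.5*(Q3 - Q1)."""
    assigned = transcripts.dropna(subset=["cell_id"])
    if assigned.empty:
        raise ValueError("no transcripts carry a cell assignment")
    counts = assigned.groupby("cell_id").size()
    q1, med, q3 = np.percentile(counts.to_numpy(), [25, 50, 75])
    cutoff = med - 1.5 * (q3 - q1)
    flagged = sorted(int(c) for c, n in counts.items() if n < cutoff)
    return {
        "per_cell_counts": {int(c): int(n) for c, n in counts.items()},
        "cutoff": float(cutoff),
        "flagged_cells": flagged,
    }


# ---------------------------------------------------------------------------
# 8. Ripley's K spatial homogeneity test
# ---------------------------------------------------------------------------


def ripley_k(points: np.ndarray, area: float, radii: np.ndarray) -> np.ndarray:
    """Raw (uncorrected) Ripley K estimate at each radius for a 2D pattern."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    dists = pdist(points)
    # each unordered pair counts twice in the i != j double sum
    counts = np.array([2 * np.count_nonzero(dists <= r) for r in radii], dtype=float)
    return area * counts / (n * (n - 1))


def ripley_k_csr_test(
    transcripts: pd.DataFrame,
    fov_dims: tuple[float, float],
    n_radii: int = 10,
    n_mc: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    max_radius: float | None = None,
) -> dict:
    """Monte-Carlo CSR envelope test on the decoded transcript positions.

    K is evaluated at ``n_radii`` radii from 0 to sqrt(area)/2 for the
    observed 2D pattern and for ``n_mc`` uniform-random patterns of the same
    size in the same window; the envelope is the pointwise
    (alpha/2, 1-alpha/2) percentile band.  Clustered data exceed the upper
    envelope at small radii.
    """
    pts = transcripts[["x", "y"]].to_numpy(dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 points for the CSR test")
    width, height = fov_dims
    if width <= 0 or height <= 0:
        raise ValueError("field-of-view dimensions must be positive")
    area = width * height
    if max_radius is None:
        max_radius = math.sqrt(area) / 2
    radii = np.linspace(0.0, max_radius, n_radii)
    k_obs = ripley_k(pts, area, radii)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_mc, n_radii))
    for i in range(n_mc):
        rand = rng.uniform([0, 0], [width, height], size=(len(pts), 2))
        sims[i] = ripley_k(rand, area, radii)
    low = np.percentile(sims, 100 * alpha / 2, axis=0)
    high = np.percentile(sims, 100 * (1 - alpha / 2), axis=0)
    return {
        "radii": radii.tolist(),
        "k_observed": k_obs.tolist(),
        "envelope_low": low.tolist(),
        "envelope_high": high.tolist(),
        "outside": [bool(k < lo or k > hi) for k, lo, hi in zip(k_obs, low, high)],
        "above": [bool(k > hi) for k, hi in zip(k_obs, high)],
    }


# ---------------------------------------------------------------------------
# 9-10. scalar ratios
# ---------------------------------------------------------------------------


def spots_per_barcode(spots: SpotTable, codebook: Codebook) -> float:
    if len(codebook) == 0:
        raise ValueError("empty codebook")
    return len(spots) / len(codebook)


def fraction_spots_used(transcripts: pd.DataFrame, spots: SpotTable) -> float:
    """|union of source spot ids| / total spots; 0 for an empty spot table."""
    if len(spots) == 0:
        return 0.0
    used: set[int] = set()
    for ids in transcripts["source_spot_ids"]:
        used.update(int(s) for s in ids)
    return len(used) / len(spots)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Structured metric collection with per-FOV and combined sections."""

    per_fov: dict[str, dict] = field(default_factory=dict)
    combined: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_fov": self.per_fov, "combined": self.combined}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "QCReport":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(per_fov=doc.get("per_fov", {}), combined=doc.get("combined", {}))


def _fov_metrics(
    transcripts: pd.DataFrame,
    spots: SpotTable,
    codebook: Codebook,
    fov_dims: tuple[float, float],
    ripley: bool,
    ripley_seed: int,
    n_mc: int,
    alpha: float,
) -> dict:
    n_rounds, n_channels = codebook.n_rounds, codebook.n_channels
    n_ec = int((transcripts["rounds_used"] < n_rounds).sum())
    on = ~transcripts["is_off_target"].astype(bool)
    metrics: dict = {
        "n_transcripts": int(len(transcripts)),
        "tallies": {
            "non_corrected_on_target": int(
                ((transcripts["rounds_used"] == n_rounds) & on).sum()
            ),
            "non_corrected_off_target": int(
                ((transcripts["rounds_used"] == n_rounds) & ~on).sum()
            ),
            "corrected_on_target": int(
                ((transcripts["rounds_used"] < n_rounds) & on).sum()
            ),
            "corrected_off_target": int(
                ((transcripts["rounds_used"] < n_rounds) & ~on).sum()
            ),
        },
        "spots_per_barcode": spots_per_barcode(spots, codebook),
        "fraction_spots_used": fraction_spots_used(transcripts, spots),
    }
    if len(spots):
        metrics["spots_per_round"] = spots_per_round_stats(spots, n_rounds)
        metrics["spots_per_channel"] = spots_per_channel_stats(spots, n_channels)
    if len(transcripts):
        metrics["source_spots_per_round"] = source_spot_round_stats(
            transcripts, spots, n_rounds
        )
        metrics["source_spots_per_channel"] = source_spot_channel_stats(
            transcripts, spots, n_channels
        )
    if codebook.is_off_target.sum() >= 2:
        metrics["offtarget_threshold"] = offtarget_count_threshold(
            transcripts, codebook
        )
    if transcripts["cell_id"].notna().any():
        metrics["false_positive_rate"] = false_positive_rate_per_cell(transcripts)
        metrics["transcripts_per_cell"] = transcripts_per_cell_cutoff(transcripts)
    if ripley and len(transcripts) >= 10:
        metrics["ripley_csr"] = ripley_k_csr_test(
            transcripts, fov_dims, seed=ripley_seed, n_mc=n_mc, alpha=alpha
        )
    return metrics


def build_report(
    transcripts_by_fov: Mapping[str, pd.DataFrame],
    spots_by_fov: Mapping[str, SpotTable],
    codebook: Codebook,
    ripley: bool = True,
    seed: int = 0,
    n_mc: int = 100,
    alpha: float = 0.05,
) -> QCReport:
    """Compute every metric per FOV and over all FOVs combined."""
    report = QCReport()
    for i, fov in enumerate(sorted(transcripts_by_fov)):
        spots = spots_by_fov[fov]
        report.per_fov[fov] = _fov_metrics(
            transcripts_by_fov[fov],
            spots,
            codebook,
            (spots.fov_width, spots.fov_height),
            ripley,
            seed + i,
            n_mc,
            alpha,
        )
    report.combined = _combine(report.per_fov, transcripts_by_fov, spots_by_fov, codebook)
    return report


def _combine(
    per_fov: Mapping[str, dict],
    transcripts_by_fov: Mapping[str, pd.DataFrame],
    spots_by_fov: Mapping[str, SpotTable],
    codebook: Codebook,
) -> dict:
    """Combined-FOV scope: tallies summed, moment stats recomputed on sums.

    Spot ids are only unique within a FOV, so id-based metrics (fraction of
    spots used, source-spot tallies) are aggregated from the per-FOV values
    rather than recomputed on a concatenated table.  K is a per-window
    statistic and has no combined analogue.
    """
    fovs = sorted(per_fov)
    all_transcripts = pd.concat(
        [transcripts_by_fov[f] for f in fovs], ignore_index=True
    )
    n_spots_total = sum(len(spots_by_fov[f]) for f in fovs)
    combined: dict = {
        "n_transcripts": int(len(all_transcripts)),
        "tallies": {
            key: sum(per_fov[f]["tallies"][key] for f in fovs)
            for key in per_fov[fovs[0]]["tallies"]
        },
        "spots_per_barcode": n_spots_total / len(codebook),
    }
    used = sum(
        per_fov[f]["fraction_spots_used"] * len(spots_by_fov[f]) for f in fovs
    )
    combined["fraction_spots_used"] = used / n_spots_total if n_spots_total else 0.0
    for key, n_bins in (
        ("spots_per_round", codebook.n_rounds),
        ("spots_per_channel", codebook.n_channels),
        ("source_spots_per_round", codebook.n_rounds),
        ("source_spots_per_channel", codebook.n_channels),
    ):
        parts = [per_fov[f][key]["counts"] for f in fovs if key in per_fov[f]]
        if parts:
            total = np.sum(parts, axis=0)
            combined[key] = _tally_stats(pd.Series(total), n_bins)
    if codebook.is_off_target.sum() >= 2:
        combined["offtarget_threshold"] = offtarget_count_threshold(
            all_transcripts, codebook
        )
    if all_transcripts["cell_id"].notna().any():
        combined["false_positive_rate"] = false_positive_rate_per_cell(all_transcripts)
        combined["transcripts_per_cell"] = transcripts_per_cell_cutoff(all_transcripts)
    return combined
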