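"""Exhaustive candidate-checking decoder for combinatorial FISH barcodes.

For each spot (the *seed*) all full-length channel sequences that could be
formed from its cross-round neighbors are enumerated and scored; the best
candidate per seed survives a codebook filter and a support filter, and the
surviving set is reduced to non-overlapping calls by greedy elimination on
the conflict graph.  The procedure is repeated over an increasing radius
schedule, first with the strict *filter-first* selection order, then with the
permissive *decode-first* order, consuming spots as they are used.  With
``error_rounds=1`` a final series of passes matches partial sequences with a
single round dropped, which is well defined whenever all codebook pairs
differ in at least two rounds.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from spotdecode.core import (
    Codebook,
    SpotTable,
    min_pairwise_hamming,
    normalize_intensities,
)

logger = logging.getLogger(__name__)

MODES = ("high", "medium", "low")


def _mode_supports(mode: str, n_rounds: int) -> tuple[int, int | None]:
    """(filter-first min support, decode-first min support or None to skip)."""
    if mode == "high":
        return n_rounds, None
    if mode == "medium":
        return n_rounds, n_rounds - 1
    if mode == "low":
        return n_rounds - 1, 1
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


@dataclass
class DecodeConfig:
    """Decoder settings.

    ``radius_schedule`` defaults to 5 evenly spaced values from 0 to
    ``search_radius``; the support thresholds default from ``mode`` but can be
    overridden.  ``recompute_degrees`` selects whether conflict-graph
    elimination uses current degrees (default) or initial degrees.
    """

    search_radius: float
    mode: str = "medium"
    error_rounds: int = 0
    score_constant_c: float = 2.0
    radius_schedule: tuple[float, ...] | None = None
    min_support_filter_first: int | None = None
    min_support_decode_first: int | None = None
    recompute_degrees: bool = True

    def __post_init__(self) -> None:
        if self.search_radius < 0:
            raise ValueError("search_radius must be non-negative")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.error_rounds not in (0, 1):
            raise ValueError("error_rounds must be 0 or 1")
        if self.radius_schedule is None:
            self.radius_schedule = tuple(np.unique(np.linspace(0.0, self.search_radius, 5)))
        else:
            self.radius_schedule = tuple(float(r) for r in self.radius_schedule)
            if list(self.radius_schedule) != sorted(set(self.radius_schedule)):
                raise ValueError("radius_schedule must be strictly increasing")
            if self.radius_schedule[0] != 0.0:
                raise ValueError("radius_schedule must start at 0")
            if not math.isclose(self.radius_schedule[-1], self.search_radius):
                raise ValueError("radius_schedule must end at search_radius")

    def supports(self, n_rounds: int) -> tuple[int, int | None]:
        ff, df = _mode_supports(self.mode, n_rounds)
        if self.min_support_filter_first is not None:
            ff = self.min_support_filter_first
        if self.min_support_decode_first is not None:
            df = self.min_support_decode_first
        return ff, df


@dataclass(frozen=True)
class BarcodeCandidate:
    """An ordered selection of spots, one per included round."""

    spot_ids: tuple[int, ...]
    rounds: tuple[int, ...]
    channel_sequence: tuple[int, ...]
    seed_spot_id: int
    score: float
    qual_sum: float
    target: str | None = None
    dropped_round: int | None = None

    @property
    def rounds_used(self) -> int:
        return len(self.spot_ids)

    @property
    def spot_set(self) -> frozenset[int]:
        return frozenset(self.spot_ids)


# ---------------------------------------------------------------------------
# Step 1: neighbors
# ---------------------------------------------------------------------------


def find_neighbors(spots: SpotTable, radius: float) -> dict[int, dict[int, list[int]]]:
    """Cross-round neighbor map within Euclidean ``radius`` in (x, y, z).

    Returns ``{spot_id: {other_round: [neighbor spot_ids...]}}``; same-round
    spots are never neighbors and the relation is symmetric.  Neighbor lists
    are sorted by spot_id for determinism.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    df = spots.data
    ids = df["spot_id"].to_numpy()
    rounds = df["r"].to_numpy()
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    neighbor_map: dict[int, dict[int, list[int]]] = {int(i): {} for i in ids}
    by_round: dict[int, np.ndarray] = {}
    trees: dict[int, cKDTree] = {}
    for rnd in sorted(set(int(r) for r in rounds)):
        mask = rounds == rnd
        by_round[rnd] = np.flatnonzero(mask)
        trees[rnd] = cKDTree(coords[mask])
    round_keys = sorted(trees)
    for i, ra in enumerate(round_keys):
        for rb in round_keys[i + 1 :]:
            pairs = trees[ra].query_ball_tree(trees[rb], r=radius)
            idx_a, idx_b = by_round[ra], by_round[rb]
            for a_local, b_locals in enumerate(pairs):
                sid_a = int(ids[idx_a[a_local]])
                for b_local in b_locals:
                    sid_b = int(ids[idx_b[b_local]])
                    neighbor_map[sid_a].setdefault(rb, []).append(sid_b)
                    neighbor_map[sid_b].setdefault(ra, []).append(sid_a)
    for per_round in neighbor_map.values():
        for lst in per_round.values():
            lst.sort()
    return neighbor_map


# ---------------------------------------------------------------------------
# Steps 2-3: candidate enumeration and scoring
# ---------------------------------------------------------------------------


def score_barcode(
    intensities: Sequence[float],
    coords: np.ndarray,
    n_rounds: int,
    c: float = 2.0,
) -> tuple[float, float]:
    """Score = Q + Sv*C (lower is better); returns ``(score, qual_sum)``.

    Q = ln(1 + (n_rounds - sum of normalized intensities)) and
    Sv = ln(1 + sum over x,y,z of the population variance of member
    coordinates).  Intensities must already be normalized to [0, 1].
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size == 0:
        raise ValueError("barcode must have at least one member spot")
    if (intensities < 0).any() or (intensities > 1).any():
        raise ValueError("intensities must be normalized to [0, 1]")
    qual_sum = float(intensities.sum())
    q = math.log1p(n_rounds - qual_sum)
    var_sum = float(np.var(np.asarray(coords, dtype=float), axis=0).sum())
    sv = math.log1p(var_sum)
    return q + sv * c, qual_sum


class _SpotIndex:
    """Per-spot attribute lookup as plain dicts (fast in tight loops)."""

    def __init__(self, spots: SpotTable) -> None:
        df = spots.data
        ids = df["spot_id"].to_numpy()
        self.round = dict(zip(ids, (int(v) for v in df["r"])))
        self.channel = dict(zip(ids, (int(v) for v in df["c"])))
        self.x = dict(zip(ids, (float(v) for v in df["x"])))
        self.y = dict(zip(ids, (float(v) for v in df["y"])))
        self.z = dict(zip(ids, (float(v) for v in df["z"])))
        self.intensity = dict(zip(ids, (float(v) for v in df["intensity"])))
        bad = df.loc[(df["intensity"] < 0) | (df["intensity"] > 1), "intensity"]
        if len(bad):
            raise ValueError(
                f"intensities must be normalized to [0, 1]; saw {bad.iloc[0]}"
            )


def build_candidates(
    seed_spot_id: int,
    neighbor_map: Mapping[int, Mapping[int, Sequence[int]]],
    spots: SpotTable,
    n_rounds: int,
    c: float = 2.0,
    dropped_round: int | None = None,
    index: "_SpotIndex | None" = None,
) -> list[BarcodeCandidate]:
    """Enumerate and score every barcode the seed could participate in.

    Each candidate takes the seed in its own round and exactly one neighbor of
    the seed in every other included round (the full cartesian product).  With
    ``dropped_round`` set, that round is excluded and (n_rounds-1)-length
    partial barcodes are produced; the dropped round must differ from the
    seed's round.
    """
    if index is None:
        index = _SpotIndex(spots)
    seed_round = index.round[seed_spot_id]
    if dropped_round == seed_round:
        raise ValueError("cannot drop the seed's own round")
    included = [r for r in range(n_rounds) if r != dropped_round]
    per_round: list[list[int]] = []
    for rnd in included:
        if rnd == seed_round:
            per_round.append([seed_spot_id])
        else:
            choices = list(neighbor_map.get(seed_spot_id, {}).get(rnd, []))
            if not choices:
                return []
            per_round.append(choices)
    out = []
    m = len(included)
    # center on the seed position: variance is shift-invariant and this
    # avoids cancellation in the single-pass moment sums
    x0, y0, z0 = index.x[seed_spot_id], index.y[seed_spot_id], index.z[seed_spot_id]
    for combo in itertools.product(*per_round):
        qual_sum = 0.0
        sx = sy = sz = sx2 = sy2 = sz2 = 0.0
        for sid in combo:
            qual_sum += index.intensity[sid]
            px, py, pz = index.x[sid] - x0, index.y[sid] - y0, index.z[sid] - z0
            sx += px
            sy += py
            sz += pz
            sx2 += px * px
            sy2 += py * py
            sz2 += pz * pz
        var_sum = (
            max(sx2 / m - (sx / m) ** 2, 0.0)
            + max(sy2 / m - (sy / m) ** 2, 0.0)
            + max(sz2 / m - (sz / m) ** 2, 0.0)
        )
        score = math.log1p(n_rounds - qual_sum) + math.log1p(var_sum) * c
        out.append(
            BarcodeCandidate(
                spot_ids=tuple(int(s) for s in combo),
                rounds=tuple(included),
                channel_sequence=tuple(index.channel[s] for s in combo),
                seed_spot_id=int(seed_spot_id),
                score=score,
                qual_sum=qual_sum,
                dropped_round=dropped_round,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Steps 3-4: per-seed best selection under either order
# ---------------------------------------------------------------------------


def _candidate_sort_key(c: BarcodeCandidate) -> tuple:
    # score ascending, then larger qual_sum, then smallest id tuple: deterministic
    return (c.score, -c.qual_sum, c.spot_ids)


def _match_target(
    cand: BarcodeCandidate,
    exact: Mapping[tuple[int, ...], int],
    partial: Mapping[tuple[int, tuple[int, ...]], int] | None,
) -> int | None:
    if cand.dropped_round is None:
        return exact.get(cand.channel_sequence)
    if partial is None:
        return None
    return partial.get((cand.dropped_round, cand.channel_sequence))


def select_best_per_seed(
    candidates_by_seed: Mapping[int, Sequence[BarcodeCandidate]],
    order: str,
    codebook: Codebook,
) -> dict[int, BarcodeCandidate]:
    """Pick one candidate per seed under ``filter_first`` or ``decode_first``.

    filter_first: take the minimum-score candidate, then discard it if its
    channel sequence has no codebook match.  decode_first: restrict to
    codebook matches first, then take the minimum score.  Matched candidates
    are returned with ``target`` filled in.
    """
    if order not in ("filter_first", "decode_first"):
        raise ValueError(f"unknown selection order {order!r}")
    exact = codebook.exact_lookup()
    partial = codebook.partial_lookup()
    best: dict[int, BarcodeCandidate] = {}
    for seed in sorted(candidates_by_seed):
        cands = candidates_by_seed[seed]
        if not cands:
            continue
        if order == "filter_first":
            pool = list(cands)
        else:
            pool = [c for c in cands if _match_target(c, exact, partial) is not None]
        if not pool:
            continue
        chosen = min(pool, key=_candidate_sort_key)
        idx = _match_target(chosen, exact, partial)
        if idx is None:
            continue
        best[seed] = dataclass_with_target(chosen, codebook.targets[idx])
    return best


def dataclass_with_target(cand: BarcodeCandidate, target: str) -> BarcodeCandidate:
    return BarcodeCandidate(
        spot_ids=cand.spot_ids,
        rounds=cand.rounds,
        channel_sequence=cand.channel_sequence,
        seed_spot_id=cand.seed_spot_id,
        score=cand.score,
        qual_sum=cand.qual_sum,
        target=target,
        dropped_round=cand.dropped_round,
    )


# ---------------------------------------------------------------------------
# Step 5: support filter
# ---------------------------------------------------------------------------


def filter_by_support(
    best_per_seed: Mapping[int, BarcodeCandidate],
    min_support_n: int,
    n_rounds: int,
) -> list[BarcodeCandidate]:
    """Keep barcodes chosen as best by >= ``min_support_n`` of their own spots.

    Candidates from different seeds with identical spot sets are one barcode;
    support is the number of distinct member seeds that selected it.  One
    representative per spot set is returned, ordered by smallest id tuple.
    """
    if min_support_n > n_rounds:
        raise ValueError("min_support_n cannot exceed the number of rounds")
    groups: dict[frozenset[int], list[tuple[int, BarcodeCandidate]]] = {}
    for seed, cand in best_per_seed.items():
        groups.setdefault(cand.spot_set, []).append((seed, cand))
    kept = []
    for spot_set, members in groups.items():
        supporters = {seed for seed, _ in members if seed in spot_set}
        if len(supporters) >= min_support_n:
            rep = min((cand for _, cand in members), key=lambda c: c.spot_ids)
            kept.append(rep)
    kept.sort(key=lambda c: c.spot_ids)
    return kept


# ---------------------------------------------------------------------------
# Step 6: conflict resolution (greedy approximate maximum independent set)
# ---------------------------------------------------------------------------


def resolve_conflicts(
    candidates: Sequence[BarcodeCandidate],
    recompute_degrees: bool = True,
) -> list[BarcodeCandidate]:
    """Eliminate overlapping candidates until the survivors are spot-disjoint.

    Nodes sharing at least one spot are connected; the node of highest degree
    is removed repeatedly, breaking degree ties by removing the higher (worse)
    score, until no edges remain.  ``recompute_degrees=False`` freezes the
    elimination order at the initial degrees.
    """
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(range(len(candidates)))
    for i in range(len(candidates)):
        set_i = candidates[i].spot_set
        for j in range(i + 1, len(candidates)):
            if set_i & candidates[j].spot_set:
                graph.add_edge(i, j)
    initial_degree = dict(graph.degree())

    def elimination_key(node: int) -> tuple:
        degree = graph.degree(node) if recompute_degrees else initial_degree[node]
        cand = candidates[node]
        # max degree first, then worse score, then deterministic id order
        return (-degree, -cand.score, cand.qual_sum, cand.spot_ids)

    removed = []
    while graph.number_of_edges() > 0:
        conflicted = [n for n in graph.nodes if graph.degree(n) > 0]
        victim = min(conflicted, key=elimination_key)
        graph.remove_node(victim)
        removed.append(victim)

    # elimination alone can strand re-addable nodes (all of a victim's
    # conflicts may themselves be eliminated later); greedily re-insert by
    # best score so the survivor set is maximal
    survivor_ids = set(graph.nodes)
    used: set[int] = set()
    for i in survivor_ids:
        used |= candidates[i].spot_set
    for i in sorted(removed, key=lambda i: _candidate_sort_key(candidates[i])):
        if not (candidates[i].spot_set & used):
            survivor_ids.add(i)
            used |= candidates[i].spot_set
    return [candidates[i] for i in sorted(survivor_ids)]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _run_pass(
    spots: SpotTable,
    codebook: Codebook,
    radius: float,
    order: str,
    min_support: int,
    config: DecodeConfig,
    error_pass: bool,
) -> list[BarcodeCandidate]:
    n_rounds = codebook.n_rounds
    if len(spots) == 0:
        return []
    neighbor_map = find_neighbors(spots, radius)
    index = _SpotIndex(spots)
    candidates_by_seed: dict[int, list[BarcodeCandidate]] = {}
    for seed in sorted(int(s) for s in spots.data["spot_id"]):
        cands: list[BarcodeCandidate] = []
        if not error_pass:
            cands = build_candidates(
                seed, neighbor_map, spots, n_rounds, config.score_constant_c, index=index
            )
        else:
            for dropped in range(n_rounds):
                if dropped == index.round[seed]:
                    continue
                cands.extend(
                    build_candidates(
                        seed,
                        neighbor_map,
                        spots,
                        n_rounds,
                        config.score_constant_c,
                        dropped_round=dropped,
                        index=index,
                    )
                )
        if cands:
            candidates_by_seed[seed] = cands
    best = select_best_per_seed(candidates_by_seed, order, codebook)
    supported = filter_by_support(best, min_support, n_rounds)
    return resolve_conflicts(supported, config.recompute_degrees)


def decode(spots: SpotTable, codebook: Codebook, config: DecodeConfig) -> pd.DataFrame:
    """Run the staged decoder and return the decoded transcript table.

    Columns: target, x, y, z (member-spot centroid), rounds_used,
    source_spot_ids (tuple), is_off_target, cell_id (NaN; assignment is a
    separate step).  No spot id appears in more than one record.
    """
    if config.error_rounds == 1 and min_pairwise_hamming(codebook) < 2:
        raise ValueError(
            "error_rounds=1 requires all codebook pairs at Hamming distance >= 2"
        )
    spots = normalize_intensities(spots)
    n_rounds = codebook.n_rounds
    ff_support, df_support = config.supports(n_rounds)
    remaining = spots
    accepted: list[BarcodeCandidate] = []
    off_flags = dict(zip(codebook.targets, codebook.is_off_target))

    error_stages = [False] + ([True] if config.error_rounds == 1 else [])
    for error_pass in error_stages:
        for radius in config.radius_schedule:
            passes: list[tuple[str, int]] = [("filter_first", ff_support)]
            if df_support is not None:
                passes.append(("decode_first", df_support))
            for order, support in passes:
                support_eff = min(support, n_rounds - 1) if error_pass else support
                calls = _run_pass(
                    remaining, codebook, radius, order, support_eff, config, error_pass
                )
                if calls:
                    used = set().union(*(c.spot_set for c in calls))
                    keep = ~remaining.data["spot_id"].isin(used)
                    remaining = SpotTable(
                        remaining.data[keep],
                        remaining.fov_width,
                        remaining.fov_height,
                    )
                    accepted.extend(calls)
                logger.info(
                    "stage radius=%.3g order=%s ec=%d: %d calls, %d spots left",
                    radius,
                    order,
                    int(error_pass),
                    len(calls),
                    len(remaining),
                )

    lookup = spots.data.set_index("spot_id")
    records = []
    for cand in accepted:
        members = lookup.loc[list(cand.spot_ids)]
        records.append(
            {
                "target": cand.target,
                "x": float(members["x"].mean()),
                "y": float(members["y"].mean()),
                "z": float(members["z"].mean()),
                "rounds_used": cand.rounds_used,
                "source_spot_ids": tuple(sorted(cand.spot_ids)),
                "is_off_target": bool(off_flags[cand.target]),
                "cell_id": np.nan,
            }
        )
    df = pd.DataFrame(
        records,
        columns=[
            "target",
            "x",
            "y",
            "z",
            "rounds_used",
            "source_spot_ids",
            "is_off_target",
            "cell_id",
        ],
    )
    return df
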