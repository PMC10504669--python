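"""Independent brute-force oracles for the decoder stages.

Deliberately naive: plain Python loops, no KD-trees, no graph library, no
imports from the package's decoder internals.  Shared by the unit tests and
the acceptance suite.
"""

from __future__ import annotations

import itertools
import math


def brute_neighbors(rows, radius):
    """All-pairs cross-round neighbor map.

    ``rows``: list of dicts with spot_id, r, x, y, z.  Returns
    {spot_id: {round: sorted [spot_ids]}}.
    """
    out = {row["spot_id"]: {} for row in rows}
    for a, b in itertools.combinations(rows, 2):
        if a["r"] == b["r"]:
            continue
        d = math.dist((a["x"], a["y"], a["z"]), (b["x"], b["y"], b["z"]))
        if d <= radius:
            out[a["spot_id"]].setdefault(b["r"], []).append(b["spot_id"])
            out[b["spot_id"]].setdefault(a["r"], []).append(a["spot_id"])
    for per_round in out.values():
        for lst in per_round.values():
            lst.sort()
    return out


def brute_score(intensities, coords, n_rounds, c=2.0):
    qual_sum = sum(intensities)
    q = math.log(1 + (n_rounds - qual_sum))
    var_sum = 0.0
    m = len(coords)
    for axis in range(3):
        vals = [p[axis] for p in coords]
        mean = sum(vals) / m
        var_sum += sum((v - mean) ** 2 for v in vals) / m
    return q + math.log(1 + var_sum) * c, qual_sum


def brute_candidates(seed_id, rows, radius, n_rounds, c=2.0, dropped_round=None):
    """Enumerate every one-spot-per-included-round tuple containing the seed,
    with all non-seed members within ``radius`` of the seed."""
    by_id = {row["spot_id"]: row for row in rows}
    seed = by_id[seed_id]
    included = [r for r in range(n_rounds) if r != dropped_round]
    if seed["r"] not in included:
        raise ValueError("cannot drop the seed's round")
    pools = []
    for rnd in included:
        if rnd == seed["r"]:
            pools.append([seed_id])
        else:
            pool = sorted(
                row["spot_id"]
                for row in rows
                if row["r"] == rnd
                and math.dist(
                    (row["x"], row["y"], row["z"]),
                    (seed["x"], seed["y"], seed["z"]),
                )
                <= radius
            )
            if not pool:
                return []
            pools.append(pool)
    cands = []
    for combo in itertools.product(*pools):
        members = [by_id[s] for s in combo]
        score, qual_sum = brute_score(
            [m["intensity"] for m in members],
            [(m["x"], m["y"], m["z"]) for m in members],
            n_rounds,
            c,
        )
        cands.append(
            {
                "spot_ids": tuple(combo),
                "channels": tuple(m["c"] for m in members),
                "score": score,
                "qual_sum": qual_sum,
                "seed": seed_id,
                "dropped_round": dropped_round,
            }
        )
    return cands


def brute_best(cands_by_seed, order, matcher):
    """Per-seed minimum-score selection under either order.

    ``matcher(cand)`` returns a target name or None.  Ties: larger qual_sum,
    then smallest spot_id tuple.
    """
    key = lambda c: (c["score"], -c["qual_sum"], c["spot_ids"])
    best = {}
    for seed in sorted(cands_by_seed):
        cands = cands_by_seed[seed]
        pool = cands if order == "filter_first" else [c for c in cands if matcher(c)]
        if not pool:
            continue
        chosen = min(pool, key=key)
        target = matcher(chosen)
        if target is None:
            continue
        best[seed] = dict(chosen, target=target)
    return best


def brute_support(best_per_seed, min_n):
    """Group identical spot sets; keep those supported by >= min_n member seeds."""
    groups = {}
    for seed, cand in best_per_seed.items():
        groups.setdefault(frozenset(cand["spot_ids"]), []).append((seed, cand))
    kept = []
    for spot_set, members in groups.items():
        supporters = {s for s, _ in members if s in spot_set}
        if len(supporters) >= min_n:
            kept.append(min((c for _, c in members), key=lambda c: c["spot_ids"]))
    kept.sort(key=lambda c: c["spot_ids"])
    return kept


def brute_greedy_mis(cands, recompute_degrees=True):
    """Degree-ordered elimination with the documented tie-breaks."""
    nodes = list(range(len(cands)))
    adj = {i: set() for i in nodes}
    for i, j in itertools.combinations(nodes, 2):
        if set(cands[i]["spot_ids"]) & set(cands[j]["spot_ids"]):
            adj[i].add(j)
            adj[j].add(i)
    initial = {i: len(adj[i]) for i in nodes}
    alive = set(nodes)
    removed = []
    while any(adj[i] for i in alive):
        conflicted = [i for i in alive if adj[i]]
        victim = min(
            conflicted,
            key=lambda i: (
                -(len(adj[i]) if recompute_degrees else initial[i]),
                -cands[i]["score"],
                cands[i]["qual_sum"],
                cands[i]["spot_ids"],
            ),
        )
        alive.remove(victim)
        removed.append(victim)
        for other in adj[victim]:
            adj[other].discard(victim)
        adj[victim] = set()
    # re-insert stranded nodes, best score first, to make the set maximal
    used = set()
    for i in alive:
        used |= set(cands[i]["spot_ids"])
    for i in sorted(
        removed,
        key=lambda i: (cands[i]["score"], -cands[i]["qual_sum"], cands[i]["spot_ids"]),
    ):
        if not (set(cands[i]["spot_ids"]) & used):
            alive.add(i)
            used |= set(cands[i]["spot_ids"])
    return [cands[i] for i in sorted(alive)]


def brute_exact_mis_size(cands):
    """Exact maximum independent set size by subset enumeration (small n only)."""
    n = len(cands)
    sets = [frozenset(c["spot_ids"]) for c in cands]
    best = 0
    for mask in range(1 << n):
        chosen = [i for i in range(n) if mask >> i & 1]
        ok = all(
            not (sets[i] & sets[j]) for i, j in itertools.combinations(chosen, 2)
        )
        if ok:
            best = max(best, len(chosen))
    return best
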