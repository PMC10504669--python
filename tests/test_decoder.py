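import math

import numpy as np
import pandas as pd
import pytest

import brute
from conftest import random_codebook, random_instance
from spotdecode.core import Codebook, SpotTable
from spotdecode.decoder import (
    BarcodeCandidate,
    DecodeConfig,
    build_candidates,
    decode,
    filter_by_support,
    find_neighbors,
    resolve_conflicts,
    score_barcode,
    select_best_per_seed,
)
from spotdecode.simulate import (
    SimulationConfig,
    drop_one_round_per_transcript,
    evaluate_decoding,
    generate_codebook,
    simulate,
)


def _as_dicts(spots: SpotTable):
    return spots.data.to_dict("records")


def _matcher(codebook: Codebook):
    exact = codebook.exact_lookup()
    partial = codebook.partial_lookup()

    def match(cand: dict):
        if cand["dropped_round"] is None:
            idx = exact.get(cand["channels"])
        else:
            idx = partial.get((cand["dropped_round"], cand["channels"]))
        return None if idx is None else codebook.targets[idx]

    return match


class TestFindNeighbors:
    def test_negative_radius_errors(self, tiny_spots):
        with pytest.raises(ValueError):
            find_neighbors(tiny_spots, -1.0)

    def test_radius_zero_colocated_only(self):
        df = pd.DataFrame(
            {
                "spot_id": [0, 1, 2],
                "r": [0, 1, 1],
                "c": [0, 0, 0],
                "x": [1.0, 1.0, 2.0],
                "y": [1.0, 1.0, 1.0],
                "z": [0.0, 0.0, 0.0],
                "intensity": [1.0, 1.0, 1.0],
            }
        )
        nmap = find_neighbors(SpotTable(df, 5, 5), 0.0)
        assert nmap[0] == {1: [1]}
        assert nmap[1] == {0: [0]}
        assert nmap[2] == {}

    def test_out_of_radius(self):
        df = pd.DataFrame(
            {
                "spot_id": [0, 1],
                "r": [0, 1],
                "c": [0, 0],
                "x": [0.0, 1.0],
                "y": [0.0, 0.0],
                "z": [0.0, 0.0],
                "intensity": [1.0, 1.0],
            }
        )
        nmap = find_neighbors(SpotTable(df, 5, 5), 0.5)
        assert nmap == {0: {}, 1: {}}

    def test_same_round_never_neighbors(self):
        df = pd.DataFrame(
            {
                "spot_id": [0, 1],
                "r": [0, 0],
                "c": [0, 1],
                "x": [0.0, 0.0],
                "y": [0.0, 0.0],
                "z": [0.0, 0.0],
                "intensity": [1.0, 1.0],
            }
        )
        nmap = find_neighbors(SpotTable(df, 5, 5), 10.0)
        assert nmap == {0: {}, 1: {}}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        rows, spots = random_instance(rng, n_spots=50, box=6.0)
        assert find_neighbors(spots, 2.0) == brute.brute_neighbors(rows, 2.0)


class TestScoreBarcode:
    def test_perfect_barcode_scores_zero(self):
        coords = np.zeros((4, 3))
        score, qual = score_barcode([1.0] * 4, coords, 4, c=2.0)
        assert score == 0.0 and qual == 4.0

    def test_closed_form(self):
        # QualSum=3, var-sum=1, RoundNum=4, C=2 -> ln2 + 2 ln2 = 3 ln2
        coords = np.array([[1.0, 0, 0], [-1.0, 0, 0], [1.0, 0, 0], [-1.0, 0, 0]])
        assert np.var(coords[:, 0]) == 1.0
        score, _ = score_barcode([0.75] * 4, coords, 4, c=2.0)
        assert score == pytest.approx(3 * math.log(2), abs=1e-12)

    def test_scatter_increases_score(self):
        base = np.zeros((4, 3))
        s0, _ = score_barcode([0.9] * 4, base, 4)
        scattered = base + np.array([[0, 0, 0], [0.5, 0, 0], [0, 0.5, 0], [0, 0, 0.5]])
        s1, _ = score_barcode([0.9] * 4, scattered, 4)
        assert s1 > s0

    def test_unnormalized_intensity_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            score_barcode([1.5, 1.0, 1.0, 1.0], np.zeros((4, 3)), 4)


class TestBuildCandidates:
    def test_one_neighbor_per_round_single_candidate(self, tiny_spots):
        nmap = find_neighbors(tiny_spots, 1.0)
        cands = build_candidates(0, nmap, tiny_spots, 4)
        assert len(cands) == 1
        assert cands[0].spot_ids == (0, 1, 2, 3)
        assert cands[0].channel_sequence == (0, 1, 2, 0)

    def test_cartesian_product_count(self):
        rows = []
        sid = 0
        for rnd in range(4):
            for copy in range(1 if rnd == 0 else 2):
                rows.append(
                    dict(spot_id=sid, r=rnd, c=copy, x=0.0, y=0.0, z=0.0, intensity=1.0)
                )
                sid += 1
        spots = SpotTable(pd.DataFrame(rows), 5, 5)
        nmap = find_neighbors(spots, 1.0)
        cands = build_candidates(0, nmap, spots, 4)
        assert len(cands) == 8  # 2^3

    def test_missing_round_yields_none(self):
        df = pd.DataFrame(
            {
                "spot_id": [0, 1],
                "r": [0, 1],
                "c": [0, 0],
                "x": [0.0, 0.0],
                "y": [0.0, 0.0],
                "z": [0.0, 0.0],
                "intensity": [1.0, 1.0],
            }
        )
        spots = SpotTable(df, 5, 5)
        nmap = find_neighbors(spots, 1.0)
        assert build_candidates(0, nmap, spots, n_rounds=3) == []

    def test_dropped_round_partial(self, tiny_spots):
        nmap = find_neighbors(tiny_spots, 1.0)
        cands = build_candidates(0, nmap, tiny_spots, 4, dropped_round=2)
        assert len(cands) == 1
        assert cands[0].spot_ids == (0, 1, 3)
        assert cands[0].rounds == (0, 1, 3)
        assert cands[0].dropped_round == 2

    def test_cannot_drop_seed_round(self, tiny_spots):
        nmap = find_neighbors(tiny_spots, 1.0)
        with pytest.raises(ValueError, match="seed"):
            build_candidates(0, nmap, tiny_spots, 4, dropped_round=0)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        rows, spots = random_instance(rng, n_spots=12, box=3.0)
        nmap = find_neighbors(spots, 2.0)
        for row in rows:
            got = build_candidates(row["spot_id"], nmap, spots, 4)
            want = brute.brute_candidates(row["spot_id"], rows, 2.0, 4)
            assert sorted(c.spot_ids for c in got) == sorted(
                c["spot_ids"] for c in want
            )
            by_ids = {c["spot_ids"]: c for c in want}
            for cand in got:
                assert cand.score == pytest.approx(by_ids[cand.spot_ids]["score"])
                assert cand.channel_sequence == by_ids[cand.spot_ids]["channels"]


def _mk_cand(spot_ids, channels, seed, score, qual=1.0, dropped=None):
    return BarcodeCandidate(
        spot_ids=tuple(spot_ids),
        rounds=tuple(range(len(spot_ids))),
        channel_sequence=tuple(channels),
        seed_spot_id=seed,
        score=score,
        qual_sum=qual,
        dropped_round=dropped,
    )


class TestSelectBest:
    def test_orders_agree_when_best_matches(self, simple_codebook):
        good = _mk_cand((0, 1, 2, 3), (0, 0, 0, 0), 0, 0.5)
        bad = _mk_cand((0, 4, 5, 6), (0, 2, 1, 0), 0, 1.5)
        for order in ("filter_first", "decode_first"):
            best = select_best_per_seed({0: [good, bad]}, order, simple_codebook)
            assert best[0].spot_ids == good.spot_ids
            assert best[0].target == "geneA"

    def test_filter_first_drops_unmatched_best(self, simple_codebook):
        off_code = _mk_cand((0, 1, 2, 3), (0, 0, 0, 1), 0, 0.5)  # not in codebook
        matched = _mk_cand((0, 4, 5, 6), (1, 1, 1, 1), 0, 1.5)
        ff = select_best_per_seed({0: [off_code, matched]}, "filter_first", simple_codebook)
        assert ff == {}
        df = select_best_per_seed({0: [off_code, matched]}, "decode_first", simple_codebook)
        assert df[0].target == "geneB"

    def test_unknown_order_rejected(self, simple_codebook):
        with pytest.raises(ValueError):
            select_best_per_seed({}, "best_first", simple_codebook)

    @pytest.mark.parametrize("order", ["filter_first", "decode_first"])
    @pytest.mark.parametrize("seed", [6, 7])
    def test_matches_bruteforce(self, order, seed, simple_codebook):
        rng = np.random.default_rng(seed)
        rows, spots = random_instance(rng, n_spots=12, box=2.5)
        nmap = find_neighbors(spots, 2.0)
        cands = {
            row["spot_id"]: build_candidates(row["spot_id"], nmap, spots, 4)
            for row in rows
        }
        cands = {s: c for s, c in cands.items() if c}
        got = select_best_per_seed(cands, order, simple_codebook)
        brute_cands = {
            row["spot_id"]: brute.brute_candidates(row["spot_id"], rows, 2.0, 4)
            for row in rows
        }
        brute_cands = {s: c for s, c in brute_cands.items() if c}
        want = brute.brute_best(brute_cands, order, _matcher(simple_codebook))
        assert set(got) == set(want)
        for s in got:
            assert got[s].spot_ids == want[s]["spot_ids"]
            assert got[s].target == want[s]["target"]


class TestFilterBySupport:
    def test_min_support_one_keeps_all(self):
        c = _mk_cand((0, 1, 2, 3), (0,) * 4, 0, 1.0)
        assert filter_by_support({0: c}, 1, 4) == [c]

    def test_insufficient_support_dropped(self):
        cands = {
            s: _mk_cand((0, 1, 2, 3), (0,) * 4, s, 1.0) for s in (0, 1, 2)
        }  # 3 of 4 member spots chose it
        assert filter_by_support(cands, 4, 4) == []
        kept = filter_by_support(cands, 3, 4)
        assert len(kept) == 1 and kept[0].spot_ids == (0, 1, 2, 3)

    def test_support_exceeding_rounds_errors(self):
        with pytest.raises(ValueError):
            filter_by_support({}, 5, 4)

    def test_matches_bruteforce(self, simple_codebook):
        rng = np.random.default_rng(8)
        rows, spots = random_instance(rng, n_spots=12, box=2.0)
        nmap = find_neighbors(spots, 2.0)
        cands = {
            r["spot_id"]: build_candidates(r["spot_id"], nmap, spots, 4) for r in rows
        }
        cands = {s: c for s, c in cands.items() if c}
        for min_n in (1, 2, 3, 4):
            got = filter_by_support(
                select_best_per_seed(cands, "decode_first", simple_codebook), min_n, 4
            )
            brute_cands = {
                r["spot_id"]: brute.brute_candidates(r["spot_id"], rows, 2.0, 4)
                for r in rows
            }
            brute_cands = {s: c for s, c in brute_cands.items() if c}
            want = brute.brute_support(
                brute.brute_best(brute_cands, "decode_first", _matcher(simple_codebook)),
                min_n,
            )
            assert [c.spot_ids for c in got] == [c["spot_ids"] for c in want]


class TestResolveConflicts:
    def test_disjoint_unchanged(self):
        a = _mk_cand((0, 1), (0, 0), 0, 1.0)
        b = _mk_cand((2, 3), (0, 0), 2, 2.0)
        assert resolve_conflicts([a, b]) == [a, b]

    def test_shared_spot_keeps_better_score(self):
        a = _mk_cand((0, 1), (0, 0), 0, 1.0)
        b = _mk_cand((1, 2), (0, 0), 1, 2.0)
        assert resolve_conflicts([a, b]) == [a]

    def test_survivors_disjoint_and_maximal(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            cands = [
                _mk_cand(
                    tuple(rng.choice(10, size=3, replace=False)),
                    (0, 0, 0),
                    i,
                    float(rng.uniform(0, 3)),
                )
                for i in range(8)
            ]
            out = resolve_conflicts(cands)
            ids = [s for c in out for s in c.spot_ids]
            assert len(ids) == len(set(ids))  # disjoint
            # maximal: no eliminated candidate could be added back
            for c in cands:
                if c not in out:
                    assert any(set(c.spot_ids) & set(o.spot_ids) for o in out)

    @pytest.mark.parametrize("recompute", [True, False])
    def test_matches_bruteforce_and_mis_bound(self, recompute):
        rng = np.random.default_rng(10)
        for _ in range(15):
            raw = [
                {
                    "spot_ids": tuple(sorted(rng.choice(9, size=3, replace=False))),
                    "channels": (0, 0, 0),
                    "score": float(rng.uniform(0, 3)),
                    "qual_sum": float(rng.uniform(0, 3)),
                    "seed": i,
                    "dropped_round": None,
                }
                for i in range(8)
            ]
            cands = [
                _mk_cand(r["spot_ids"], r["channels"], r["seed"], r["score"], r["qual_sum"])
                for r in raw
            ]
            got = resolve_conflicts(cands, recompute_degrees=recompute)
            want = brute.brute_greedy_mis(raw, recompute_degrees=recompute)
            assert [c.spot_ids for c in got] == [c["spot_ids"] for c in want]
            assert len(got) <= brute.brute_exact_mis_size(raw)


class TestDecodeConfig:
    def test_mode_presets(self):
        assert DecodeConfig(1.0, mode="high").supports(4) == (4, None)
        assert DecodeConfig(1.0, mode="medium").supports(4) == (4, 3)
        assert DecodeConfig(1.0, mode="low").supports(4) == (3, 1)

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            DecodeConfig(1.0, mode="turbo")

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            DecodeConfig(2.0, radius_schedule=(0.5, 1.0, 2.0))  # must start at 0
        with pytest.raises(ValueError):
            DecodeConfig(2.0, radius_schedule=(0.0, 1.0))  # must end at radius
        cfg = DecodeConfig(2.0, radius_schedule=(0.0, 1.0, 2.0))
        assert cfg.radius_schedule == (0.0, 1.0, 2.0)

    def test_default_schedule(self):
        cfg = DecodeConfig(2.0)
        assert cfg.radius_schedule == (0.0, 0.5, 1.0, 1.5, 2.0)


class TestDecode:
    def test_empty_input_empty_output(self, simple_codebook):
        spots = SpotTable(
            pd.DataFrame(columns=["spot_id", "r", "c", "x", "y", "z", "intensity"]),
            10,
            10,
        )
        out = decode(spots, simple_codebook, DecodeConfig(1.0))
        assert len(out) == 0
        assert "rounds_used" in out.columns

    def test_perfect_recovery(self):
        cb = generate_codebook(20, 4, 4, min_hamming=2, seed=0)
        cfg = SimulationConfig(
            n_transcripts=200, fov_width=200, fov_height=200, seed=1
        )
        spots, truth = simulate(cb, cfg)
        out = decode(spots, cb, DecodeConfig(search_radius=1.0, mode="medium"))
        res = evaluate_decoding(out, truth, 0.5, n_rounds=4)
        assert res["precision"] == 1.0 and res["recall"] == 1.0
        assert (out["rounds_used"] == 4).all()

    def test_error_rounds_requires_hamming_two(self):
        cb = generate_codebook(10, 4, 4, min_hamming=1, seed=2)
        # force a Hamming-1 pair so the gate must trip
        import numpy as np

        from spotdecode.core import Codebook, min_pairwise_hamming

        rows = cb.barcodes.copy()
        rows[1] = rows[0]
        rows[1, 0] = (rows[0, 0] + 1) % 4
        cb = Codebook(cb.targets, rows, cb.is_off_target, cb.n_channels)
        assert min_pairwise_hamming(cb) == 1
        spots = SpotTable(
            pd.DataFrame(
                {
                    "spot_id": [0],
                    "r": [0],
                    "c": [0],
                    "x": [0.0],
                    "y": [0.0],
                    "z": [0.0],
                    "intensity": [1.0],
                }
            ),
            10,
            10,
        )
        with pytest.raises(ValueError, match="Hamming"):
            decode(spots, cb, DecodeConfig(1.0, error_rounds=1))

    def test_error_correction_recovers_partial_barcodes(self):
        cb = generate_codebook(15, 4, 4, min_hamming=2, seed=3)
        cfg = SimulationConfig(n_transcripts=60, fov_width=120, fov_height=120, seed=4)
        spots, truth = simulate(cb, cfg)
        spots, truth = drop_one_round_per_transcript(spots, truth, seed=5)
        out0 = decode(spots, cb, DecodeConfig(1.0, mode="medium", error_rounds=0))
        out1 = decode(spots, cb, DecodeConfig(1.0, mode="medium", error_rounds=1))
        res0 = evaluate_decoding(out0, truth, 0.5, n_rounds=4)
        res1 = evaluate_decoding(out1, truth, 0.5, n_rounds=4)
        assert (out1["rounds_used"] == 3).all()
        assert res1["recall"] > res0["recall"]

    def test_output_spot_disjoint_and_deterministic(self):
        cb = generate_codebook(12, 4, 3, min_hamming=1, seed=6)
        cfg = SimulationConfig(
            n_transcripts=80,
            fov_width=60,
            fov_height=60,
            seed=7,
            drift_sigma=0.3,
            dropout_rate=0.1,
            noise_spot_rate=0.005,
        )
        spots, _ = simulate(cb, cfg)
        config = DecodeConfig(1.0, mode="low")
        out1 = decode(spots, cb, config)
        out2 = decode(spots, cb, config)
        pd.testing.assert_frame_equal(out1, out2)
        all_ids = [s for ids in out1["source_spot_ids"] for s in ids]
        assert len(all_ids) == len(set(all_ids))

    def test_all_targets_in_codebook(self, simple_codebook):
        cfg = SimulationConfig(n_transcripts=30, fov_width=50, fov_height=50, seed=8)
        spots, _ = simulate(simple_codebook, cfg)
        out = decode(spots, simple_codebook, DecodeConfig(1.0))
        assert set(out["target"]) <= set(simple_codebook.targets)
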