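import numpy as np
import pytest

from thermoinv.seqio import GenomeRecord, Interval, reverse_complement
from thermoinv.history import (
    PlacedRepeat,
    ancestral_arrangement,
    apply_events,
    apply_inversion,
    constrained_minimal_scenarios,
    enumerate_minimal_scenarios,
    inversion_distance,
    invert_at_pair,
    pair_cut_points,
    repeat_orientation_timeline,
)
from thermoinv.simulate import make_genome_with_repeats, make_history_dataset
from thermoinv.pipeline import recover_history

from .oracles import distance_by_enumeration


class TestApplyInversion:
    def test_single_block(self):
        assert apply_inversion((1, 2, 3), 1, 1) == (1, -2, 3)

    def test_involution(self):
        p = (3, -1, 2, -4)
        assert apply_inversion(apply_inversion(p, 0, 2), 0, 2) == p

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            apply_inversion((1, 2), 0, 2)

    def test_sequential_composition(self):
        p = apply_events((1, 2, 3, 4), [(1, 2), (0, 3)])
        assert p == (-4, 2, 3, -1) == apply_inversion(apply_inversion((1, 2, 3, 4), 1, 2), 0, 3)


class TestInversionDistance:
    def test_identity(self):
        assert inversion_distance((1, 2, 3)) == 0

    def test_single_inversion(self):
        assert inversion_distance((1, -2, 3)) == 1

    @pytest.mark.parametrize(
        "perm", [(1, -3, -2, 4), (2, 1, 3), (-2, -1, 3), (3, 1, 2), (1, -4, 3, -2)]
    )
    def test_small_instances_match_enumeration(self, perm):
        ident = tuple(range(1, len(perm) + 1))
        assert inversion_distance(perm, ident) == distance_by_enumeration(perm, ident)

    def test_symmetry(self):
        a, b = (2, -1, 3), (1, 2, 3)
        assert inversion_distance(a, b) == inversion_distance(b, a)

    def test_matches_enumeration_on_random_instances(self, rng):
        # instances of known distance <= 3, oracle = exhaustive enumeration
        # of every event sequence up to length 3
        for _ in range(25):
            n = int(rng.integers(4, 8))
            ident = tuple(range(1, n + 1))
            p = ident
            for _ in range(int(rng.integers(1, 4))):
                i = int(rng.integers(n))
                j = int(rng.integers(i, n))
                p = apply_inversion(p, i, j)
            assert inversion_distance(p, ident) == distance_by_enumeration(p, ident)

    def test_size_guard(self):
        with pytest.raises(ValueError, match="n > 12"):
            inversion_distance(tuple(range(1, 14)))


class TestEnumerateScenarios:
    def test_single_inversion_single_scenario(self):
        scen, truncated = enumerate_minimal_scenarios((1, -2, 3))
        assert not truncated and len(scen) == 1
        assert scen[0].events[0].block_range == (1, 1)

    def test_two_independent_inversions_two_orders(self):
        scen, _ = enumerate_minimal_scenarios((-1, 2, -3))
        assert len(scen) == 2
        assert {tuple(e.block_range for e in s.events) for s in scen} == {
            ((0, 0), (2, 2)),
            ((2, 2), (0, 0)),
        }

    def test_every_scenario_reapplies_to_target(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 7))
            p = tuple(range(1, n + 1))
            for _ in range(2):
                i = int(rng.integers(n))
                j = int(rng.integers(i, n))
                p = apply_inversion(p, i, j)
            scen, _ = enumerate_minimal_scenarios(p)
            assert scen
            for s in scen:
                assert apply_events(p, [e.block_range for e in s.events]) == tuple(
                    range(1, n + 1)
                )


class TestRepeatArrangement:
    def test_direct_pair_cannot_fire(self):
        arr = ancestral_arrangement(3, [(1, 0, 1), (2, 0, 1)])
        assert arr.legal_pairs() == []
        with pytest.raises(ValueError, match="direct"):
            arr.apply(0)

    def test_inversion_keeps_pair_inverted_and_flips_interior(self):
        arr = ancestral_arrangement(3, [(1, 0, 1), (2, 0, -1)])
        out = arr.apply(0)
        assert out.block_perm() == (1, -2, 3)
        assert out.pair_orientation(0) == "inverted"
        assert out.apply(0).block_perm() == (1, 2, 3)

    def test_overlapping_inversion_flips_single_contained_copy(self):
        # pair 1 direct, one copy inside pair 0's span: after firing 0 it
        # becomes inverted and usable (the became-opposed dynamics)
        arr = ancestral_arrangement(
            4, [(1, 0, 1), (3, 0, -1), (2, 1, 1), (3, 1, 1)]
        )
        assert arr.legal_pairs() == [0]
        out = arr.apply(0)
        assert out.pair_orientation(1) == "inverted"
        assert 1 in out.legal_pairs()

    def test_constrained_distance_at_least_unconstrained(self):
        arr = ancestral_arrangement(
            4, [(1, 0, 1), (3, 0, -1), (2, 1, 1), (3, 1, 1)]
        )
        target = arr.apply(0).apply(1).block_perm()
        res = constrained_minimal_scenarios(arr, target)
        assert res.reachable and res.distance == 2
        assert res.distance >= inversion_distance((1, 2, 3, 4), target)

    def test_unreachable_reports_diagnostic(self):
        arr = ancestral_arrangement(3, [(1, 0, 1), (2, 0, 1)])  # direct only
        res = constrained_minimal_scenarios(arr, (1, -2, 3), max_depth=4)
        assert not res.reachable and res.scenarios == ()
        assert "not reachable" in res.diagnostic


def _placed(pair_id, a, b, sign_a, sign_b, L):
    return PlacedRepeat(pair_id, Interval(a, a + L), Interval(b, b + L), sign_a, sign_b, L)


class TestSequenceLevelInversion:
    def _genome_with_pairs(self, seed=31):
        g, truth = make_genome_with_repeats(
            length=60_000,
            pair_specs=[(120, "inverted"), (150, "direct"), (200, "inverted")],
            min_separation=6_000,
            margin=3_000,
            seed=seed,
        )
        return g, truth.pairs

    def test_inversion_regenerates_both_copies(self):
        g, pairs = self._genome_with_pairs()
        pid = pairs[0].pair_id
        seq2, pairs2, (pa, pb) = invert_at_pair(g.seq, pairs, pid)
        assert len(seq2) == len(g.seq)
        p = [q for q in pairs2 if q.pair_id == pid][0]
        assert seq2[p.a.start : p.a.end] == g.seq[p.a.start : p.a.end]
        assert seq2[p.b.start : p.b.end] == g.seq[p.b.start : p.b.end]
        # involution at sequence level
        seq3, _, _ = invert_at_pair(seq2, pairs2, pid)
        assert seq3 == g.seq

    def test_flip_rule_exactly_one_copy_inside(self):
        g, pairs = self._genome_with_pairs()
        for pid in [p.pair_id for p in pairs if p.orientation == "inverted"]:
            pa, pb = pair_cut_points([p for p in pairs if p.pair_id == pid][0])
            _, pairs2, _ = invert_at_pair(g.seq, pairs, pid)
            for before, after in zip(pairs, pairs2):
                if before.pair_id == pid:
                    continue
                inside = sum(
                    1 for iv in (before.a, before.b) if pa <= iv.start and iv.end <= pb
                )
                flipped = before.orientation != after.orientation
                assert flipped == (inside == 1)

    def test_timeline_matches_sequence_recheck(self):
        g, pairs = self._genome_with_pairs()
        # fire every initially inverted pair in id order where legal
        events = []
        seq, cur = g.seq, pairs
        for p in sorted(cur, key=lambda p: p.pair_id):
            if [q for q in cur if q.pair_id == p.pair_id][0].orientation == "inverted":
                seq, cur, _ = invert_at_pair(seq, cur, p.pair_id)
                events.append(p.pair_id)
        tl = repeat_orientation_timeline(g, pairs, events)
        assert set(tl.orientation) <= {"direct", "inverted"}
        assert (tl.step.max() == len(events)) and len(tl) == (len(events) + 1) * len(pairs)
        # step 0 equals the planted orientations
        step0 = tl[tl.step == 0].set_index("pair").orientation
        for p in pairs:
            assert step0[p.pair_id] == p.orientation

    def test_no_events_timeline_unchanged(self):
        g, pairs = self._genome_with_pairs()
        tl = repeat_orientation_timeline(g, pairs, [])
        assert len(tl) == len(pairs) and (tl.step == 0).all()


class TestScenarioSequenceRoundtrip:
    def test_enumerated_scenarios_reproduce_derived_genome(self):
        g, der, hist = make_history_dataset(
            2, length=60_000, min_separation=8_000, margin=6_000, seed=33
        )
        rec = recover_history(g, der, truth=hist)
        assert rec.search.reachable and rec.scenario_pair_sequences
        for seq_ids in rec.scenario_pair_sequences:
            planted_ids = [rec.detected_to_planted[i] for i in seq_ids]
            seq, cur = g.seq, list(hist.pairs)
            for pid in planted_ids:
                seq, cur, _ = invert_at_pair(seq, cur, pid)
            res = recover_history(GenomeRecord("replay", seq, circular=True), der)
            assert len(res.comparison.inversions) == 0
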