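import numpy as np
import pytest
from scipy.stats import binomtest

from thermoinv.seqio import GenomeRecord, reverse_complement
from thermoinv.anchors import compare_genomes
from thermoinv.history import repeat_orientation_timeline
from thermoinv.simulate import (
    TruthSet,
    apply_truth_history,
    build_construct_map,
    make_genome_with_repeats,
    make_history_dataset,
    simulate_passaging,
    simulate_reads,
)


class TestGenomeGenerator:
    def test_same_seed_bit_identical(self):
        g1, t1 = make_genome_with_repeats(length=50_000, seed=3, min_separation=4_000, margin=3_000)
        g2, t2 = make_genome_with_repeats(length=50_000, seed=3, min_separation=4_000, margin=3_000)
        assert g1.seq == g2.seq
        assert t1.to_dict() == t2.to_dict()

    def test_truth_coordinates_verify_against_sequence(self):
        g, truth = make_genome_with_repeats(length=80_000, seed=4, min_separation=8_000, margin=3_000)
        for p in truth.pairs:
            a = g.seq[p.a.start : p.a.end]
            b = g.seq[p.b.start : p.b.end]
            assert a == (reverse_complement(b) if p.orientation == "inverted" else b)

    def test_planted_cores_are_maximal(self):
        from thermoinv.forensics import longest_shared_segment

        g, truth = make_genome_with_repeats(length=60_000, seed=5, min_separation=6_000, margin=3_000)
        for p in truth.pairs:
            seg = longest_shared_segment(
                g.seq[p.a.start - 50 : p.a.end + 50],
                g.seq[p.b.start - 50 : p.b.end + 50],
                p.orientation,
            )
            assert seg.length == p.core_len

    def test_zero_pairs_single_block_self_comparison(self):
        g, truth = make_genome_with_repeats(
            length=30_000, pair_specs=[], seed=6, min_separation=0, margin=100
        )
        assert truth.pairs == []
        res = compare_genomes(g, g)
        assert len(res.blocks) == 1 and res.permutation == (1,)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            make_genome_with_repeats(
                length=10_000, pair_specs=[(600, "inverted")] * 5, min_separation=5_000, seed=7
            )

    def test_truthset_roundtrip_and_regeneration(self, tmp_path):
        g, truth = make_genome_with_repeats(length=40_000, seed=8, min_separation=3_000, margin=3_000)
        path = tmp_path / "truth.json"
        truth.save(str(path))
        import json

        loaded = TruthSet.from_dict(json.load(open(path)))
        assert loaded.to_dict() == truth.to_dict()
        g2, _ = make_genome_with_repeats(**{k: loaded.params[k] for k in
                                            ("length", "gc", "min_separation", "margin", "seed")},
                                         pair_specs=loaded.params["pair_specs"])
        assert g2.seq == g.seq


class TestHistoryGenerator:
    def test_single_event_single_minus_run(self):
        g, der, hist = make_history_dataset(
            1, length=50_000, min_separation=8_000, margin=6_000, seed=9
        )
        res = compare_genomes(g, der, max_gap=2_000)
        assert len(res.inversions) == 1

    def test_derived_genome_preserves_length_and_composition(self):
        g, der, hist = make_history_dataset(3, length=80_000, min_separation=9_000, seed=10)
        assert len(der.seq) == len(g.seq)
        assert sorted(der.seq.count(b) + der.seq.count({"A": "T", "T": "A", "C": "G", "G": "C"}[b])
                      for b in "AC") == sorted(g.seq.count(b) + g.seq.count(
                          {"A": "T", "T": "A", "C": "G", "G": "C"}[b]) for b in "AC")

    def test_became_opposed_pair_is_used_after_overlapping_event(self):
        # pair 1 is planted direct with exactly one copy inside pair 0's
        # span; after pair 0 fires, pair 1 flips to inverted and fires
        g, truth = make_genome_with_repeats(
            length=50_000,
            pair_specs=[(100, "inverted"), (100, "direct")],
            min_separation=6_000,
            margin=6_000,
            seed=2,
        )
        der, hist = apply_truth_history(g, truth, 2, seed=0)
        assert hist.events == [0, 1]
        tl = repeat_orientation_timeline(g, truth.pairs, hist.events)
        p1 = tl[tl.pair == 1].sort_values("step").orientation.tolist()
        assert p1 == ["direct", "inverted", "inverted"]


class TestReadSimulator:
    def test_read_count_formula_and_determinism(self):
        g, _ = make_genome_with_repeats(length=20_000, pair_specs=[], seed=11,
                                        min_separation=0, margin=100)
        reads, truth = simulate_reads([(g, 1.0)], coverage=10, read_len=100, err=0.01, seed=12)
        assert len(reads) == round(10 * 20_000 / 100)
        reads2, _ = simulate_reads([(g, 1.0)], coverage=10, read_len=100, err=0.01, seed=12)
        assert reads == reads2

    def test_error_free_reads_occur_verbatim_circular(self):
        g, _ = make_genome_with_repeats(length=5_000, pair_specs=[], seed=13,
                                        min_separation=0, margin=100)
        doubled = g.seq + g.seq
        reads, _ = simulate_reads([(g, 1.0)], coverage=3, read_len=100, err=0.0, seed=14)
        for name, seq, qual in reads:
            assert seq in doubled or reverse_complement(seq) in doubled
            assert len(qual) == 100

    def test_fraction_validation_and_read_len_guard(self):
        g, _ = make_genome_with_repeats(length=2_000, pair_specs=[], seed=15,
                                        min_separation=0, margin=100)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_reads([(g, 0.5)], seed=0)
        with pytest.raises(ValueError, match="read_len"):
            simulate_reads([(g, 1.0)], read_len=3_000, seed=0)

    def test_junction_spanning_counts_match_mixture_fraction(self):
        g, der, hist = make_history_dataset(
            2, length=20_000, min_separation=2_500, margin=1_500, seed=16,
            interleave=False,
        )
        reads, _ = simulate_reads([(g, 0.3), (der, 0.7)], coverage=100, read_len=150,
                                  err=0.0, seed=17)
        p = [q for q in hist.derived_pairs if q.pair_id == hist.events[0]][0]
        j = p.a.end  # junction: divergence starts at the core end
        n_der = n_tot = 0
        L = len(g.seq)
        for name, seq, qual in reads:
            meta = dict(kv.split("=") for kv in name.split("|")[1:])
            pos = int(meta["pos"])
            if (pos <= j - 10 and j + 10 <= pos + 150) or (
                pos <= j + L - 10 and j + L + 10 <= pos + 150
            ):
                n_tot += 1
                n_der += meta["src"] == "derived"
        assert n_tot > 50
        assert binomtest(n_der, n_tot, 0.7).pvalue > 0.01


class TestConstructs:
    def test_pmc479_satisfies_printed_constraints(self):
        from thermoinv.recombine import digest

        mol = build_construct_map("pMC479_like", seed=20)
        assert len(mol) == 4573
        assert digest(mol, "CATATG").fragments == (3207, 1366)
        sites = sorted(mol.sites, key=lambda s: s.location.start)
        assert len(sites[0].location) == 87 and len(sites[1].location) == 43
        # direct orientation, identical 43 bp cores
        assert mol.core_seq(sites[0]) == mol.core_seq(sites[1])
        assert sites[1].location.start - sites[0].location.end == 762

    def test_pmc477_unsatisfiable_constraints_error(self):
        with pytest.raises(ValueError, match="digest"):
            build_construct_map(
                "pMC477_like", seed=21, pre_digest=(4000, 573), post_digest=(4500, 73)
            )

    def test_unknown_template(self):
        with pytest.raises(ValueError, match="template"):
            build_construct_map("pUC18_like", seed=0)


class TestPassaging:
    def _pairs(self, seed=22):
        _, truth = make_genome_with_repeats(
            length=60_000, seed=seed, min_separation=6_000, margin=3_000
        )
        return truth.pairs

    def test_zero_rate_monomorphic(self):
        traj = simulate_passaging(self._pairs(), inv_rate=0.0, generations=30, seed=23)
        df = traj.frame()
        assert (df.state == ()).all() and (df.frequency == 1.0).all()

    def test_frequencies_sum_to_one_every_passage(self):
        traj = simulate_passaging(self._pairs(), inv_rate=5e-3, generations=60, seed=24)
        df = traj.frame()
        sums = df.groupby("passage").frequency.sum()
        assert np.allclose(sums, 1.0)

    def test_high_rate_derived_states_reach_majority_in_some_replicates(self):
        hits = 0
        for seed in range(5):
            traj = simulate_passaging(
                self._pairs(), inv_rate=0.05, generations=60, seed=seed
            )
            df = traj.frame()
            last = df[df.passage == df.passage.max()]
            if (last[last.state != ()].frequency > 0.5).any():
                hits += 1
        assert hits >= 1

    def test_states_grow_only_by_legal_moves(self):
        traj = simulate_passaging(self._pairs(), inv_rate=1e-2, generations=30, seed=25)
        for state in {s for s in traj.frame().state}:
            assert len(set(state)) == len(state)  # a pair fires at most once
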