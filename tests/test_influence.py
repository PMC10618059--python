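import itertools

import numpy as np
import pytest

from booldoi import (
    SeedSet,
    build_gtn,
    doi_bfs,
    ground_truth,
    ibmfa_doi,
    ibmfa_run,
    mean_trajectory,
    parse_rules,
)
from booldoi.synthetic import RBNSpec, chain_network, random_network


class TestSeedSet:
    def test_contradictory_pins_rejected(self):
        with pytest.raises(ValueError):
            SeedSet.from_pairs([("a", 0), ("a", 1)])

    def test_string_round_trip(self):
        X = SeedSet.from_string("a=1,c=0")
        assert X.as_dict() == {"a": 1, "c": 0}
        assert SeedSet.from_string(str(X)) == X

    def test_empty_specification(self):
        assert len(SeedSet.from_string("")) == 0

    def test_invalid_specification_rejected(self):
        with pytest.raises(ValueError):
            SeedSet.from_string("a=2")


class TestDoiBfs:
    def test_reduced_representations_infer_the_target(self, toy_gtns, seeds_ac):
        for rep in ("DNF", "SR"):
            D = doi_bfs(toy_gtns[rep], seeds_ac)
            assert D.members == frozenset({("a", 1), ("c", 1), ("d", 1)})

    def test_raw_lut_representation_cannot(self, toy_gtns, seeds_ac):
        D = doi_bfs(toy_gtns["LUT"], seeds_ac)
        assert D.members == frozenset({("a", 1), ("c", 1)})

    def test_levels_record_bfs_stages(self, toy_gtns, seeds_ac):
        D = doi_bfs(toy_gtns["DNF"], seeds_ac)
        assert D.levels[("a", 1)] == 0
        assert D.levels[("c", 1)] == 0
        assert D.levels[("d", 1)] == 1

    def test_full_pinning_returns_exactly_the_seed_set(self, toy_gtns):
        X = SeedSet.from_pairs([("a", 1), ("b", 0), ("c", 1), ("d", 0)])
        for g in toy_gtns.values():
            assert doi_bfs(g, X).members == X.pins

    def test_seed_absent_from_gtn_rejected(self, toy_gtns):
        with pytest.raises(KeyError):
            doi_bfs(toy_gtns["DNF"], SeedSet.from_string("zz=1"))

    def test_agreement_of_dnf_and_sr_on_all_toy_singletons(self, toy, toy_gtns):
        for n in toy.nodes:
            for v in (0, 1):
                X = SeedSet.from_pairs([(n, v)])
                assert (
                    doi_bfs(toy_gtns["DNF"], X).members
                    == doi_bfs(toy_gtns["SR"], X).members
                )

    def test_containment_seed_subset_of_domain(self):
        for seed in range(4):
            net = random_network(RBNSpec(N=6, K=2, seed=seed))
            gtns = {rep: build_gtn(net, rep) for rep in ("LUT", "DNF", "SR")}
            X = SeedSet.from_pairs([(net.nodes[0], 1), (net.nodes[3], 0)])
            for g in gtns.values():
                D = doi_bfs(g, X)
                assert X.pins <= D.members
                by_node = {}
                for i, v in D.members:
                    assert by_node.setdefault(i, v) == v


class TestIbmfa:
    def test_unseeded_activation_is_the_onset_fraction(self, toy):
        traj = ibmfa_run(toy, SeedSet(frozenset()), T=1)
        assert traj.s("d", 1) == pytest.approx(3 / 8, abs=1e-15)

    def test_pinned_inputs_drive_target_to_one(self, toy, seeds_ac):
        traj = ibmfa_run(toy, seeds_ac, T=10)
        for t in range(1, 11):
            assert traj.s("d", t) == 1.0

    def test_signal_takes_one_step_per_hop_on_chains(self):
        net = chain_network(3)
        traj = ibmfa_run(net, SeedSet.from_string("x1=1"), T=3)
        assert traj.s("x3", 1) == 0.5
        assert traj.s("x3", 2) == 1.0

    def test_negation_self_loop_stays_uncertain(self):
        net = parse_rules("x = NOT x")
        X = SeedSet(frozenset())
        traj = ibmfa_run(net, X, T=10)
        assert all(traj.s("x", t) == 0.5 for t in range(11))
        assert len(ibmfa_doi(net, X, T=10)) == 0

    def test_doi_on_the_toy_example(self, toy, seeds_ac):
        D = ibmfa_doi(toy, seeds_ac, T=10)
        assert D.members == frozenset({("a", 1), ("c", 1), ("d", 1)})

    def test_no_seeds_on_copy_chain_gives_empty_domain(self):
        net = chain_network(4)
        assert len(ibmfa_doi(net, SeedSet(frozenset()), T=10)) == 0

    @pytest.mark.parametrize("L", [1, 3, 5])
    @pytest.mark.parametrize("pin", [0, 1])
    def test_exact_on_chains(self, L, pin):
        """Single-input trees develop no input correlations, so the
        mean-field activation equals the exhaustive average exactly."""
        net = chain_network(L)
        X = SeedSet.from_pairs([("x1", pin)])
        traj = ibmfa_run(net, X, T=10)
        nodes, means = mean_trajectory(net, X, T=10, mode="brute")
        assert np.allclose(traj.values, means, atol=1e-12)


class TestGroundTruth:
    def test_exhaustive_toy_domain(self, toy, seeds_ac):
        means, D = ground_truth(toy, seeds_ac, mode="brute")
        assert D.members == frozenset({("a", 1), ("c", 1), ("d", 1)})
        assert means["b"] == 0.5
        assert D.params["R"] == 4

    def test_full_pinning_any_mode(self, toy):
        X = SeedSet.from_pairs([("a", 0), ("b", 1), ("c", 0), ("d", 1)])
        _, D = ground_truth(toy, X, mode="brute")
        assert D.members == X.pins
        with pytest.warns(UserWarning):  # R exceeds the empty free space
            _, D = ground_truth(toy, X, mode="sample", R=5, rng=0)
        assert D.members == X.pins

    def test_brute_mode_ignores_rng(self, toy, seeds_ac):
        _, D1 = ground_truth(toy, seeds_ac, mode="brute", rng=1)
        _, D2 = ground_truth(toy, seeds_ac, mode="brute", rng=2)
        assert D1.members == D2.members

    def test_sample_mode_reproducible_under_seed(self):
        net = random_network(RBNSpec(N=12, K=2, seed=5))
        X = SeedSet.from_pairs([(net.nodes[0], 1)])
        _, D1 = ground_truth(net, X, mode="sample", R=50, rng=42)
        _, D2 = ground_truth(net, X, mode="sample", R=50, rng=42)
        assert D1.members == D2.members

    def test_auto_mode_selects_brute_for_small_free_space(self, toy, seeds_ac):
        _, D = ground_truth(toy, seeds_ac, mode="auto")
        assert D.params["mode"] == "brute"

    def test_oversampling_warns(self, toy, seeds_ac):
        with pytest.warns(UserWarning, match="replacement"):
            ground_truth(toy, seeds_ac, mode="sample", R=100, rng=0)

    def test_unknown_seed_node_rejected(self, toy):
        with pytest.raises(KeyError):
            ground_truth(toy, SeedSet.from_string("zz=1"))

    def test_strict_window_is_never_more_permissive(self):
        # The window check demands constancy over [T, T+w], so it can only
        # shrink the single-time domain; genuinely fixed nodes survive it.
        for seed in range(5):
            net = random_network(RBNSpec(N=7, K=2, seed=seed))
            X = SeedSet.from_pairs([(net.nodes[0], 1)])
            _, D_single = ground_truth(net, X, mode="brute")
            _, D_window = ground_truth(net, X, mode="brute", window=3)
            assert D_window.members <= D_single.members
            assert X.pins <= D_window.members


class TestPerfectPrecision:
    def test_gtn_domains_are_contained_in_exhaustive_truth(self):
        """Logical inference on a GTN is sound: every derived state is
        deterministic in the exhaustive ground truth (precision 1)."""
        mismatches = []
        for seed in range(8):
            net = random_network(RBNSpec(N=6, K=2, seed=seed))
            gtns = {rep: build_gtn(net, rep) for rep in ("LUT", "DNF", "SR")}
            for n, v in itertools.product(net.nodes[:3], (0, 1)):
                X = SeedSet.from_pairs([(n, v)])
                _, D = ground_truth(net, X, mode="brute")
                for rep, g in gtns.items():
                    DZ = doi_bfs(g, X)
                    if not DZ.members <= D.members:
                        mismatches.append((seed, n, v, rep))
        assert mismatches == []
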