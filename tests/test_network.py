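import itertools

import numpy as np
import pytest

from booldoi import (
    BooleanNetwork,
    RuleFileError,
    SeedSet,
    TransferFunction,
    materialize_lut,
    parse_rules,
    step,
    trajectory,
    write_rules,
)
from booldoi.expr import parse_expression
from booldoi.network import (
    config_from_json,
    config_to_json,
    read_lut_table,
    write_lut_table,
)
from booldoi.synthetic import RBNSpec, random_network
from oracles import truth_table

TOY_RULES = "d = (a AND c) OR (b AND c)\n"


class TestParseRules:
    def test_undeclared_symbols_become_identity_inputs(self):
        net = parse_rules(TOY_RULES)
        assert net.N == 4
        assert set(net.nodes) == {"a", "b", "c", "d"}
        # first-appearance order of d's inputs in the expression
        assert net.inputs["d"] == ["a", "c", "b"]
        for n in "abc":
            assert net.inputs[n] == [n]
            assert net.lut(n) == (0, 1)

    def test_negation_self_loop(self):
        net = parse_rules("x = NOT x")
        assert net.N == 1
        assert net.inputs["x"] == ["x"]
        assert net.lut("x") == (1, 0)

    def test_cell_collective_dialect(self):
        text = "targets, factors\nd, (a AND c) OR (b AND c)\n"
        net = parse_rules(text, dialect="cell_collective")
        assert set(net.nodes) == {"a", "b", "c", "d"}
        assert net.lut("d") == parse_rules(TOY_RULES).lut("d")

    def test_comments_and_blank_lines_ignored(self):
        net = parse_rules("# header\n\nx = y  # trailing\n")
        assert set(net.nodes) == {"x", "y"}

    @pytest.mark.parametrize(
        "bad,match",
        [
            ("x = AND y", "line 1"),
            ("x = y\nx = z", "duplicate rule"),
            ("just words", "expected"),
        ],
    )
    def test_errors_report_lines(self, bad, match):
        with pytest.raises(RuleFileError, match=match):
            parse_rules(bad)

    @pytest.mark.parametrize("seed", range(6))
    def test_write_parse_round_trip_preserves_every_lut(self, seed):
        net = random_network(RBNSpec(N=6, K=2, bias=0.5, seed=seed))
        net2 = parse_rules(write_rules(net))
        assert set(net2.nodes) == set(net.nodes)
        for n in net.nodes:
            assert net2.inputs[n] == net.inputs[n]
            assert net2.lut(n) == net.lut(n)

    def test_round_trip_preserves_constant_nodes(self):
        # bias 0/1 produce constant LUTs whose inputs must survive
        for bias in (0.0, 1.0):
            net = random_network(RBNSpec(N=4, K=2, bias=bias, seed=3))
            net2 = parse_rules(write_rules(net))
            for n in net.nodes:
                assert net2.inputs[n] == net.inputs[n]
                assert net2.lut(n) == net.lut(n)


class TestMaterializeLut:
    def test_toy_rule_has_three_active_rows(self, toy):
        lut = toy.lut("d")
        k = 3
        ones = {
            tuple((r >> (k - 1 - j)) & 1 for j in range(k))
            for r in range(8)
            if lut[r]
        }
        assert ones == {(0, 1, 1), (1, 0, 1), (1, 1, 1)}

    def test_nullary_constant(self):
        tf = TransferFunction(arity=0, expression=parse_expression("TRUE"))
        assert materialize_lut(tf, []) == (1,)

    def test_idempotent_when_lut_present(self):
        tf = TransferFunction(arity=1, lut=(1, 0))
        assert materialize_lut(tf, ["a"]) == (1, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_expression_evaluation(self, seed):
        from oracles import random_expression

        rng = np.random.default_rng(seed)
        names = ["a", "b", "c"]
        e = random_expression(rng, names)
        tf = TransferFunction(arity=3, expression=e)
        assert materialize_lut(tf, names) == truth_table(e, names)

    def test_unknown_symbol_rejected(self):
        tf = TransferFunction(arity=1, expression=parse_expression("zz"))
        with pytest.raises(Exception, match="zz"):
            materialize_lut(tf, ["a"])

    def test_expression_lut_disagreement_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            BooleanNetwork(
                ["x"],
                {"x": ["x"]},
                {"x": TransferFunction(1, parse_expression("x"), (1, 0))},
            )


class TestStep:
    def test_pinned_inputs_force_target_next_step(self, toy):
        pins = {"a": 1, "c": 1}
        for b, d in itertools.product((0, 1), repeat=2):
            config = {"a": 0, "b": b, "c": 0, "d": d}
            nxt = step(toy, {**config, **pins}, pins)
            assert nxt["d"] == 1

    def test_identity_network_is_fixed_point(self):
        net = parse_rules("a = a\nb = b")
        config = {"a": 1, "b": 0}
        assert step(net, config) == config

    def test_copy_cycle_has_period_three(self):
        net = parse_rules("a = c\nb = a\nc = b")
        config = {"a": 1, "b": 0, "c": 0}
        orbit = [config]
        for _ in range(3):
            orbit.append(step(net, orbit[-1]))
        assert orbit[3] == orbit[0]
        assert len({tuple(sorted(c.items())) for c in orbit[:3]}) == 3

    def test_step_is_deterministic(self, toy):
        config = {"a": 1, "b": 0, "c": 1, "d": 0}
        assert step(toy, config) == step(toy, config)

    def test_seedset_accepted_as_pinning(self, toy):
        pins = SeedSet.from_string("a=1,c=1")
        assert step(toy, {"a": 1, "b": 0, "c": 1, "d": 0}, pins)["a"] == 1


class TestTrajectory:
    def test_zero_steps_returns_initial(self, toy):
        config = {"a": 0, "b": 0, "c": 0, "d": 0}
        assert trajectory(toy, config, T=0) == [config]

    def test_prefix_property(self, toy):
        config = {"a": 1, "b": 0, "c": 0, "d": 1}
        full = trajectory(toy, config, T=6)
        for t in range(7):
            assert trajectory(toy, config, T=t) == full[: t + 1]

    def test_pinned_target_active_from_t1_for_all_initials(self, toy):
        pins = {"a": 1, "c": 1}
        for b, d in itertools.product((0, 1), repeat=2):
            traj = trajectory(toy, {"a": 0, "b": b, "c": 0, "d": d}, pins, T=5)
            assert all(c["d"] == 1 for c in traj[1:])

    @pytest.mark.parametrize("seed", range(5))
    def test_enters_cycle_within_state_space_bound(self, seed):
        net = random_network(RBNSpec(N=6, K=2, seed=seed))
        config = {n: 0 for n in net.nodes}
        seen = set()
        current = config
        for _ in range(2**net.N + 1):
            key = tuple(current[n] for n in net.nodes)
            if key in seen:
                break
            seen.add(key)
            current = step(net, current)
        else:
            pytest.fail("no revisit within 2^N steps")

    @pytest.mark.parametrize("seed", range(4))
    def test_vectorized_ensemble_matches_reference_step(self, seed):
        net = random_network(RBNSpec(N=7, K=3, seed=seed))
        rng = np.random.default_rng(seed)
        states = rng.integers(0, 2, size=(16, net.N), dtype=np.uint8)
        compiled = net.compiled()
        stepped = compiled.step_ensemble(states)
        for row, out in zip(states, stepped):
            config = dict(zip(net.nodes, (int(b) for b in row)))
            expected = step(net, config)
            assert [expected[n] for n in net.nodes] == list(out)


class TestSerialization:
    def test_lut_table_round_trip(self, toy):
        node, ins, lut = read_lut_table(write_lut_table(toy, "d"))
        assert node == "d"
        assert ins == ["a", "b", "c"]
        assert lut == toy.lut("d")

    def test_incomplete_lut_table_rejected(self, toy):
        text = write_lut_table(toy, "d")
        truncated = "\n".join(text.splitlines()[:-2])
        with pytest.raises(RuleFileError, match="incomplete"):
            read_lut_table(truncated)

    def test_config_json_round_trip(self):
        config = {"a": 1, "b": 0}
        assert config_from_json(config_to_json(config)) == config
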