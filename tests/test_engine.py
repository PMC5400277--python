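"""Unit and property tests of the synchronous Boolean engine."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gynogrn.engine import (
    And,
    Const,
    ModelValidationError,
    NetworkModel,
    Not,
    Or,
    StateSpaceTooLargeError,
    Var,
    bitstring_to_state,
    clamp,
    enumerate_attractors,
    evaluate_rule,
    fixed_points,
    relabel,
    simulate,
    state_to_bitstring,
    synchronous_step,
)
from gynogrn.synthetic import GeneratorSpec, random_boolean_network


def two_node(rule_a, rule_b):
    return NetworkModel(["A", "B"], {"A": rule_a, "B": rule_b})


class TestRuleEvaluation:
    @pytest.mark.parametrize("spt, arr1p, expected", [
        (1, 1, 1),   # AND-gate: both regulators present
        (1, 0, 0),   # cooperative regulation fails with one absent
        (0, 1, 0),
        (0, 0, 0),
    ])
    def test_and_gate_truth_table(self, spt, arr1p, expected):
        model = NetworkModel(
            ["SPT", "ARR1P", "T"],
            {"SPT": Var("SPT"), "ARR1P": Var("ARR1P"),
             "T": And(Var("SPT"), Var("ARR1P"))})
        state = (spt, arr1p, 0)
        assert evaluate_rule(model.rules["T"], state, model) == expected

    @pytest.mark.parametrize("ck, ahp6, expected", [
        (1, 1, 0),  # repression wins
        (1, 0, 1),
        (0, 0, 0),
    ])
    def test_repression_by_negation(self, ck, ahp6, expected):
        model = NetworkModel(
            ["CK", "AHP6", "OUT"],
            {"CK": Var("CK"), "AHP6": Var("AHP6"),
             "OUT": And(Var("CK"), Not(Var("AHP6")))})
        state = (ck, ahp6, 0)
        assert evaluate_rule(model.rules["OUT"], state, model) == expected

    def test_undeclared_literal_rejected(self):
        with pytest.raises(ModelValidationError, match="GHOST"):
            NetworkModel(["A"], {"A": Var("GHOST")})

    def test_evaluation_is_pure(self):
        model = two_node(Or(Var("A"), Var("B")), Var("A"))
        state = (1, 0)
        before = tuple(state)
        evaluate_rule(model.rules["A"], state, model)
        assert state == before


class TestSynchronousStep:
    def test_constant_network_jumps_to_all_ones(self):
        model = NetworkModel(["A", "B", "C"],
                             {n: Const(1) for n in "ABC"})
        assert synchronous_step(model, (0, 0, 0)) == (1, 1, 1)

    def test_toggle_from_00(self, toggle_model):
        assert synchronous_step(toggle_model, (0, 0)) == (1, 1)

    def test_core_model_one_step_activates_arr1(self, core_model):
        state = core_model.state_from_mapping({"CK": 1, "SPT": 1})
        nxt = synchronous_step(core_model, state)
        assert nxt[core_model.index("ARR1")] == 1

    def test_inputs_keep_their_value(self, core_model):
        state = core_model.state_from_mapping({"CK": 1, "SPT": 0})
        nxt = synchronous_step(core_model, state)
        assert nxt[core_model.index("CK")] == 1
        assert nxt[core_model.index("SPT")] == 0

    def test_determinism(self, toggle_model):
        s = (0, 1)
        assert synchronous_step(toggle_model, s) == \
            synchronous_step(toggle_model, tuple(s))


class TestSimulate:
    def test_fixed_point_trajectory_has_length_one(self, toggle_model):
        traj = simulate(toggle_model, (0, 1))
        assert len(traj) == 1 and traj.terminal == 0
        assert traj.attractor_states == [(0, 1)]

    def test_toggle_enters_two_cycle(self, toggle_model):
        traj = simulate(toggle_model, (0, 0))
        assert traj.terminal == 0
        assert set(traj.attractor_states) == {(0, 0), (1, 1)}

    def test_core_reaches_all_active_within_n_steps(self, core_model):
        init = core_model.state_from_mapping({"CK": 1, "SPT": 1})
        traj = simulate(core_model, init, max_steps=core_model.n)
        assert not traj.truncated
        assert traj.states[-1] == (1,) * core_model.n

    def test_truncation_is_flagged_not_silent(self):
        # 3-bit counter-ish chain takes several steps to settle
        model = NetworkModel(
            ["A", "B", "C"],
            {"A": Const(1), "B": Var("A"), "C": Var("B")})
        traj = simulate(model, (0, 0, 0), max_steps=2)
        assert traj.truncated and traj.terminal is None
        with pytest.raises(ValueError):
            traj.attractor_states


class TestFixedPoints:
    def test_constant_all_true(self):
        model = NetworkModel(["A", "B", "C"], {n: Const(1) for n in "ABC"})
        assert fixed_points(model) == [(1, 1, 1)]

    def test_toggle_fixed_points(self, toggle_model):
        assert fixed_points(toggle_model) == [(0, 1), (1, 0)]

    def test_identity_input_node_has_both(self):
        model = NetworkModel(["A"], {"A": Var("A")})
        assert fixed_points(model) == [(0,), (1,)]

    def test_size_cap_refused(self):
        n = 25
        names = [f"X{i}" for i in range(n)]
        model = NetworkModel(names, {nm: Const(0) for nm in names})
        with pytest.raises(StateSpaceTooLargeError):
            fixed_points(model)
        with pytest.raises(StateSpaceTooLargeError):
            enumerate_attractors(model)


class TestEnumerateAttractors:
    def test_toggle_attractor_census(self, toggle_model):
        atts = enumerate_attractors(toggle_model)
        assert len(atts) == 3
        reps = {a.representative: (a.kind, a.basin_size) for a in atts}
        assert reps[(0, 1)] == ("fixed_point", 1)
        assert reps[(1, 0)] == ("fixed_point", 1)
        assert reps[(0, 0)] == ("cycle", 2)
        # canonical cycle starts at its smallest bitstring
        cyc = next(a for a in atts if a.kind == "cycle")
        assert cyc.states == ((0, 0), (1, 1))

    def test_basins_partition_state_space(self, toggle_model, core_model):
        for model in (toggle_model, core_model):
            atts = enumerate_attractors(model)
            assert sum(a.basin_size for a in atts) == 2 ** model.n

    def test_fixed_points_equal_length_one_attractors(self, core_model):
        atts = enumerate_attractors(core_model)
        fps = [a.representative for a in atts if a.is_fixed_point]
        assert fps == fixed_points(core_model)

    def test_sorted_by_representative(self, core_model):
        atts = enumerate_attractors(core_model)
        reps = [a.representative for a in atts]
        assert reps == sorted(reps)


class TestClamp:
    def test_clamped_node_invariant_along_trajectory(self, core_model):
        model = clamp(core_model, "SPT", 0)
        i = model.index("SPT")
        traj = simulate(model, (1,) * model.n)
        assert all(s[i] == 0 for s in traj.states[1:])

    def test_clamp_leaves_other_rules_unchanged(self, core_model):
        clamped = clamp(core_model, "TAA1", 0)
        for name in core_model.nodes:
            if name != "TAA1":
                assert clamped.rules[name] == core_model.rules[name]
        assert core_model.rules["TAA1"] != clamped.rules["TAA1"]

    def test_clamp_is_idempotent(self, core_model):
        once = clamp(core_model, "PIN3", 0)
        twice = clamp(once, "PIN3", 0)
        assert once.rules == twice.rules

    def test_unknown_node_named_in_error(self, core_model):
        with pytest.raises(ModelValidationError, match="WUS"):
            clamp(core_model, "WUS", 0)


class TestRelabeling:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 6))
    def test_relabeling_preserves_attractor_structure(self, seed, n):
        model = random_boolean_network(
            GeneratorSpec(n_nodes=n, in_degree=min(2, n - 1), seed=seed))
        mapping = {name: f"G_{name}" for name in model.nodes}
        renamed = relabel(model, mapping)
        a1 = enumerate_attractors(model)
        a2 = enumerate_attractors(renamed)
        assert len(a1) == len(a2)
        assert sorted(a.basin_size for a in a1) == \
            sorted(a.basin_size for a in a2)
        assert sorted(len(a) for a in a1) == sorted(len(a) for a in a2)


def test_bitstring_round_trip():
    state = (1, 0, 1, 1, 0)
    assert bitstring_to_state(state_to_bitstring(state)) == state
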