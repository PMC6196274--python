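"""Tests for asynchronous Monte-Carlo evolution and treatment simulation."""

import itertools

import numpy as np
import pytest

from glionet import (
    SystemState,
    TreatmentSpec,
    TrialConfig,
    ValidationError,
    apply_treatment,
    async_successors,
    evolve_to_attractor,
    image_vector,
    run_treatment_trials,
    standard_treatments,
)
from glionet.model import StateSignature

from conftest import naive_image


class TestSuccessors:
    def test_fixed_point_has_no_successors(self, net, ss0_state, ss1_state):
        assert async_successors(ss0_state, net) == []
        assert async_successors(ss1_state, net) == []

    def test_one_successor_per_differing_entity(self, toy_mutual_activation):
        state = SystemState((1, -1))  # image is (-1, 1): both entities move
        succ = async_successors(state, toy_mutual_activation)
        assert {s.values for s in succ} == {(0, -1), (1, 0)}

    def test_two_level_gap_moves_one_step_only(self):
        """An entity at -1 preferring +1 passes through 0, never jumps."""
        from glionet import RegulatoryNetwork

        chain = RegulatoryNetwork(["A", "B"], [("A", 1, "B")])
        succ = async_successors(SystemState((1, -1)), chain)
        assert [s.values for s in succ] == [(1, 0)]

    def test_matches_naive_transition_graph_on_toys(
        self, toy_mutual_activation, toy_negative_feedback
    ):
        """Successor sets agree with a brute-force derivation for all 9 states."""
        for network in (toy_mutual_activation, toy_negative_feedback):
            for state in itertools.product((-1, 0, 1), repeat=2):
                img = naive_image(state, network)
                expected = set()
                for k in range(2):
                    if img[k] != state[k]:
                        moved = list(state)
                        moved[k] += 1 if img[k] > state[k] else -1
                        expected.add(tuple(moved))
                got = {s.values for s in async_successors(SystemState(state), network)}
                assert got == expected


class TestEvolution:
    def test_fixed_point_terminates_immediately(self, net, ss0_state):
        record = evolve_to_attractor(ss0_state, net, seed=5)
        assert record.converged and record.steps == 0
        assert record.terminal.values == ss0_state.values

    def test_negative_feedback_always_reaches_baseline(self, toy_negative_feedback):
        for seed in range(20):
            record = evolve_to_attractor(
                SystemState((1, 0)), toy_negative_feedback, seed=seed
            )
            assert record.converged
            assert record.terminal.values == (0, 0)

    def test_same_seed_same_trajectory(self, net, ss1_state):
        perturbed = apply_treatment(
            ss1_state, standard_treatments()["BAA"], net
        )
        a = evolve_to_attractor(perturbed, net, seed=123)
        b = evolve_to_attractor(perturbed, net, seed=123)
        assert a.terminal.values == b.terminal.values
        assert a.steps == b.steps

    def test_converged_terminals_are_verified_fixed_points(self, net, tables, ss1_state):
        for seed in range(25):
            perturbed = apply_treatment(
                ss1_state, standard_treatments()["IST+GRB"], net
            )
            record = evolve_to_attractor(perturbed, net, tables, seed=seed)
            if record.converged:
                img = image_vector(record.terminal, net, tables)
                assert img.values == record.terminal.values


class TestApplyTreatment:
    def test_delta_mode_clips_at_ternary_bounds(self, net, ss1_state):
        grb = standard_treatments("delta")["GRB"]
        shifted = apply_treatment(ss1_state, grb, net)
        assert shifted.as_dict(net)["CORT"] == 0  # 1 + (-1)
        twice = apply_treatment(apply_treatment(ss1_state, grb, net), grb, net)
        assert twice.as_dict(net)["CORT"] == -1  # clipped thereafter

    def test_set_mode_pins_the_value(self, net, ss1_state):
        grb = standard_treatments("set")["GRB"]
        assert apply_treatment(ss1_state, grb, net).as_dict(net)["CORT"] == -1

    def test_untouched_entities_are_preserved(self, net, ss1_state):
        grb = standard_treatments()["GRB"]
        before = ss1_state.as_dict(net)
        after = apply_treatment(ss1_state, grb, net).as_dict(net)
        assert {k: v for k, v in after.items() if k != "CORT"} == {
            k: v for k, v in before.items() if k != "CORT"
        }

    def test_empty_treatment_is_identity(self, net, ss1_state):
        null = TreatmentSpec.from_mapping("null", {})
        assert apply_treatment(ss1_state, null, net).values == ss1_state.values

    def test_standard_strategy_definitions(self):
        specs = standard_treatments()
        assert dict(specs["GRB"].shifts) == {"CORT": -1}
        assert dict(specs["IST"].shifts) == {"IL1b": -1, "IL6": -1, "TNFa": -1}
        assert set(dict(specs["BAA"].shifts)) == {"Microglia", "IL1b", "IL6", "TNFa"}
        assert set(dict(specs["IST+GRB"].shifts)) == {"CORT", "IL1b", "IL6", "TNFa"}
        # BAA strictly contains IST
        assert set(dict(specs["IST"].shifts)) < set(dict(specs["BAA"].shifts))


class TestTreatmentTrials:
    def test_start_must_be_a_fixed_point(self, net, signatures):
        ss0, _ = signatures
        not_fixed = SystemState((1,) + (0,) * (net.n - 1))
        with pytest.raises(ValidationError, match="fixed point"):
            run_treatment_trials(
                net, None, standard_treatments()["GRB"], not_fixed, ss0,
                TrialConfig(n_trials=2, n_batches=1),
            )

    def test_null_treatment_never_leaves_the_fixed_point(self, net, ss1_state, signatures):
        ss0, _ = signatures
        null = TreatmentSpec.from_mapping("null", {})
        outcome = run_treatment_trials(
            net, None, null, ss1_state, ss0, TrialConfig(n_trials=50, n_batches=2)
        )
        assert outcome.mean == 0.0
        assert outcome.n_nonconvergent == 0

    def test_outcome_is_reproducible(self, net, ss1_state, signatures):
        ss0, _ = signatures
        cfg = TrialConfig(n_trials=100, n_batches=2, base_seed=9)
        spec = standard_treatments()["BAA"]
        a = run_treatment_trials(net, None, spec, ss1_state, ss0, cfg)
        b = run_treatment_trials(net, None, spec, ss1_state, ss0, cfg)
        assert a.batch_fractions == b.batch_fractions

    def test_disjoint_seed_sets_concentrate(self, toy_mutual_activation):
        """Success fractions from disjoint seeds differ < 5pp at n = 1000."""
        goal = StateSignature.from_mapping("baseline", {"A": 0, "B": 0})
        spec = TreatmentSpec.from_mapping("kick", {"A": -1})
        start = SystemState((1, 1))
        out = []
        for base in (101, 202):
            outcome = run_treatment_trials(
                toy_mutual_activation, None, spec, start, goal,
                TrialConfig(n_trials=1000, n_batches=1, base_seed=base),
            )
            out.append(outcome.mean)
        assert 0.0 < out[0] < 1.0  # the toy race is genuinely stochastic
        assert abs(out[0] - out[1]) < 0.05

    def test_broader_suppression_does_no_worse(self, net, ss1_state, signatures):
        """BAA's shift set strictly contains IST's; its success rate must too."""
        ss0, _ = signatures
        cfg = TrialConfig(n_trials=400, n_batches=2, base_seed=3)
        specs = standard_treatments()
        baa = run_treatment_trials(net, None, specs["BAA"], ss1_state, ss0, cfg)
        ist = run_treatment_trials(net, None, specs["IST"], ss1_state, ss0, cfg)
        assert baa.mean >= ist.mean
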