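"""Firing semantics, filtering, cycle detection and enumeration properties."""

import dataclasses
import logging

import pytest
from hypothesis import given, settings, strategies as st

from pathdyn import (
    DisabledEdgeError,
    EngineConfig,
    Interaction,
    LatchRegister,
    NetworkModel,
    RandomNetworkParams,
    Speed,
    Terminal,
    augment_reverse_edges,
    build_fixture,
    classify_and_default,
    detect_cycle,
    enabled_edges,
    enumerate_trajectories,
    filter_speed_priority,
    fire_edge,
    generate_random_network,
    is_enabled,
    replay,
    states_update,
)


@pytest.fixture(scope="module")
def gated_conversion():
    """A -> B with activator C, plus its auto-added reverse."""
    model, _, _ = build_fixture("conversion_basic")
    return model


class TestEnablement:
    def test_forward_enabled_when_input_and_activator_present(self, gated_conversion):
        assert is_enabled(gated_conversion.edges[0], (1, 0, 1))

    def test_reverse_enabled_only_without_activator(self, gated_conversion):
        fwd, rev = gated_conversion.edges
        assert is_enabled(rev, (0, 1, 0))
        assert not is_enabled(fwd, (0, 1, 0))
        assert not is_enabled(rev, (0, 1, 1))  # activator present blocks reverse

    def test_inhibitor_blocks_conversion(self):
        e = Interaction(0, inputs=(0,), outputs=(1,), inhibitors=(2,))
        model = classify_and_default(NetworkModel(["A", "B", "I"], [e]))
        assert not is_enabled(model.edges[0], (1, 0, 1))
        assert is_enabled(model.edges[0], (1, 0, 0))

    def test_duplicated_input_needs_matching_token_count(self):
        e = Interaction(0, inputs=(0, 0), outputs=(1,))
        model = classify_and_default(NetworkModel(["A", "AA"], [e]))
        assert not is_enabled(model.edges[0], (1, 0))
        assert is_enabled(model.edges[0], (2, 0))

    def test_transcription_requires_active_driver_and_stale_latch(self):
        model, _, _ = build_fixture("transcription_basic")
        e = model.edges[0]
        latch = LatchRegister()
        assert is_enabled(e, (1, 0), latch)
        assert not is_enabled(e, (0, 0), latch)  # driver absent
        _, latched = fire_edge(e, (1, 0), latch)
        assert not is_enabled(e, (1, 1), latched)  # already written
        assert is_enabled(e, (2, 1), latched)  # driver level changed


class TestFiring:
    def test_conversion_update(self, gated_conversion):
        x, _ = fire_edge(gated_conversion.edges[0], (1, 0, 1))
        assert x == (0, 1, 1)

    def test_reverse_update(self, gated_conversion):
        x, _ = fire_edge(gated_conversion.edges[1], (0, 1, 0))
        assert x == (1, 0, 0)

    def test_transcription_sets_output_and_latch(self):
        model, _, _ = build_fixture("transcription_basic")
        x, latch = fire_edge(model.edges[0], (1, 0), LatchRegister())
        assert x == (1, 1)
        assert latch[0] == (1,)

    def test_sequestration_step(self):
        model, x0, _ = build_fixture("bak1_mcl1")
        x, _ = fire_edge(model.edges[2], x0)
        assert x == (1, 0, 0, 0, 1)

    def test_input_state_not_mutated(self, gated_conversion):
        x0 = (1, 0, 1)
        fire_edge(gated_conversion.edges[0], x0)
        assert x0 == (1, 0, 1)

    def test_firing_disabled_edge_raises(self, gated_conversion):
        with pytest.raises(DisabledEdgeError):
            fire_edge(gated_conversion.edges[0], (0, 0, 1))


class TestEnabledSet:
    def test_illustrative_initial_state(self):
        model, x0, _ = build_fixture("illustrative")
        assert enabled_edges(model, x0, LatchRegister()) == [0, 1, 2]

    def test_illustrative_after_complex_assembly(self):
        model, _, _ = build_fixture("illustrative")
        x1 = (1, 1, 0, 0, 0, 1, 1, 0, 0, 1, 0, 0)  # after the n4+n5 binding
        assert enabled_edges(model, x1, LatchRegister()) == [0, 4]

    def test_all_zero_state(self):
        model, _, _ = build_fixture("illustrative")
        assert enabled_edges(model, (0,) * 12, LatchRegister()) == []


class TestFiltering:
    def test_slow_removed_when_fast_coenabled(self):
        model, _, _ = build_fixture("illustrative")
        assert filter_speed_priority([0, 1, 2], model) == [0, 2]

    def test_absent_outranker_does_not_prune(self):
        model, _, _ = build_fixture("illustrative")
        assert filter_speed_priority([0, 4], model) == [0, 4]

    def test_outranked_edge_removed(self):
        model, _, _ = build_fixture("illustrative")
        assert filter_speed_priority([3, 4], model) == [3]

    def test_lone_slow_edge_survives(self):
        model, _, _ = build_fixture("illustrative")
        assert filter_speed_priority([1], model) == [1]


class TestStatesUpdate:
    def test_branching_from_initial_state(self):
        model, x0, _ = build_fixture("illustrative")
        upd = states_update(x0, (), LatchRegister(), model)
        assert not upd.dead_end
        assert [s[1] for s in upd.successors] == [(0,), (2,)]

    def test_priority_yields_single_successor(self):
        model, x0, _ = build_fixture("bak1_mcl1")
        upd = states_update(x0, (), LatchRegister(), model)
        assert upd.enabled == (0, 2)
        assert upd.filtered == (2,)
        assert len(upd.successors) == 1

    def test_dead_end(self):
        model, _, _ = build_fixture("bak1_mcl1")
        upd = states_update((0, 0, 0, 0, 0), (2,), LatchRegister(), model)
        assert upd.dead_end
        assert upd.successors == ()


class TestCycles:
    def test_state_recurrence_detected(self):
        assert detect_cycle([(1, 0), (0, 1)], (1, 0))
        assert not detect_cycle([(1, 0)], (0, 1))

    def test_two_edge_loop(self):
        model = classify_and_default(NetworkModel(
            ["A", "B"],
            [Interaction(0, inputs=(0,), outputs=(1,)),
             Interaction(1, inputs=(1,), outputs=(0,))],
        ))
        ts = enumerate_trajectories(model, (1, 0))
        assert len(ts) == 1
        traj = ts[0]
        assert traj.edge_sequence == (0, 1)
        assert traj.terminal is Terminal.CYCLE
        assert traj.cycle_start == 0
        assert traj.states[-1] == traj.states[0]

    def test_feedback_loop_relaxes_to_initial_state(self):
        model, x0, _ = build_fixture("map_kinase")
        (traj,) = enumerate_trajectories(model, x0)
        assert traj.terminal is Terminal.CYCLE
        assert traj.states[-1] == x0


class TestReplay:
    def test_replay_reproduces_published_states(self):
        model, x0, exp = build_fixture("bak1_mcl1")
        history = replay(model, x0, (2, 0, 1))
        assert history == [tuple(s) for s in exp["states"][(2, 0, 1)]]
        assert history[-1] == (0, 0, 0, 1, 1)

    def test_empty_sequence_rejected(self):
        model, x0, _ = build_fixture("bak1_mcl1")
        with pytest.raises(ValueError, match="empty"):
            replay(model, x0, ())

    def test_disabled_step_named_in_error(self):
        model, x0, _ = build_fixture("bak1_mcl1")
        with pytest.raises(DisabledEdgeError, match="step 2"):
            replay(model, x0, (2, 2))


class TestEnumeration:
    def test_sync_mode_reserved(self):
        model, x0, _ = build_fixture("bak1_mcl1")
        with pytest.raises(NotImplementedError):
            enumerate_trajectories(model, x0, EngineConfig(mode="sync"))

    def test_wrong_state_length_rejected(self):
        model, _, _ = build_fixture("bak1_mcl1")
        with pytest.raises(ValueError, match="entries"):
            enumerate_trajectories(model, (1, 0))

    def test_step_limit_flags_unbounded_accumulation(self, caplog):
        # autocatalytic A -> A + B grows without bound; no state ever repeats
        model = classify_and_default(NetworkModel(
            ["A", "B"], [Interaction(0, inputs=(0,), outputs=(0, 1))]
        ))
        with caplog.at_level(logging.WARNING, logger="pathdyn.engine"):
            ts = enumerate_trajectories(model, (1, 0), EngineConfig(max_steps=5))
        (traj,) = ts
        assert traj.terminal is Terminal.STEP_LIMIT
        assert len(traj.edge_sequence) == 5
        assert any("step limit" in rec.message for rec in caplog.records)

    def test_speed_label_only_prunes(self):
        """Adding a slow label never enlarges the trajectory set."""
        model, x0, exp = build_fixture("speed_example")
        base = {t.edge_sequence for t in enumerate_trajectories(model, x0)}
        slow_edges = [
            dataclasses.replace(e, speed=Speed.SLOW) if e.index == exp["slow_edge"] else e
            for e in model.edges
        ]
        slow_model = NetworkModel(model.nodes, slow_edges, model.observables)
        pruned = {t.edge_sequence for t in enumerate_trajectories(slow_model, x0)}
        assert pruned <= base
        assert pruned == set(exp["sequences_slow"])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_enumeration_invariants_on_random_networks(self, seed):
        """Soundness, non-negativity, conservation and determinism."""
        model, x0 = generate_random_network(RandomNetworkParams(seed=seed))
        cfg = EngineConfig(max_steps=25)
        ts = enumerate_trajectories(model, x0, cfg)
        assert ts == enumerate_trajectories(model, x0, cfg)  # deterministic
        for traj in ts:
            assert len(traj.states) == len(traj.edge_sequence) + 1
            assert all(v >= 0 for x in traj.states for v in x)
            # replay soundness: every recorded firing was enabled
            assert replay(model, x0, traj.edge_sequence) == list(traj.states)
            for k, idx in enumerate(traj.edge_sequence):
                e = model.edges[idx]
                pre, post = traj.states[k], traj.states[k + 1]
                if e.kind.value == "conversion":
                    assert sum(post) - sum(pre) == len(e.outputs) - len(e.inputs)
                if e.is_reverse:
                    fwd = model.edges[e.reverse_of]
                    assert all(pre[a] == 0 for a in fwd.activators)
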