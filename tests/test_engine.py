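"""Engine behaviour: clamping, convergence, cycles, seeding, invariants."""

import math

import numpy as np
import pytest

from fcmsim import (
    ClampEntry,
    ClampSchedule,
    Concept,
    ConceptNetwork,
    EngineConfig,
    Influence,
    parse_network,
    resolve_indeterminates,
    run_replicates,
    simulate,
    update_state,
)
from fcmsim.errors import EnginePreconditionError, FcmError, UnknownConceptError


def chain(*weights):
    """A -> B -> C ... with the given weights."""
    ids = [chr(ord("A") + i) for i in range(len(weights) + 1)]
    net = ConceptNetwork([Concept(i) for i in ids])
    for (s, t), w in zip(zip(ids, ids[1:]), weights):
        net.add_influence(Influence(s, t, w))
    return net


class TestResolveIndeterminates:
    def test_r_zero_drops_edges(self):
        net = parse_network("A B I\nA C 0.5\n")
        out = resolve_indeterminates(net, seed=1, r=0.0)
        assert out.n_influences == 1
        assert not out.has_indeterminate()

    def test_determinism(self):
        net = parse_network("A B I\nB C I\nA C 0.5\n")
        a = resolve_indeterminates(net, seed=42, r=0.25)
        b = resolve_indeterminates(net, seed=42, r=0.25)
        assert a == b
        c = resolve_indeterminates(net, seed=43, r=0.25)
        assert a != c

    def test_uniform_distribution(self):
        # 1,000 resolved weights: bounded by r, mean near 0
        lines = "\n".join(f"A B{i:04d} I" for i in range(1000))
        net = parse_network(lines)
        out = resolve_indeterminates(net, seed=7, r=0.25)
        ws = np.array([e.weight for e in out.influences])
        assert np.all(np.abs(ws) <= 0.25)
        se = 0.25 / math.sqrt(3) / math.sqrt(len(ws))  # sd of U[-r,r]/sqrt(n)
        assert abs(ws.mean()) < 3 * se

    def test_determinate_weights_untouched(self):
        net = parse_network("A B I\nA C 0.5\n")
        out = resolve_indeterminates(net, seed=1, r=0.25)
        (e,) = [e for e in out.influences if e.target == "C"]
        assert e.weight == 0.5


class TestUpdateState:
    def test_no_input_unlocked_goes_to_baseline(self):
        net = chain(0.5)
        state = np.array([0.7, 0.0])
        new = update_state(state, net)
        assert new[0] == 0.0  # A has no inputs, lambda = 0

    def test_closed_form_tanh(self):
        net = chain(1.0)
        clamps = ClampSchedule({"A": ClampEntry(1.0)})
        new = update_state(np.array([1.0, 0.0]), net, clamps)
        assert new[1] == pytest.approx(math.tanh(1.0))
        assert new[1] == pytest.approx(0.7616, abs=5e-5)

    def test_locked_value_dominates_inputs(self):
        net = chain(1.0)
        clamps = ClampSchedule({"A": ClampEntry(1.0), "B": ClampEntry(-1.0)})
        new = update_state(np.array([1.0, -1.0]), net, clamps)
        assert new[1] == -1.0

    def test_unresolved_indeterminate_rejected(self):
        net = parse_network("A B I\n")
        with pytest.raises(EnginePreconditionError):
            update_state(np.zeros(2), net)

    def test_memory_term(self):
        net = ConceptNetwork([Concept("A"), Concept("B")],
                             [Influence("B", "A", 0.5)])
        cfg = EngineConfig(memory=0.5)
        new = update_state(np.array([0.4, 0.2]), net, config=cfg)
        assert new[0] == pytest.approx(math.tanh(0.5 * 0.4 + 0.5 * 0.2))


class TestSimulate:
    def test_zero_state_is_fixed_point(self):
        net = chain(0.5, -0.5)
        traj = simulate(net)
        assert traj.outcome == "fixed_point"
        assert traj.iterations_to_convergence == 1
        assert np.all(traj.final_state == 0.0)

    def test_driven_chain_fixed_point(self):
        net = chain(0.8)
        clamps = ClampSchedule({"A": ClampEntry(1.0)})
        traj = simulate(net, clamps)
        assert traj.outcome == "fixed_point"
        assert traj.iterations_to_convergence <= 3
        assert traj.value("B") == pytest.approx(math.tanh(0.8), abs=1e-4)

    def test_limit_cycle_detected(self):
        # two sources each inhibiting two sinks and vice versa: the summed
        # gain exceeds the squash slope, so the flip-flop persists
        lines = ("A C -1\nA D -1\nB C -1\nB D -1\n"
                 "C A -1\nC B -1\nD A -1\nD B -1\n")
        net = parse_network(lines)
        clamps = ClampSchedule({
            "A": ClampEntry(0.9, locked=False),
            "B": ClampEntry(0.9, locked=False),
        })
        traj = simulate(net, clamps)
        assert traj.outcome == "limit_cycle"
        assert traj.cycle_length == 2
        # final state is the element-wise mean over the cycle
        assert np.all(np.abs(traj.final_state) < 0.5)

    def test_unlocked_clamp_sets_initial_state_only(self):
        net = chain(0.8)
        clamps = ClampSchedule({"A": ClampEntry(1.0, locked=False)})
        traj = simulate(net, clamps)
        assert traj.states[0][0] == 1.0
        assert traj.value("A") == 0.0  # decays: no inputs, not locked

    def test_unknown_clamp_concept_rejected(self):
        net = chain(0.8)
        with pytest.raises(UnknownConceptError):
            simulate(net, ClampSchedule({"Z": ClampEntry(1.0)}))

    def test_locked_concepts_constant_in_every_stored_state(self):
        net = chain(0.8, -0.5)
        clamps = ClampSchedule({"A": ClampEntry(-0.3)})
        traj = simulate(net, clamps)
        assert np.all(traj.states[:, 0] == -0.3)

    def test_determinism_bit_identical(self):
        net = parse_network("A B I\nB C 0.9\nA C -0.4\n")
        clamps = ClampSchedule({"A": ClampEntry(1.0)})
        cfg = EngineConfig(seed=11, initial_jitter=0.05)
        t1 = simulate(net, clamps, cfg)
        t2 = simulate(net, clamps, cfg)
        assert np.array_equal(t1.states, t2.states)
        t3 = simulate(net, clamps, EngineConfig(seed=12, initial_jitter=0.05))
        assert not np.array_equal(t1.states, t3.states)

    def test_monotone_propagation_positive_chain(self):
        net = chain(0.9, 0.8, 0.7, 0.6)
        clamps = ClampSchedule({"A": ClampEntry(1.0)})
        traj = simulate(net, clamps)
        assert np.all(traj.final_state >= 0.0)


class TestBoundsAndContraction:
    def test_states_bounded_random_networks(self):
        """All states in [-1,1] and locked concepts invariant, any network."""
        from fcmsim.synthetic import GeneratorSpec, random_network

        rng = np.random.default_rng(0)
        for trial in range(100):
            net = random_network(GeneratorSpec(
                n_concepts=12, mean_degree=3.0, pos_fraction=0.658,
                ind_fraction=0.1, seed=trial,
            ))
            ids = net.concept_ids
            clamps = ClampSchedule()
            for cid in rng.choice(ids, size=3, replace=False):
                clamps.set(cid, float(rng.uniform(-1, 1)),
                           locked=bool(rng.random() < 0.7))
            cfg = EngineConfig(seed=trial, max_iterations=60,
                               initial_jitter=0.1)
            traj = simulate(net, clamps, cfg)
            assert np.all(traj.states >= -1.0) and np.all(traj.states <= 1.0)
            for cid, entry in clamps.entries.items():
                if entry.locked:
                    col = traj.states[:, ids.index(cid)]
                    assert np.all(col == entry.value)

    def test_contraction_always_reaches_fixed_point(self):
        """Max |column sum| * max squash slope < 1 forces a fixed point."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 8
            w = rng.uniform(-1, 1, (n, n)) * (rng.random((n, n)) < 0.4)
            np.fill_diagonal(w, 0.0)
            colsum = np.abs(w).sum(axis=0)
            scale = 0.9 / max(1.0, colsum.max())
            w *= scale
            net = ConceptNetwork([Concept(f"N{i}") for i in range(n)])
            for i in range(n):
                for j in range(n):
                    if w[i, j] != 0.0:
                        net.add_influence(Influence(f"N{i}", f"N{j}", w[i, j]))
            clamps = ClampSchedule({"N0": ClampEntry(1.0)})
            traj = simulate(net, clamps, EngineConfig(seed=seed))
            assert traj.outcome == "fixed_point"


class TestReplicates:
    def test_default_triplicate(self):
        net = chain(0.8)
        reps = run_replicates(net, ClampSchedule({"A": ClampEntry(1.0)}))
        assert reps.k == 3

    def test_deterministic_map_gives_zero_dispersion(self):
        net = chain(0.8)
        cfg = EngineConfig(initial_jitter=0.0)
        reps = run_replicates(net, ClampSchedule({"A": ClampEntry(1.0)}), cfg)
        assert np.all(reps.dispersion_final() == 0.0)
        assert np.array_equal(reps.final_states[0], reps.final_states[2])

    def test_same_master_seed_reproduces(self):
        net = parse_network("A B I\nB C 0.9\n")
        clamps = ClampSchedule({"A": ClampEntry(1.0)})
        a = run_replicates(net, clamps, EngineConfig(), k=3, seed=5)
        b = run_replicates(net, clamps, EngineConfig(), k=3, seed=5)
        assert np.array_equal(a.final_states, b.final_states)
        c = run_replicates(net, clamps, EngineConfig(), k=3, seed=6)
        assert not np.array_equal(a.final_states, c.final_states)

    def test_indeterminates_drive_variability(self):
        net = parse_network("A B I\nB C 0.9\n")
        clamps = ClampSchedule({"A": ClampEntry(1.0)})
        reps = run_replicates(net, clamps, EngineConfig(), k=3, seed=5)
        assert reps.dispersion_final()[1] > 0.0

    def test_k_must_be_positive(self):
        with pytest.raises(FcmError):
            run_replicates(chain(0.5), k=0)


def test_engine_config_serialization_round_trip():
    cfg = EngineConfig(memory=0.3, tolerance=1e-5, seed=9)
    assert EngineConfig.from_dict(cfg.to_dict()) == cfg
    # defaults survive serialization
    assert EngineConfig.from_dict(EngineConfig().to_dict()) == EngineConfig()
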