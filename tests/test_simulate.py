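"""The synthetic-data generator: Q-matrix structure, latent states and the
slip/guess response model."""

from __future__ import annotations

import numpy as np
import pytest

from npcda import (
    STUDY_ATTRIBUTE_COUNTS,
    SimulationSpec,
    conjunctive_table,
    npc_classify,
    simulate_dataset,
    simulate_knowledge_states,
    simulate_qmatrix,
    simulate_responses,
    study_spec,
    validate_qmatrix,
    wgnpc_classify,
)


class TestQmatrixGeneration:
    def test_forced_identity_when_items_equal_attributes(self):
        spec = SimulationSpec(n_examinees=1, n_items=3, n_attributes=3, seed=0)
        q = simulate_qmatrix(spec)
        assert np.array_equal(q.entries, np.eye(3, dtype=int))

    def test_generated_matrices_are_always_valid(self):
        for seed in range(8):
            spec = SimulationSpec(
                n_examinees=5, n_items=30, n_attributes=6,
                attribute_skew=1.0, seed=seed,
            )
            q = simulate_qmatrix(spec)
            assert validate_qmatrix(q).ok
            assert q.entries.sum(axis=1).max() <= spec.max_attrs_per_item

    def test_study_shape_column_sums_track_published_targets(self):
        q = simulate_qmatrix(study_spec(seed=3))
        targets = np.array(list(STUDY_ATTRIBUTE_COUNTS.values()))
        sums = q.entries.sum(axis=0)
        assert q.entries.shape == (2809, 22)
        assert (np.abs(sums - targets) <= np.maximum(1, 0.05 * targets)).all()
        assert q.entries.sum(axis=1).max() <= 3
        assert validate_qmatrix(q).ok

    def test_infeasible_targets_error(self):
        with pytest.raises(ValueError, match="sum below"):
            SimulationSpec(
                n_examinees=1, n_items=10, n_attributes=2,
                attribute_targets=(4, 4),
            )

    def test_reproducible_given_seed(self):
        spec = SimulationSpec(n_examinees=2, n_items=25, n_attributes=5, seed=11)
        assert np.array_equal(
            simulate_qmatrix(spec).entries, simulate_qmatrix(spec).entries
        )


class TestKnowledgeStates:
    def test_prob_one_gives_full_mastery(self):
        spec = SimulationSpec(n_examinees=6, n_items=4, n_attributes=4,
                              mastery_prob=1.0, seed=0)
        assert simulate_knowledge_states(spec).min() == 1

    def test_half_prob_prevalence_within_monte_carlo_error(self):
        spec = SimulationSpec(n_examinees=4000, n_items=4, n_attributes=4,
                              mastery_prob=0.5, seed=1)
        prev = simulate_knowledge_states(spec).mean(axis=0)
        assert np.abs(prev - 0.5).max() < 0.05

    def test_explicit_states_echoed(self):
        states = ((1, 0), (0, 1), (1, 1))
        spec = SimulationSpec(n_examinees=3, n_items=2, n_attributes=2,
                              explicit_states=states)
        assert simulate_knowledge_states(spec).tolist() == [list(s) for s in states]


class TestResponseModel:
    def test_zero_noise_reproduces_conjunctive_ideals(self):
        spec = SimulationSpec(n_examinees=7, n_items=15, n_attributes=4, seed=2)
        q = simulate_qmatrix(spec)
        states = simulate_knowledge_states(spec)
        y = simulate_responses(q, states, 0.0, 0.0, seed=3)
        assert np.array_equal(y.entries, conjunctive_table(states, q.entries))

    def test_half_noise_is_independent_of_states(self):
        spec = SimulationSpec(n_examinees=400, n_items=20, n_attributes=3, seed=4)
        q = simulate_qmatrix(spec)
        states = simulate_knowledge_states(spec)
        y = simulate_responses(q, states, 0.5, 0.5, seed=5)
        ideal = conjunctive_table(states, q.entries)
        assert abs(y.entries[ideal == 1].mean() - 0.5) < 0.02
        assert abs(y.entries[ideal == 0].mean() - 0.5) < 0.02

    def test_slip_rate_recovered_in_monte_carlo(self):
        spec = SimulationSpec(n_examinees=500, n_items=30, n_attributes=4,
                              mastery_prob=0.5, seed=6)
        q = simulate_qmatrix(spec)
        states = simulate_knowledge_states(spec)
        y = simulate_responses(q, states, 0.1, 0.1, seed=7)
        ideal = conjunctive_table(states, q.entries)
        n_ones = int((ideal == 1).sum())
        se = 3 * np.sqrt(0.9 * 0.1 / n_ones)
        assert abs(y.entries[ideal == 1].mean() - 0.9) < se + 0.01

    def test_dino_generator_follows_disjunctive_ideals(self):
        from npcda import disjunctive_table

        spec = SimulationSpec(n_examinees=5, n_items=12, n_attributes=3, seed=8,
                              generating_rule="disjunctive")
        q, y, states = simulate_dataset(spec)
        spec0 = SimulationSpec(n_examinees=5, n_items=12, n_attributes=3, seed=8,
                               generating_rule="disjunctive", slip=0.0, guess=0.0)
        q0, y0, states0 = simulate_dataset(spec0)
        assert np.array_equal(y0.entries, disjunctive_table(states0, q0.entries))


class TestEndToEndRecovery:
    def test_noiseless_npc_recovers_truth_exactly(self):
        spec = SimulationSpec(n_examinees=20, n_items=16, n_attributes=4,
                              slip=0.0, guess=0.0, seed=9)
        q, y, truth = simulate_dataset(spec)
        res = npc_classify(y, q)
        assert np.array_equal(res.states, truth)

    def test_recovery_degrades_monotonically_with_noise(self):
        agreements = []
        for noise in (0.0, 0.1, 0.2, 0.3):
            vals = []
            for seed in range(3):
                spec = SimulationSpec(
                    n_examinees=500, n_items=30, n_attributes=4,
                    slip=noise, guess=noise, mastery_prob=0.5, seed=100 + seed,
                )
                q, y, truth = simulate_dataset(spec)
                res = wgnpc_classify(y, q)
                vals.append((res.states == truth).mean())
            agreements.append(float(np.mean(vals)))
        # monotone within a small sampling-error slack
        for lo, hi in zip(agreements[1:], agreements[:-1]):
            assert lo <= hi + 0.02

    def test_spec_json_round_trip(self, tmp_path):
        spec = study_spec(seed=5)
        path = tmp_path / "spec.json"
        spec.to_json(path)
        assert SimulationSpec.from_json(path) == spec
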