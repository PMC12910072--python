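"""Distance primitives, weight estimation and the NPC/GNPC/WGNPC engines,
checked against independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from npcda import (
    ClassifierConfig,
    QMatrix,
    ResponseMatrix,
    conjunctive_table,
    disjunctive_table,
    estimate_weights,
    gnpc_classify,
    hamming_distance,
    item_pass_rates,
    npc_classify,
    residual_distance,
    states_array,
    state_space_for,
    weighted_distance,
    wgnpc_classify,
)
from npcda.classify import PASS_RATE_CLAMP, PassRates

import _oracles as oracle
from conftest import random_instance, random_qmatrix


class TestHamming:
    def test_identical_vectors_have_zero_distance(self):
        assert hamming_distance([1, 0, 1], [1, 0, 1]) == 0

    def test_direct_count(self):
        assert hamming_distance([1, 1, 0], [1, 0, 1]) == 2

    def test_equals_squared_distance_on_all_binary_pairs(self):
        for length in (1, 2, 3, 4):
            for y in itertools.product((0, 1), repeat=length):
                for e in itertools.product((0, 1), repeat=length):
                    ya, ea = np.array(y), np.array(e)
                    assert hamming_distance(ya, ea) == ((ya - ea) ** 2).sum()

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            hamming_distance([1, 0], [1, 0, 1])


class TestWeightedDistance:
    def test_uniform_half_rates_scale_squared_distance_by_four(self):
        rates = PassRates(np.full(3, 0.5))
        d = weighted_distance([1, 1, 0], [0, 1, 1], rates)
        assert d == pytest.approx(4 * 2)

    def test_zero_when_orp_equals_ideal(self):
        rates = PassRates(np.array([0.3, 0.6]))
        assert weighted_distance([1, 0], [1.0, 0.0], rates) == 0.0

    def test_clamped_item_contributes_ten_thousandfold(self):
        # an all-wrong item has p clamped to 0.0001; its weight is
        # 1 / (0.0001 * 0.9999)
        y = ResponseMatrix([[0], [0], [0]])
        rates = item_pass_rates(y)
        assert rates.p_bar[0] == pytest.approx(PASS_RATE_CLAMP)
        expected = 1.0 / (PASS_RATE_CLAMP * (1 - PASS_RATE_CLAMP))
        assert weighted_distance([1], [0.0], rates) == pytest.approx(expected)

    def test_all_correct_item_clamped_symmetrically(self):
        y = ResponseMatrix([[1], [1]])
        assert item_pass_rates(y).p_bar[0] == pytest.approx(1 - PASS_RATE_CLAMP)


class TestResidualAndWeights:
    def test_residual_of_empty_cluster_is_zero(self):
        y = ResponseMatrix([[1, 0]])
        eta_w = np.array([[0.5, 0.5], [1.0, 0.0]])
        d = residual_distance(y, eta_w, np.array([1]))
        assert d[0].tolist() == [0.0, 0.0]

    def test_residual_direct_arithmetic(self):
        # cluster responses {1,1,0} vs blended ideal 2/3:
        # 2*(1/3)^2 + (2/3)^2 = 2/3
        y = ResponseMatrix([[1], [1], [0]])
        d = residual_distance(y, np.array([[2 / 3]]), np.zeros(3, dtype=int))
        assert d[0, 0] == pytest.approx(2 / 3)

    def test_closed_form_weight_direct_substitution(self):
        # members {1,1,0}, eta_d=0, eta_c=1 -> omega = 2/3
        y = ResponseMatrix([[1], [1], [0]])
        w = estimate_weights(y, np.zeros(3, dtype=int),
                             np.array([[1]]), np.array([[0]]))
        assert w.omega[0, 0] == pytest.approx(2 / 3)

    def test_members_matching_conjunctive_ideal_give_weight_one(self):
        y = ResponseMatrix([[1], [1]])
        w = estimate_weights(y, np.zeros(2, dtype=int),
                             np.array([[1]]), np.array([[0]]))
        assert w.omega[0, 0] == 1.0

    def test_empty_cluster_and_degenerate_cells_default_to_one(self):
        y = ResponseMatrix([[1], [0]])
        # two states; everyone assigned to state 0; item has eta_c == eta_d
        w = estimate_weights(y, np.zeros(2, dtype=int),
                             np.array([[1], [1]]), np.array([[1], [1]]))
        assert w.omega.tolist() == [[1.0], [1.0]]

    def test_weights_clamped_into_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            q, y, _ = random_instance(rng)
            states = states_array(q.n_attributes)
            ec = conjunctive_table(states, q.entries)
            ed = disjunctive_table(states, q.entries)
            assign = rng.integers(0, len(states), size=y.n_examinees)
            w = estimate_weights(y, assign, ec, ed)
            assert (w.omega >= 0).all() and (w.omega <= 1).all()
            eta_w = w.omega * ec + (1 - w.omega) * ed
            assert (eta_w >= 0).all() and (eta_w <= 1).all()

    def test_closed_form_matches_grid_search_argmin(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            m = int(rng.integers(1, 9))
            members = rng.integers(0, 2, size=m)
            y = ResponseMatrix(members.reshape(-1, 1))
            w = estimate_weights(y, np.zeros(m, dtype=int),
                                 np.array([[0]]), np.array([[1]]))
            grid = oracle.grid_omega(members.tolist(), 0, 1)
            assert abs(w.omega[0, 0] - grid) <= 1e-3


class TestNpc:
    def test_orp_equal_to_unique_irp_gives_that_state(self):
        q = QMatrix([[1, 0], [0, 1], [1, 1]])
        y = ResponseMatrix([[1, 0, 0]])
        res = npc_classify(y, q)
        assert res.states.tolist() == [[1, 0]]
        assert res.distances.tolist() == [0.0]

    def test_worked_example_assignment(self):
        q = QMatrix([[1, 0], [1, 1]])
        y = ResponseMatrix([[1, 0]])
        res = npc_classify(y, q)
        assert res.states.tolist() == [[1, 0]]
        assert res.distances[0] == 0.0

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            q, y, _ = random_instance(rng)
            res = npc_classify(y, q)
            expected = oracle.brute_npc(y.entries.tolist(), q.entries.tolist())
            assert res.states.tolist() == expected

    def test_tie_break_prefers_fewest_mastered_attributes(self):
        # one item measuring one attribute, answered wrong: states [0,*]
        # all at distance 1 for the second attribute; parsimony picks 00
        q = QMatrix([[1, 0]])
        y = ResponseMatrix([[0]])
        res = npc_classify(y, q)
        assert res.states.tolist() == [[0, 0]]
        assert res.tie_log  # multiple states tied


class TestIterativeEngines:
    def test_noiseless_complete_design_recovers_truth_in_one_round(self):
        rng = np.random.default_rng(31)
        q, y, truth = random_instance(rng, n_attrs=4, n_items=12,
                                      n_examinees=12, slip=0.0, guess=0.0)
        for classify in (gnpc_classify, wgnpc_classify):
            res = classify(y, q)
            assert np.array_equal(res.states, truth)
            assert res.converged and res.iterations == 1

    def test_gnpc_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(41)
        for _ in range(25):
            q, y, _ = random_instance(rng)
            res = gnpc_classify(y, q)
            expected = oracle.brute_general(
                y.entries.tolist(), q.entries.tolist(), weighted=False
            )
            assert res.states.tolist() == expected

    def test_wgnpc_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(43)
        for _ in range(25):
            q, y, _ = random_instance(rng)
            res = wgnpc_classify(y, q)
            expected = oracle.brute_general(
                y.entries.tolist(), q.entries.tolist(), weighted=True
            )
            assert res.states.tolist() == expected

    def test_single_examinee_reduces_to_npc_assignment(self):
        rng = np.random.default_rng(47)
        for _ in range(20):
            q, y, _ = random_instance(rng, n_examinees=1)
            base = npc_classify(y, q)
            for classify in (gnpc_classify, wgnpc_classify):
                res = classify(y, q)
                assert res.states.tolist() == base.states.tolist()

    def test_wgnpc_equals_gnpc_under_uniform_pass_rates(self):
        # equal pass rates scale every distance by the same factor,
        # preserving the argmin
        q = QMatrix([[1, 0], [0, 1], [1, 1], [1, 1]])
        y = ResponseMatrix([[1, 0, 0, 1], [0, 1, 1, 0], [1, 1, 0, 1], [0, 0, 1, 0]])
        p = item_pass_rates(y).p_bar
        assert len(set(np.round(p, 12))) == 1
        a = gnpc_classify(y, q)
        b = wgnpc_classify(y, q)
        assert a.states.tolist() == b.states.tolist()

    def test_gnpc_total_residual_is_monotone_over_iterations(self):
        rng = np.random.default_rng(53)
        for _ in range(10):
            q, y, _ = random_instance(rng, slip=0.25, guess=0.25)
            states = states_array(q.n_attributes)
            ec = conjunctive_table(states, q.entries)
            ed = disjunctive_table(states, q.entries)
            # replay the scheme step by step via public pieces
            assign = np.array([
                oracle.all_states(q.n_attributes).index(s)
                for s in oracle.brute_npc(y.entries.tolist(), q.entries.tolist())
            ])
            prev = np.inf
            for _ in range(8):
                w = estimate_weights(y, assign, ec, ed)
                eta_w = w.omega * ec + (1 - w.omega) * ed
                total = residual_distance(y, eta_w, assign).sum()
                assert total <= prev + 1e-9
                prev = total
                d = ((y.entries[:, None, :] - eta_w[None, :, :]) ** 2).sum(axis=2)
                assign = d.argmin(axis=1)

    def test_component_mode_equals_exhaustive_for_npc(self):
        rng = np.random.default_rng(59)
        for _ in range(15):
            q, y, _ = random_instance(rng, n_attrs=6, n_items=14)
            ex = npc_classify(y, q, space=state_space_for(q, mode="exhaustive"))
            co = npc_classify(y, q, space=state_space_for(q, mode="component"))
            assert ex.states.tolist() == co.states.tolist()

    def test_component_mode_matches_exhaustive_on_noiseless_data(self):
        rng = np.random.default_rng(61)
        for classify in (gnpc_classify, wgnpc_classify):
            q, y, truth = random_instance(rng, n_attrs=6, n_items=16,
                                          n_examinees=10, slip=0.0, guess=0.0)
            ex = classify(y, q, space=state_space_for(q, mode="exhaustive"))
            co = classify(y, q, space=state_space_for(q, mode="component"))
            assert np.array_equal(ex.states, co.states)
            assert np.array_equal(ex.states, truth)

    def test_component_mode_close_to_exhaustive_under_noise(self):
        # the iterated methods pool weights per component, which is a
        # coarser clustering than the joint space, so exact equality is
        # not guaranteed; agreement should still be high
        rng = np.random.default_rng(67)
        agreements = []
        for _ in range(15):
            q, y, _ = random_instance(rng, n_attrs=6, n_items=16)
            ex = wgnpc_classify(y, q, space=state_space_for(q, mode="exhaustive"))
            co = wgnpc_classify(y, q, space=state_space_for(q, mode="component"))
            agreements.append((ex.states == co.states).mean())
        assert np.mean(agreements) >= 0.9

    def test_coordinate_descent_agrees_with_exhaustive_on_small_designs(self):
        # force the fallback by setting the cap below K
        rng = np.random.default_rng(71)
        hits = []
        for _ in range(10):
            q, y, _ = random_instance(rng, n_attrs=6, n_items=18, n_examinees=8)
            # keep a single component so the cap bites
            cfg_small = ClassifierConfig(state_cap=3, seed=1)
            ex = npc_classify(y, q, space=state_space_for(q, mode="exhaustive"))
            cd = npc_classify(y, q, config=cfg_small)
            hits.append((ex.states == cd.states).mean())
        assert np.mean(hits) >= 0.95

    def test_deterministic_given_inputs_and_seed(self):
        rng = np.random.default_rng(73)
        q, y, _ = random_instance(rng)
        cfg = ClassifierConfig(seed=9)
        a = wgnpc_classify(y, q, config=cfg)
        b = wgnpc_classify(y, q, config=cfg)
        assert a.states.tolist() == b.states.tolist()
        assert a.distances.tolist() == b.distances.tolist()

    def test_result_bookkeeping(self):
        q = QMatrix([[1, 0], [0, 1], [1, 1]])
        y = ResponseMatrix([[1, 0, 0], [1, 1, 1]], examinee_ids=("a", "b"))
        res = wgnpc_classify(y, q)
        assert set(res.memberships()) <= {"10", "01", "00", "11"}
        assert sum(len(v) for v in res.memberships().values()) == 2
        frame = res.to_frame()
        assert list(frame.columns) == [
            "examinee_id", "state", "distance", "method", "iterations"
        ]
        assert (res.distances >= 0).all()
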