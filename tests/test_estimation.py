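"""Penalized OptV likelihood, optimization, cross-validation, model tests."""

import math

import numpy as np
import pytest

from thermirl import (DataError, FitConfig, GridSpec, PassiveKernel,
                      TransitionData, build_grid, compare_models,
                      cross_validate, estimate_value, gaussian_passive_kernel,
                      optimal_policy, penalized_objective,
                      smoothness_penalty, transition_loglik)
from thermirl.simulate import GroundTruthSpec, SimConfig, generate_training_set
from conftest import random_stochastic_matrix, random_transitions


class TestTransitionData:
    def test_counts_total_matches_pairs(self, rng):
        data = random_transitions(rng, 10, 250)
        assert data.counts().sum() == 250

    def test_contiguous_folds_partition_in_order(self, rng):
        data = random_transitions(rng, 10, 95)
        folds = data.folds(9)
        test_sizes = [len(test) for _, test in folds]
        assert sum(test_sizes) == 95 and max(test_sizes) - min(test_sizes) <= 1
        # fold test blocks are contiguous slices of the original sequence
        start = 0
        for _, test in folds:
            assert np.array_equal(test.pairs, data.pairs[start:start + len(test)])
            start += len(test)

    def test_too_few_transitions_for_folds(self, rng):
        with pytest.raises(DataError):
            random_transitions(rng, 10, 5).folds(9)

    def test_csv_round_trip(self, rng, tmp_path):
        data = random_transitions(rng, 12, 40)
        path = tmp_path / "t.csv"
        data.to_csv(path)
        back = TransitionData.from_csv(path, 12)
        assert np.array_equal(back.pairs, data.pairs)


class TestTransitionLoglik:
    def test_uniform_policy_value(self):
        n, m = 6, 50
        K = PassiveKernel(np.full((n, n), 1 / n))
        rng = np.random.default_rng(0)
        data = random_transitions(rng, n, m)
        ll = transition_loglik(np.zeros(n), K, data)
        assert ll == pytest.approx(-m * np.log(n))

    def test_two_state_single_transition(self):
        K = PassiveKernel(np.full((2, 2), 0.5))
        data = TransitionData([[0, 1]], ["w"], 2)
        ll = transition_loglik(np.array([0.0, np.log(2.0)]), K, data)
        assert ll == pytest.approx(np.log(2 / 3))

    def test_matches_per_pair_brute_force(self, rng):
        # oracle: sum log pi*(to|from) pair by pair via explicit normalization
        for _ in range(5):
            n = 7
            K = PassiveKernel(random_stochastic_matrix(rng, n))
            v = rng.normal(size=n)
            data = random_transitions(rng, n, 60)
            brute = 0.0
            for s, s2 in data.pairs:
                w = K.matrix[s] * np.exp(v)
                brute += math.log(w[s2] / w.sum())
            assert transition_loglik(v, K, data) == pytest.approx(
                brute, abs=1e-10)

    def test_empty_data_rejected(self, tiny_kernel):
        empty = TransitionData(np.empty((0, 2)), np.empty(0),
                               tiny_kernel.n_states)
        with pytest.raises(DataError):
            transition_loglik(np.zeros(tiny_kernel.n_states), tiny_kernel,
                              empty)


class TestSmoothnessPenalty:
    def test_constant_value_costs_nothing(self, tiny_grid):
        assert smoothness_penalty(np.full(tiny_grid.n_states, 2.0),
                                  tiny_grid) == 0.0

    def test_two_state_pair_counted_twice(self):
        grid = build_grid(GridSpec(0.0, 1.0, 2, 0.0, 0.0, 1))
        assert smoothness_penalty(np.array([0.0, 1.0]), grid) == pytest.approx(2.0)

    def test_shift_invariance(self, tiny_grid, rng):
        v = rng.normal(size=tiny_grid.n_states)
        assert smoothness_penalty(v, tiny_grid) == pytest.approx(
            smoothness_penalty(v + 3.3, tiny_grid))

    def test_matches_neighbor_enumeration(self, tiny_grid, rng):
        from thermirl import neighbors
        v = rng.normal(size=tiny_grid.n_states)
        brute = sum((v[k] - v[m]) ** 2
                    for k in range(tiny_grid.n_states)
                    for m in neighbors(k, tiny_grid))
        assert smoothness_penalty(v, tiny_grid) == pytest.approx(brute)


class TestObjective:
    def test_analytic_gradient_matches_central_differences(self, tiny_grid,
                                                           tiny_kernel, rng):
        data = random_transitions(rng, tiny_grid.n_states, 400)
        cfg = FitConfig(lam=0.7)
        v = rng.normal(size=tiny_grid.n_states)
        _, grad = penalized_objective(v, data, tiny_kernel, tiny_grid, cfg)
        eps = 1e-5
        for i in range(tiny_grid.n_states):
            e = np.zeros_like(v)
            e[i] = eps
            fp, _ = penalized_objective(v + e, data, tiny_kernel, tiny_grid, cfg)
            fm, _ = penalized_objective(v - e, data, tiny_kernel, tiny_grid, cfg)
            fd = (fp - fm) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_concave_along_random_segments(self, tiny_grid, tiny_kernel, rng):
        data = random_transitions(rng, tiny_grid.n_states, 300)
        cfg = FitConfig(lam=0.3)

        def f(v):
            return penalized_objective(v, data, tiny_kernel, tiny_grid, cfg)[0]

        for _ in range(10):
            v1 = rng.normal(size=tiny_grid.n_states)
            v2 = rng.normal(size=tiny_grid.n_states)
            for a in (0.25, 0.5, 0.75):
                mid = f(a * v1 + (1 - a) * v2)
                assert mid >= a * f(v1) + (1 - a) * f(v2) - 1e-9


class TestEstimateValue:
    def test_recovers_truth_from_exhaustive_sampling(self, tiny_grid,
                                                     tiny_kernel, rng):
        # sample transitions directly from the optimal policy of a known v
        v_true = rng.normal(size=tiny_grid.n_states)
        pi = optimal_policy(tiny_kernel, v_true).matrix
        n = tiny_grid.n_states
        per_state = 4000
        pairs = []
        for s in range(n):
            to = rng.choice(n, size=per_state, p=pi[s])
            pairs.append(np.column_stack([np.full(per_state, s), to]))
        pairs = np.concatenate(pairs)
        data = TransitionData(pairs, np.zeros(len(pairs)), n)
        v_hat = estimate_value(data, tiny_kernel, tiny_grid,
                               FitConfig(lam=1e-6))
        r = np.corrcoef(v_hat.values, v_true)[0, 1]
        assert r >= 0.95

    def test_huge_lambda_flattens_the_value(self, tiny_grid, tiny_kernel, rng):
        data = random_transitions(rng, tiny_grid.n_states, 500)
        v = estimate_value(data, tiny_kernel, tiny_grid, FitConfig(lam=1e6))
        assert v.values.max() - v.values.min() < 1e-3

    def test_estimate_is_optimal_on_training_data(self, tiny_grid,
                                                  tiny_kernel, rng):
        v_true = rng.normal(size=tiny_grid.n_states)
        data = random_transitions(rng, tiny_grid.n_states, 500)
        cfg = FitConfig(lam=0.1)
        v_hat = estimate_value(data, tiny_kernel, tiny_grid, cfg)
        obj_hat, _ = penalized_objective(v_hat, data, tiny_kernel, tiny_grid, cfg)
        obj_true, _ = penalized_objective(v_true, data, tiny_kernel, tiny_grid, cfg)
        assert obj_hat >= obj_true - 1e-6

    def test_unvisited_states_flagged(self, tiny_grid, tiny_kernel):
        pairs = [[0, 1], [1, 0], [0, 0]]
        data = TransitionData(pairs, ["w"] * 3, tiny_grid.n_states)
        v = estimate_value(data, tiny_kernel, tiny_grid, FitConfig(lam=0.5))
        unvisited = v.info["unvisited_states"]
        assert 0 not in unvisited and 1 not in unvisited
        assert len(unvisited) == tiny_grid.n_states - 2

    def test_relabeling_equivariance(self, tiny_grid, tiny_kernel, rng):
        # permuting state labels permutes the estimate identically;
        # the permuted problem uses an unstructured (complete-graph-free)
        # penalty, so compare at lambda = 0
        data = random_transitions(rng, tiny_grid.n_states, 800)
        cfg = FitConfig(lam=0.0)
        v = estimate_value(data, tiny_kernel, tiny_grid, cfg).values
        perm = rng.permutation(tiny_grid.n_states)
        inv = np.argsort(perm)
        K_p = PassiveKernel(tiny_kernel.matrix[np.ix_(perm, perm)])
        pairs_p = inv[data.pairs]
        data_p = TransitionData(pairs_p, data.worm_ids, tiny_grid.n_states)
        # the grid's neighbor structure is label-dependent, so equivariance
        # is exact only for the likelihood part
        v_p = estimate_value(data_p, K_p, tiny_grid, cfg).values
        assert np.abs(v_p - v[perm]).max() < 1e-4


class TestCrossValidate:
    def test_single_candidate_returns_its_fold_scores(self, tiny_grid, rng):
        data = random_transitions(rng, tiny_grid.n_states, 300)
        cv = cross_validate(data, tiny_grid, [0.5], [0.5], [0.004], n_folds=5)
        assert cv.selected == {"lam": 0.5, "sigma_T": 0.5, "sigma_dT": 0.004}
        assert len(cv.fold_scores()) == 5

    def test_recovers_generating_sigmas(self):
        # CV picks the sigma grid point nearest the generating noise in a
        # majority of replicate runs
        grid = build_grid(GridSpec(18.0, 22.0, 8, -0.01, 0.01, 5))
        spec = GroundTruthSpec("pd_diagonal", dm_slope=0.005, dm_width=0.003,
                               im_width=0.002)
        true_sT, true_sD = 0.3, 0.003
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = SimConfig(n_worms=10, n_steps=101,
                            start_T=tuple(np.linspace(18.3, 21.7, 10)),
                            seed=1000 + rep)
            ts = generate_training_set(spec, grid, true_sT, true_sD, cfg,
                                       test_fraction=0.0)
            cv = cross_validate(ts.train, grid, [0.1],
                                [0.15, 0.3, 0.6], [0.0015, 0.003, 0.006],
                                n_folds=9)
            if (cv.selected["sigma_T"] == true_sT
                    and cv.selected["sigma_dT"] == true_sD):
                hits += 1
        assert hits > n_rep / 2


class TestCompareModels:
    def test_identical_scores_are_indistinguishable(self):
        s = [1.0, 2.0, 3.0, 4.0]
        res = compare_models(s, s)
        assert res.p_value == 1.0 and res.direction == "none"

    def test_disjoint_ranges_give_exact_tail_probability(self):
        a = list(range(10, 19))      # 9 folds, all above b
        b = list(range(9))
        res = compare_models(a, b)
        # exact two-sided Mann-Whitney tail for complete separation, n=m=9
        assert res.p_value == pytest.approx(2 / math.comb(18, 9))
        assert res.direction == "a"

    def test_swapping_flips_direction_not_p(self):
        a = [5.0, 6.0, 7.5, 8.0, 9.0]
        b = [1.0, 2.0, 3.0, 4.0, 4.5]
        r1 = compare_models(a, b)
        r2 = compare_models(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.direction == "a" and r2.direction == "b"

    def test_too_few_folds_rejected(self):
        with pytest.raises(DataError):
            compare_models([1.0], [2.0])
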