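"""StARS instability machinery, StEPS and the cubic stability search."""

import numpy as np
import pytest

from mgmsteps import core
from mgmsteps.core import FitConfig, PenaltyWeights
from mgmsteps.selection import LambdaGrid
from mgmsteps.stability import (InstabilityProfile, cubic_stability_select,
                                default_subsample_size, draw_subsamples,
                                edge_frequency, edge_instability,
                                instability_profile, monotonize,
                                profile_from_ensemble, stars_select,
                                stars_select_lambda, steps_select,
                                subsample_adjacencies, SubsampleEnsemble)
from conftest import random_dataset


class TestSubsampling:
    def test_default_size_formula(self):
        assert default_subsample_size(500) == 223  # floor(10 * sqrt(500))
        assert default_subsample_size(100) == 100  # capped at n
        assert default_subsample_size(10000) == 1000

    def test_full_size_subsamples_are_whole_index_set(self):
        idx = draw_subsamples(100, N=3, b=100, seed=0)
        for row in idx:
            assert sorted(row) == list(range(100))

    def test_deterministic_given_seed(self):
        a = draw_subsamples(50, N=5, b=20, seed=42)
        b = draw_subsamples(50, N=5, b=20, seed=42)
        assert np.array_equal(a, b)
        c = draw_subsamples(50, N=5, b=20, seed=43)
        assert not np.array_equal(a, c)

    def test_indices_distinct_within_subsample(self):
        idx = draw_subsamples(30, N=4, b=25, seed=1)
        for row in idx:
            assert len(set(row)) == 25

    def test_oversized_b_rejected(self):
        with pytest.raises(ValueError):
            draw_subsamples(10, N=2, b=11)


class TestInstabilityFormulas:
    def test_edge_frequency_counts(self):
        adjs = np.zeros((20, 3, 3), dtype=bool)
        adjs[:, 0, 1] = adjs[:, 1, 0] = True       # always present
        adjs[:10, 0, 2] = adjs[:10, 2, 0] = True   # present in 10 of 20
        theta = edge_frequency(adjs)
        assert theta[0, 1] == 1.0
        assert theta[0, 2] == 0.5
        assert theta[1, 2] == 0.0

    @pytest.mark.parametrize("theta,expected", [
        (0.0, 0.0), (1.0, 0.0), (0.5, 0.5), (0.25, 0.375)])
    def test_instability_formula(self, theta, expected):
        assert edge_instability(np.array(theta)) == pytest.approx(expected)

    def test_total_instability_denominators(self):
        from mgmsteps.stability import total_instability
        p = q = 2
        xi = np.zeros((4, 4))
        xi[0, 2] = xi[2, 0] = 0.5  # one cd entry
        assert total_instability(xi, "cd", p, q) == pytest.approx(0.125)
        assert total_instability(xi, "all", p, q) == pytest.approx(0.5 / 6)
        assert total_instability(xi, "cc", p, q) == 0.0
        with pytest.raises(ValueError):
            total_instability(xi, "cc", 1, 3)

    def test_total_instability_matches_masked_mean(self, rng):
        from mgmsteps.core import edge_type_masks
        from mgmsteps.stability import total_instability
        p, q = 3, 4
        xi = rng.random((7, 7))
        xi = (xi + xi.T) / 2
        masks = edge_type_masks(p, q)
        for et in ("all", "cc", "cd", "dd"):
            assert total_instability(xi, et, p, q) == pytest.approx(
                xi[masks[et]].mean())


class TestMonotonize:
    def test_already_monotone_unchanged(self):
        d = np.array([0.01, 0.05, 0.2])
        assert np.array_equal(monotonize(d), d)

    def test_running_max_over_larger_penalties(self):
        # lambda = (.64, .32, .16): the dip at .16 is lifted to the sup
        d = np.array([0.01, 0.08, 0.04])
        assert np.allclose(monotonize(d), [0.01, 0.08, 0.08])

    def test_constant_unchanged(self):
        d = np.full(4, 0.03)
        assert np.array_equal(monotonize(d), d)


class TestStarsThreshold:
    def test_all_stable_selects_smallest_lambda(self):
        lam, idx, warned = stars_select_lambda((0.64, 0.32, 0.16),
                                               np.zeros(3), 0.05)
        assert lam == 0.16 and not warned

    def test_threshold_scan(self):
        lam, idx, warned = stars_select_lambda(
            (0.64, 0.32, 0.16), np.array([0.01, 0.04, 0.06]), 0.05)
        assert lam == 0.32 and not warned

    def test_infeasible_returns_largest_with_warning(self):
        lam, idx, warned = stars_select_lambda(
            (0.64, 0.32), np.array([0.02, 0.2]), 0.0)
        assert lam == 0.64 and warned


def _toy_profile(lambdas, d_hat_by_type, p=2, q=2):
    d_bar = {et: monotonize(np.asarray(d)) for et, d in d_hat_by_type.items()}
    G = len(lambdas)
    return InstabilityProfile(tuple(lambdas), np.zeros((G, p + q, p + q)),
                              np.zeros((G, p + q, p + q)),
                              {et: np.asarray(d) for et, d in d_hat_by_type.items()},
                              d_bar, np.zeros((2, G)))


class TestStepsSelection:
    def test_identical_profiles_reduce_to_single_lambda_stars(self, rng):
        data = random_dataset(40, 2, (2, 2), rng)
        lambdas = (0.6, 0.3, 0.1)
        d = [0.0, 0.03, 0.2]
        prof = _toy_profile(lambdas, {et: d for et in ("all", "cc", "cd", "dd")})
        grid = LambdaGrid(lambdas)
        steps = steps_select(data, grid, profile=prof)
        stars = stars_select(data, grid, profile=prof)
        assert steps.chosen == PenaltyWeights.single(0.3)
        assert stars.chosen == steps.chosen

    def test_constructed_profiles_order_penalties(self, rng):
        """cc stabilizes late (large lambda), dd early -> lambda_cc > lambda_dd."""
        data = random_dataset(40, 2, (2, 2), rng)
        lambdas = (0.6, 0.3, 0.1)
        prof = _toy_profile(lambdas, {
            "all": [0.0, 0.1, 0.3],
            "cc": [0.04, 0.2, 0.4],   # only the largest lambda is stable
            "cd": [0.0, 0.04, 0.3],
            "dd": [0.0, 0.01, 0.02],  # stable everywhere
        })
        res = steps_select(data, LambdaGrid(lambdas), profile=prof)
        assert res.chosen.lambda_cc == 0.6
        assert res.chosen.lambda_cd == 0.3
        assert res.chosen.lambda_dd == 0.1
        assert res.chosen.lambda_cc > res.chosen.lambda_dd

    def test_fit_call_accounting_linear_in_grid(self, rng):
        """The subsample ensemble costs exactly N * |grid| fits."""
        data = random_dataset(60, 2, (2, 2), rng)
        grid = LambdaGrid((0.5, 0.25))
        N = 3
        idx = draw_subsamples(data.n, N=N, b=40, seed=0)
        core.reset_fit_counter()
        subsample_adjacencies(data, grid.candidates(), idx)
        assert core.fit_call_count() == N * len(grid.values)

    def test_profile_dbar_nonincreasing_in_lambda(self, rng):
        data = random_dataset(80, 3, (2, 2), rng)
        prof = instability_profile(data, LambdaGrid((0.6, 0.3, 0.15, 0.05)),
                                   N=4, b=50, seed=3)
        for et, d in prof.d_bar.items():
            assert np.all(np.diff(d) >= -1e-12)  # rises as lambda falls


def _ensemble_from_adjacencies(adjs, candidates):
    N = adjs.shape[0]
    return SubsampleEnsemble(np.zeros((N, 1), dtype=int), list(candidates), adjs)


class TestCubicSearch:
    def test_trivial_single_cell_grid(self, rng):
        data = random_dataset(50, 2, (2, 2), rng)
        res = cubic_stability_select(data, LambdaGrid((0.3,)), N=3, b=30,
                                     seed=0)
        assert res.chosen == PenaltyWeights.single(0.3)

    def test_fit_call_accounting_cubic_in_grid(self, rng):
        data = random_dataset(50, 2, (2, 2), rng)
        grid = LambdaGrid((0.5, 0.25))
        core.reset_fit_counter()
        cubic_stability_select(data, grid, N=2, b=35, seed=1)
        # N * G^3 subsample fits plus the final refit on all samples
        assert core.fit_call_count() == 2 * 8 + 1

    def test_matches_exhaustive_enumeration_on_synthetic_ensemble(self, rng):
        """2x2x2 toy grid with hand-built adjacency ensembles."""
        from mgmsteps.core import edge_type_masks
        p = q = 2
        P = p + q
        grid = LambdaGrid((0.4, 0.2))
        triple = LambdaGrid((0.4, 0.2), mode="triple")
        candidates = triple.candidates()
        N, C = 6, len(candidates)
        # half the candidates are perfectly stable with varying density,
        # the rest flicker; feasibility and edge counts then both matter
        adjs = np.zeros((N, C, P, P), dtype=bool)
        for c in range(C):
            if c % 2 == 0:
                fixed = rng.random((P, P)) < (0.2 + 0.1 * c)
                fixed = np.triu(fixed, 1)
                adjs[:, c] = fixed | fixed.T
            else:
                r = rng.random((N, P, P)) < 0.4
                r = np.triu(r, 1)
                adjs[:, c] = r | r.transpose(0, 2, 1)
        data = random_dataset(30, p, (2, 2), rng)
        ens = _ensemble_from_adjacencies(adjs, candidates)
        gamma = 0.3
        res = cubic_stability_select(data, grid, gamma=gamma,
                                     rule="per_type_max", ensemble=ens)
        # independent exhaustive scan
        masks = edge_type_masks(p, q)
        theta = adjs.mean(axis=0)
        xi = 2 * theta * (1 - theta)
        stats = []
        for et in ("cc", "cd", "dd"):
            d = xi[:, masks[et]].mean(axis=1).reshape(2, 2, 2)
            for ax in range(3):
                d = np.maximum.accumulate(d, axis=ax)
            stats.append(d)
        stat = np.maximum.reduce(stats).ravel()
        counts = adjs[:, :, masks["all"]].sum(axis=(0, 2))
        feasible = np.flatnonzero(stat <= gamma)
        assert feasible.size  # the toy ensemble admits feasible settings
        best = max(feasible, key=lambda i: (
            counts[i], candidates[i].lambda_dd, candidates[i].lambda_cd,
            candidates[i].lambda_cc))
        assert res.chosen == candidates[best]

    def test_single_feasible_setting_wins_regardless_of_edges(self, rng):
        p = q = 2
        P = p + q
        grid = LambdaGrid((0.4, 0.2))
        candidates = LambdaGrid((0.4, 0.2), mode="triple").candidates()
        N, C = 4, len(candidates)
        # every candidate maximally unstable except index 0 (all large lambdas)
        adjs = np.zeros((N, C, P, P), dtype=bool)
        adjs[:2, 1:, :, :] = True  # theta = .5 -> xi = .5 on all edges
        for c in range(C):
            for i in range(N):
                np.fill_diagonal(adjs[i, c], False)
        data = random_dataset(30, p, (2, 2), rng)
        res = cubic_stability_select(data, grid, gamma=0.05,
                                     ensemble=_ensemble_from_adjacencies(adjs, candidates))
        assert res.chosen == candidates[0]

    def test_no_feasible_setting_warns_and_returns_most_stable(self, rng):
        p = q = 2
        P = p + q
        grid = LambdaGrid((0.4, 0.2))
        candidates = LambdaGrid((0.4, 0.2), mode="triple").candidates()
        N, C = 4, len(candidates)
        adjs = np.zeros((N, C, P, P), dtype=bool)
        adjs[:2, :, :, :] = True  # all candidates unstable
        for c in range(C):
            for i in range(N):
                np.fill_diagonal(adjs[i, c], False)
        data = random_dataset(30, p, (2, 2), rng)
        with pytest.warns(RuntimeWarning):
            res = cubic_stability_select(
                data, grid, gamma=0.01,
                ensemble=_ensemble_from_adjacencies(adjs, candidates))
        assert res.warnings
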