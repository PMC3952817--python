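import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ordfit.data import RegionMap
from ordfit.scaling import (
    IntervalSet,
    ScalingConfig,
    clip_surrogates,
    feasible_zero_error,
    min_range_and_gap,
    model_scale,
    scaling_error,
    solve_scaling_cells,
    solve_scaling_ranks,
    total_variation,
)

from oracles import os_bruteforce, os_error_direct, os_zero_feasible


class TestModelScale:
    @pytest.mark.parametrize("y,expected", [
        ([0, 2, 4], 4.0),       # range
        ([5, 5, 5], 5.0),       # flat fallback to max |y|
        ([0, 0, 0], 1.0),       # degenerate fallback
        ([-1, 1], 2.0),
    ])
    def test_scale(self, y, expected):
        assert model_scale(np.asarray(y, float)) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            model_scale(np.array([1.0, np.nan]))


class TestMinRangeAndGap:
    def test_budget_consumed_exactly_for_two_or_more_ranks(self):
        # N minimum ranges plus N−1 minimum gaps account for 75% of the scale
        for n in range(2, 12):
            d, g = min_range_and_gap(n, 1.0)
            assert n * d + (n - 1) * g == pytest.approx(0.75)

    def test_single_rank_has_no_gap(self):
        d, g = min_range_and_gap(1, 1.0)
        assert g == 0.0 and d == pytest.approx(0.5)

    def test_scales_linearly_with_model_scale(self):
        d1, g1 = min_range_and_gap(3, 1.0)
        d2, g2 = min_range_and_gap(3, 7.0)
        assert (d2, g2) == (pytest.approx(7 * d1), pytest.approx(7 * g1))

    def test_budget_bound_holds_for_large_category_counts(self):
        b = ScalingConfig().min_range_fraction_budget
        for n in (1, 2, 10, 100, 1000):
            d, g = min_range_and_gap(n, 1.0)
            assert n * d + max(n - 1, 0) * g <= b + 1e-12

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            min_range_and_gap(2, 0.0)


class TestClipSurrogates:
    def test_inside_boundary_outside(self):
        iv = IntervalSet((0.2,), (0.8,))
        ranks = np.array([1, 1, 1])
        s = clip_surrogates(np.array([0.5, 1.0, 0.0]), iv, ranks)
        assert s == pytest.approx([0.5, 0.8, 0.2])

    def test_rank_without_interval_is_logic_error(self):
        iv = IntervalSet((0.0,), (1.0,))
        with pytest.raises(LookupError):
            clip_surrogates(np.array([0.5]), iv, np.array([2]))


class TestScalingError:
    def test_perfect_fit_is_zero(self):
        y = np.array([0.1, 0.5, 0.9])
        assert scaling_error(y, y, [np.arange(3)]) == 0.0

    def test_flat_output_penalized_via_epsilon(self):
        # nu = 0: error ~ |y − s| / (eps·S), very large
        y = np.full(4, 2.0)
        s = np.full(4, 1.0)
        err = scaling_error(y, s, [np.arange(4)])
        assert err == pytest.approx(1.0 / (1e-6 * 2.0), rel=1e-9)

    def test_hand_computed_example(self):
        y = np.array([1.0, 0.9, 0.2, 0.1])
        s = np.full(4, 0.55)
        # direct evaluation: nu = 0.9, eps = 1e-6 * 0.9
        nu = 0.1 + 0.7 + 0.1
        denom = nu + 1e-6 * 0.9
        expected = np.sqrt(np.mean(((y - s) / denom) ** 2))
        assert scaling_error(y, s, [np.arange(4)]) == pytest.approx(expected)

    def test_empty_domain_rejected(self):
        y = np.array([1.0, 2.0])
        with pytest.raises(ValueError):
            scaling_error(y, y, [np.array([], dtype=int)])


class TestSolveScaling:
    def test_rank_consistent_separable_is_exact(self):
        sol = solve_scaling_cells(np.array([0.1, 0.2, 0.8, 0.9]),
                                  np.array([1, 1, 2, 2]))
        assert sol.error == 0.0
        assert sol.feasible_zero

    def test_reversed_pattern_has_positive_error(self):
        sol = solve_scaling_cells(np.array([0.9, 0.8, 0.2, 0.1]),
                                  np.array([1, 1, 2, 2]))
        assert sol.error > 0.1

    def test_surrogates_lie_in_their_intervals(self):
        sol = solve_scaling_cells(np.array([0.9, 0.8, 0.2, 0.1]),
                                  np.array([1, 1, 2, 2]))
        lo, hi = sol.intervals.as_arrays()
        ranks = np.array([1, 1, 2, 2]) - 1
        assert np.all(sol.surrogates >= lo[ranks] - 1e-9)
        assert np.all(sol.surrogates <= hi[ranks] + 1e-9)

    def test_scale_invariance(self, rng):
        y = rng.uniform(0, 1, 6)
        ranks = rng.integers(1, 3, 6)
        e1 = solve_scaling_cells(y, ranks).error
        e2 = solve_scaling_cells(1000.0 * y, ranks).error
        assert e2 == pytest.approx(e1, rel=1e-6, abs=1e-9)

    def test_relaxing_budget_never_increases_error(self, rng):
        y = rng.uniform(0, 1, 6)
        ranks = np.array([2, 1, 2, 1, 1, 2])
        errs = [solve_scaling_cells(y, ranks,
                                    cfg=ScalingConfig(min_range_fraction_budget=b)).error
                for b in (0.75, 0.5, 0.25)]
        assert errs[1] <= errs[0] + 1e-9
        assert errs[2] <= errs[1] + 1e-9

    def test_matches_bruteforce_oracle_on_small_instances(self, rng):
        cfg = ScalingConfig()
        for _ in range(15):
            n = int(rng.integers(3, 7))
            n_cat = int(rng.integers(2, 4))
            y = rng.uniform(0, 1, n)
            ranks = rng.integers(1, n_cat + 1, n)
            sol = solve_scaling_cells(y, ranks, n_cat=n_cat, cfg=cfg)
            S, nu = model_scale(y), total_variation(y)
            d, g = min_range_and_gap(n_cat, S, cfg)
            ref = os_bruteforce(y, ranks, [np.arange(n)], n_cat, d, g,
                                cfg.lower_bound, nu, cfg.epsilon_fraction * S,
                                grid=5 if n_cat == 3 else 7)
            assert sol.error <= ref + 1e-3 * max(ref, 1.0)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_zero_error_iff_feasible(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 7))
        n_cat = int(r.integers(1, 4))
        y = np.round(r.uniform(0, 1, n), 3)
        ranks = r.integers(1, n_cat + 1, n)
        cfg = ScalingConfig()
        sol = solve_scaling_cells(y, ranks, n_cat=n_cat, cfg=cfg)
        S = model_scale(y)
        d, g = min_range_and_gap(n_cat, S, cfg)
        feasible = os_zero_feasible(y, ranks, n_cat, d, g, cfg.lower_bound)
        assert sol.feasible_zero == feasible
        assert (sol.error == 0.0) == feasible


class TestRegionInterface:
    def test_region_domains_weight_regions_equally(self, region_map):
        # same per-region pattern; cyst has 7 cells but counts as one domain
        y = np.concatenate([[1.0, 1.0], np.full(7, 0.1), np.full(8, 0.1)])
        sol = solve_scaling_ranks(y, {"GSC": 2, "CB": 2, "Cyst": 1, "Posterior": 1},
                                  2, region_map)
        assert sol.error == 0.0

    def test_error_consistent_with_direct_formula(self, region_map, rng):
        y = rng.uniform(0, 1, 17)
        ranks = {"GSC": 2, "CB": 1, "Cyst": 2, "Posterior": 1}
        sol = solve_scaling_ranks(y, ranks, 2, region_map)
        cells = np.concatenate([region_map.cells(r) for r in ranks]) - 1
        per_cell = np.concatenate([[ranks[r]] * len(region_map.cells(r))
                                   for r in ranks])
        s = clip_surrogates(y[cells], sol.intervals, per_cell)
        domains, pos = [], 0
        for r in ranks:
            k = len(region_map.cells(r))
            domains.append(np.arange(pos, pos + k))
            pos += k
        direct = os_error_direct(y[cells], s, domains, total_variation(y),
                                 1e-6 * model_scale(y))
        assert sol.error == pytest.approx(direct, rel=1e-9)


class TestFeasibilityHelper:
    def test_greedy_bounds_satisfy_constraints_when_feasible(self, rng):
        y = np.array([0.05, 0.1, 0.6, 0.9])
        ranks = np.array([1, 1, 2, 2])
        d, g = min_range_and_gap(2, model_scale(y))
        ok, L, U = feasible_zero_error(y, ranks, 2, d, g, 0.0)
        assert ok
        assert U[0] - L[0] >= d - 1e-12
        assert L[1] - U[0] >= g - 1e-12
        assert L[0] >= 0.0
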