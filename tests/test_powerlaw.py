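import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import zeta as scipy_zeta

from zipflemma.powerlaw import (
    DiscretePowerLaw,
    alpha_to_gamma,
    cutoff_grid,
    gamma_to_alpha,
    gof_and_sigma,
    hurwitz_zeta,
    ks_distance,
    mle_exponent,
    scan_lower_cutoff,
    scan_upper_cutoff,
)

BASEL = math.pi**2 / 6


# --- independent oracles -------------------------------------------------

def grid_search_mle(counts, a, b=None, lo=1.01, hi=4.0, step=1e-4):
    """Brute-force exponent fit: dense grid over the log-likelihood."""
    vals = np.asarray(counts)
    vals = vals[vals >= a]
    if b is not None:
        vals = vals[vals <= b]
    sum_log = np.sum(np.log(vals))
    gammas = np.arange(lo, hi, step)
    if b is None:
        Z = scipy_zeta(gammas, a)
    else:
        k = np.arange(a, b + 1, dtype=float)
        Z = np.array([np.sum(k**-g) for g in gammas])
    ll = -gammas * sum_log - vals.size * np.log(Z)
    return gammas[np.argmax(ll)]


def step_function_ks(counts, gamma, a):
    """KS oracle: compare step CDFs at every integer of the observed range."""
    vals = np.sort(np.asarray(counts))
    Z = scipy_zeta(gamma, a)
    best = 0.0
    for n in range(a, vals.max() + 1):
        ecdf = np.mean(vals <= n)
        model = 1.0 - scipy_zeta(gamma, n + 1) / Z
        best = max(best, abs(ecdf - model))
        # the supremum can also sit just below a jump of the empirical CDF
        ecdf_before = np.mean(vals <= n - 1)
        model_before = 1.0 - scipy_zeta(gamma, n) / Z
        best = max(best, abs(ecdf_before - model_before))
    return best


# --- hurwitz zeta and pmf ------------------------------------------------

class TestModel:
    def test_zeta_closed_forms(self):
        assert math.isclose(hurwitz_zeta(2, 1), BASEL, rel_tol=1e-12)
        assert math.isclose(hurwitz_zeta(2, 2), BASEL - 1, rel_tol=1e-12)
        # direct series summation oracle for zeta(3, 1) = Apery's constant
        direct = sum(k**-3.0 for k in range(1, 200_000))
        assert math.isclose(hurwitz_zeta(3, 1), direct, rel_tol=1e-10)

    def test_zeta_divergence_error(self):
        with pytest.raises(ValueError):
            hurwitz_zeta(1.0, 1)

    def test_pmf_closed_forms(self):
        assert math.isclose(DiscretePowerLaw(2, 1).pmf(1), 6 / math.pi**2, rel_tol=1e-12)
        assert math.isclose(DiscretePowerLaw(2, 2).pmf(2), 0.25 / (BASEL - 1), rel_tol=1e-12)

    def test_pmf_zero_outside_support(self):
        m = DiscretePowerLaw(2.0, 5)
        assert m.pmf(4) == 0.0
        assert DiscretePowerLaw(2.0, 1, b=10).pmf(11) == 0.0

    @pytest.mark.parametrize("gamma", [1.5, 2.0, 3.0])
    @pytest.mark.parametrize("a", [1, 10, 200])
    @pytest.mark.parametrize("b", [None, "a+500"])
    def test_pmf_normalization(self, gamma, a, b):
        b = a + 500 if b else None
        m = DiscretePowerLaw(gamma, a, b)
        top = b if b is not None else a + 2_000_000
        n = np.arange(a, top + 1)
        total = m.pmf(n).sum() + (m.sf(top + 1) if b is None else 0.0)
        assert abs(total - 1.0) <= 1e-9


class TestSampling:
    def test_concentration_at_cutoff_for_steep_exponent(self):
        draws = DiscretePowerLaw(50.0, 5).sample(2000, seed=0)
        assert np.all(draws >= 5)
        assert np.mean(draws == 5) > 0.96

    def test_single_point_support(self):
        draws = DiscretePowerLaw(2.0, 3, b=3).sample(100, seed=0)
        assert np.all(draws == 3)

    def test_empirical_mass_matches_pmf(self):
        m = DiscretePowerLaw(2.0, 1)
        draws = m.sample(100_000, seed=123)
        p1 = m.pmf(1)
        se = math.sqrt(p1 * (1 - p1) / draws.size)
        assert abs(np.mean(draws == 1) - p1) < 3 * se

    def test_determinism(self):
        m = DiscretePowerLaw(2.0, 1)
        assert np.array_equal(m.sample(1000, seed=9), m.sample(1000, seed=9))


class TestMLE:
    def test_parameter_recovery_within_3_sigma(self):
        model = DiscretePowerLaw(2.0, 10)
        draws = model.sample(10_000, seed=5)
        res = gof_and_sigma(draws, 10, n_sims=200, seed=6)
        assert abs(res.gamma_hat - 2.0) < 3 * res.sigma

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gamma = float(rng.uniform(1.3, 3.2))
        a = int(rng.choice([1, 2, 5]))
        draws = DiscretePowerLaw(gamma, a).sample(300, rng)
        fitted = mle_exponent(draws, a)
        oracle = grid_search_mle(draws, a)
        assert abs(fitted - oracle) < 1e-3

    def test_truncated_matches_grid_search_oracle(self):
        draws = DiscretePowerLaw(1.7, 1, b=60).sample(400, seed=2)
        fitted = mle_exponent(draws, 1, b=60)
        assert abs(fitted - grid_search_mle(draws, 1, b=60)) < 1e-3

    def test_local_optimality(self):
        counts = [2, 2, 2, 4]
        g = mle_exponent(counts, 2)
        def ll(gamma):
            vals = np.array(counts, float)
            return -gamma * np.sum(np.log(vals)) - vals.size * np.log(scipy_zeta(gamma, 2))
        assert ll(g) >= ll(g - 0.01)
        assert ll(g) >= ll(g + 0.01)

    def test_insufficient_data_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            mle_exponent([1, 1, 5], 5)
        with pytest.raises(ValueError, match="equal"):
            mle_exponent([7, 7, 7], 5)


class TestKS:
    def test_bounded_between_zero_and_one(self):
        m = DiscretePowerLaw(2.0, 4)
        d = ks_distance([4], m)
        assert 0 <= d <= 1

    def test_matches_step_function_oracle(self):
        counts = [2, 2, 3, 5, 9]
        m = DiscretePowerLaw(1.9, 2)
        assert math.isclose(ks_distance(counts, m), step_function_ks(counts, 1.9, 2), rel_tol=1e-10)

    def test_exact_match_on_replicated_proportions(self):
        # truncated toy whose empirical proportions equal the pmf exactly
        m = DiscretePowerLaw(1.0 + 1e-9, 1, b=2)  # pmf = (2/3, 1/3)
        counts = [1, 1, 2]
        assert ks_distance(counts, m) < 1e-6

    def test_empty_in_range_error(self):
        with pytest.raises(ValueError):
            ks_distance([1, 2], DiscretePowerLaw(2.0, 10))


class TestGof:
    def test_determinism(self):
        draws = DiscretePowerLaw(2.0, 5).sample(500, seed=3)
        r1 = gof_and_sigma(draws, 5, n_sims=50, seed=4)
        r2 = gof_and_sigma(draws, 5, n_sims=50, seed=4)
        assert (r1.p_value, r1.sigma, r1.gamma_hat) == (r2.p_value, r2.sigma, r2.gamma_hat)

    def test_rejects_grossly_non_power_law_data(self):
        counts = np.array([5] * 250 + [400] * 250)
        res = gof_and_sigma(counts, 5, n_sims=200, seed=8)
        assert res.p_value < 0.05

    def test_nsims_validation(self):
        with pytest.raises(ValueError):
            gof_and_sigma([2, 3, 4], 2, n_sims=0, seed=0)


class TestCutoffGrid:
    def test_default_enumeration_matches_successive_multiplication(self):
        grid = cutoff_grid(1, 260, per_decade=10)
        v, expected = 1.0, []
        while math.ceil(v) <= 260:
            if not expected or math.ceil(v) != expected[-1]:
                expected.append(math.ceil(v))
            v *= 10 ** 0.1
        assert grid == expected
        # the grid reproduces published cutoffs, including the ones just
        # past an exact power of ten
        for a in [6, 8, 13, 16, 20, 26, 32, 40, 51, 101, 200]:
            assert a in grid

    def test_one_per_decade_is_powers_of_ten(self):
        assert cutoff_grid(1, 10_000, per_decade=1)[:3] == [1, 10, 100]

    def test_degenerate_range(self):
        assert cutoff_grid(7, 7) == [7]

    def test_validation(self):
        with pytest.raises(ValueError):
            cutoff_grid(1, 10, per_decade=0)
        with pytest.raises(ValueError):
            cutoff_grid(5, 2)

    @given(st.integers(1, 50), st.integers(1, 12))
    @settings(deadline=None, max_examples=30)
    def test_strictly_increasing_within_bounds(self, a_min, per_decade):
        grid = cutoff_grid(a_min, a_min + 500, per_decade)
        assert all(x < y for x, y in zip(grid, grid[1:]))
        assert grid[0] == a_min and grid[-1] <= a_min + 500


class TestScans:
    def test_pure_power_law_selects_small_cutoff(self):
        draws = DiscretePowerLaw(2.0, 1).sample(5000, seed=21)
        scan = scan_lower_cutoff(draws, n_sims=100, seed=22)
        assert scan.found
        assert scan.fit.a <= 3
        assert abs(scan.fit.gamma_hat - 2.0) < 3 * scan.fit.sigma

    def test_contamination_forces_cutoff_up(self):
        rng = np.random.default_rng(23)
        draws = DiscretePowerLaw(2.0, 1).sample(5000, rng)
        low = draws < 20
        draws[low] = rng.integers(1, 20, size=low.sum())  # wreck the head
        scan = scan_lower_cutoff(draws, n_sims=100, seed=24)
        assert scan.found and scan.fit.a >= 10

    def test_two_decade_validity_rule(self):
        from zipflemma.powerlaw import TailFit

        fit = TailFit(a=6, gamma_hat=1.95, sigma=0.01, ks=0.01, p_value=0.5,
                      N_a=4377, n_m=14934, n_sims=0, seed=0)
        assert fit.zipf_valid  # 14934 / 6 ~ 2489, over two decades
        assert not TailFit(a=200, gamma_hat=2.0, sigma=0.01, ks=0.01, p_value=0.5,
                           N_a=100, n_m=5000, n_sims=0, seed=0).zipf_valid

    def test_upper_scan_recovers_truncated_head_regime(self):
        rng = np.random.default_rng(25)
        head = DiscretePowerLaw(1.7, 1, b=50).sample(4000, rng)
        tail = DiscretePowerLaw(2.1, 51).sample(400, rng)
        counts = np.concatenate([head, tail])
        scan = scan_upper_cutoff(counts, a=1, n_sims=100, seed=26)
        assert scan.found
        assert scan.fit.b >= 30
        assert abs(scan.fit.gamma_hat - 1.7) < 0.15

    def test_upper_scan_accepts_pure_power_law_to_near_max(self):
        draws = DiscretePowerLaw(2.0, 1).sample(2000, seed=30)
        scan = scan_upper_cutoff(draws, a=1, n_sims=100, seed=28)
        assert scan.found
        assert scan.fit.b == scan.fit.n_m

    def test_no_tail_is_a_result_not_an_error(self):
        counts = np.array([1] * 400 + [2] * 400 + [37] * 200)
        scan = scan_lower_cutoff(counts, n_sims=50, seed=29)
        assert not scan.found and scan.fit is None


class TestExponentConversion:
    def test_published_worked_examples(self):
        assert round(gamma_to_alpha(1.715), 2) == 1.40
        assert round(gamma_to_alpha(1.77), 2) == 1.30

    def test_classical_zipf_case(self):
        assert gamma_to_alpha(2.0) == 1.0

    @given(st.floats(1.05, 9.0))
    @settings(deadline=None, max_examples=50)
    def test_round_trip(self, gamma):
        assert math.isclose(alpha_to_gamma(gamma_to_alpha(gamma)), gamma, rel_tol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            gamma_to_alpha(1.0)
        with pytest.raises(ValueError):
            alpha_to_gamma(0.0)
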