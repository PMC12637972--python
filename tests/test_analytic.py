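"""Fixation probability, exact chain oracle, shape analysis, dosimetry."""

import math

import numpy as np
import pytest

from stemcomp import (
    CostMatrix,
    OccupationalScenario,
    Shape,
    approx_absorption_time,
    classify_shape,
    dose_rate_from_annual,
    exact_expected_absorption_time,
    fixation_probability,
    fixation_probability_bruteforce,
    large_n_increase,
    log_normalized_absorption_time,
    normalized_absorption_time,
    occupational_lambda,
    small_n_decrease,
    working_days_per_elemental_dose,
)
from conftest import (
    CONVEX_E,
    DAMAGED_DOMINANT,
    GREEN,
    HAWK_DOVE,
    INTACT_DOMINANT,
    NEUTRAL,
    random_cost_matrix,
)


class TestFixationProbability:
    @pytest.mark.parametrize("n", [2, 20, 1000, 100_000])
    def test_neutral_identity_n_times_pi_is_one(self, n):
        assert n * fixation_probability(n, NEUTRAL) == pytest.approx(1.0, abs=1e-12)
        assert normalized_absorption_time(n, NEUTRAL) == pytest.approx(1.0, abs=1e-12)

    def test_constant_ratio_geometric_closed_form(self):
        # frequency-independent costs give G_k/F_k = c everywhere, so
        # pi_1 = (1-c)/(1-c^n)
        for c, n in [(0.8, 10), (1.25, 10), (0.8, 50), (1.25, 50)]:
            cm = CostMatrix(1.0, 1.0, c, c)
            expected = (1 - c) / (1 - c**n)
            assert fixation_probability(n, cm) == pytest.approx(expected, abs=1e-10)

    def test_two_cell_pool_closed_form(self):
        # n=2: single-term sum, pi_1 = F_1 / (F_1 + G_1) = c_id/(c_id + c_di)
        pi = fixation_probability(2, GREEN)
        assert pi == pytest.approx(1.5 / (1.5 + 1.16), abs=1e-12)
        assert pi == pytest.approx(fixation_probability_bruteforce(2, GREEN), abs=1e-10)

    def test_log_space_and_bruteforce_routes_agree(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 51))
            cm = random_cost_matrix(rng)
            a = fixation_probability(n, cm)
            b = fixation_probability_bruteforce(n, cm)
            assert a == pytest.approx(b, abs=1e-10, rel=1e-8)

    def test_bruteforce_neutral_is_one_over_n(self):
        assert fixation_probability_bruteforce(20, NEUTRAL) == pytest.approx(0.05, abs=1e-12)

    def test_huge_pool_reachable_without_overflow(self):
        # strongly selected regimes overflow direct products long before 1e5
        lf = log_normalized_absorption_time(100_000, INTACT_DOMINANT)
        assert math.isfinite(lf) and lf > 0


class TestApproxAbsorptionTime:
    def test_neutral_low_dose_time_is_inverse_dose_rate(self):
        for n in (2, 10, 50):
            assert approx_absorption_time(n, 1e-3, NEUTRAL) == pytest.approx(1000.0)

    def test_inverse_proportionality_in_dose_rate(self):
        t1 = approx_absorption_time(20, 0.01, GREEN)
        t2 = approx_absorption_time(20, 0.02, GREEN)
        assert t2 == pytest.approx(t1 / 2, rel=1e-14)

    def test_intact_dominance_lengthens_with_pool_size(self):
        cm = CostMatrix(1, 1, 1.25, 1.25)
        assert approx_absorption_time(50, 0.01, cm) > approx_absorption_time(5, 0.01, cm)

    def test_rejects_zero_dose_rate(self):
        with pytest.raises(ValueError):
            approx_absorption_time(10, 0.0, NEUTRAL)


class TestExactChain:
    def test_three_state_chain_matches_symbolic_solve(self):
        # n=2 neutral: build the composite radiation+competition chain in
        # sympy and solve the mean-hitting-time system exactly
        sympy = pytest.importorskip("sympy")
        lam = sympy.Rational(1, 2)
        p = 1 - sympy.exp(-lam / 2)
        # radiation kernel rows from k=0,1,2 then the neutral competition step
        rad = sympy.Matrix(
            [
                [(1 - p) ** 2, 2 * p * (1 - p), p**2],
                [0, 1 - p, p],
                [0, 0, 1],
            ]
        )
        quarter = sympy.Rational(1, 4)
        moran = sympy.Matrix(
            [[1, 0, 0], [quarter, sympy.Rational(1, 2), quarter], [0, 0, 1]]
        )
        full = rad * moran
        q = full[:2, :2]
        t = (sympy.eye(2) - q).solve(sympy.ones(2, 1))
        expected = float(t[0] / 2)
        assert exact_expected_absorption_time(2, 0.5, NEUTRAL) == pytest.approx(
            expected, rel=1e-12
        )

    def test_converges_to_low_dose_approximation(self):
        exact = exact_expected_absorption_time(10, 1e-4, NEUTRAL)
        assert exact == pytest.approx(1e4, rel=0.02)
        # and for a selected matrix the ratio to the approximation -> 1
        exact_g = exact_expected_absorption_time(10, 1e-5, GREEN)
        approx_g = approx_absorption_time(10, 1e-5, GREEN)
        assert exact_g / approx_g == pytest.approx(1.0, abs=0.05)

    def test_rejects_zero_dose_rate(self):
        # at lam=0 the all-intact state is absorbing too
        with pytest.raises(ValueError):
            exact_expected_absorption_time(10, 0.0, NEUTRAL)

    def test_absorption_is_certain_for_positive_dose(self):
        # unique absorbing state: hitting probability of k=n is 1 from anywhere
        from scipy.stats import binom

        from stemcomp.wellmixed import _step_tables

        for n in (3, 7, 10):
            lam = 0.05
            p = -math.expm1(-lam / n)
            states = np.arange(n + 1)
            rad = np.zeros((n + 1, n + 1))
            for k in states:
                j = np.arange(0, n - k + 1)
                rad[k, k + j] = binom.pmf(j, n - k, p)
            up, down = _step_tables(n, GREEN)
            moran = np.zeros((n + 1, n + 1))
            moran[states, states] = 1 - up - down
            moran[states[:-1], states[:-1] + 1] = up[:-1]
            moran[states[1:], states[1:] - 1] = down[1:]
            full = rad @ moran
            q = full[:n, :n]
            hit = np.linalg.solve(np.eye(n) - q, full[:n, n])
            assert hit == pytest.approx(np.ones(n), abs=1e-10)


class TestShapeAnalysis:
    @pytest.mark.parametrize(
        "cm, expected",
        [
            (NEUTRAL, Shape.CONSTANT),
            (DAMAGED_DOMINANT, Shape.MONOTONE_DECREASING),
            (INTACT_DOMINANT, Shape.MONOTONE_INCREASING),
            (HAWK_DOVE, Shape.CONVEX_DOWN),
            (CONVEX_E, Shape.CONVEX_DOWN),
        ],
    )
    def test_benchmark_shapes(self, cm, expected):
        assert classify_shape(cm) is expected

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            classify_shape(NEUTRAL, [2, 3])
        with pytest.raises(ValueError):
            classify_shape(NEUTRAL, [2, 5, 4])
        with pytest.raises(ValueError):
            classify_shape(NEUTRAL, [1, 2, 3])

    @pytest.mark.parametrize(
        "cm, small_dec, large_inc",
        [
            (NEUTRAL, False, False),
            (DAMAGED_DOMINANT, True, False),
            (INTACT_DOMINANT, False, True),
            (CONVEX_E, True, True),
        ],
    )
    def test_boundary_indicators(self, cm, small_dec, large_inc):
        assert small_n_decrease(cm) is small_dec
        assert large_n_increase(cm) is large_inc

    def test_dominance_regimes_map_to_monotone_shapes(self, rng):
        # sampled over the diagram region: intact dominance always rises,
        # damaged dominance always falls
        for _ in range(10):
            hi = float(rng.uniform(1.02, 1.5))
            lo = float(rng.uniform(0.5, 0.98))
            up_cm = CostMatrix(1.0, 1.0, hi, float(rng.uniform(1.02, 1.5)))
            dn_cm = CostMatrix(1.0, 1.0, lo, float(rng.uniform(0.5, 0.98)))
            grid = (2, 3, 4, 8, 16, 64, 256, 1000)
            assert classify_shape(up_cm, grid) is Shape.MONOTONE_INCREASING
            assert classify_shape(dn_cm, grid) is Shape.MONOTONE_DECREASING


class TestDosimetry:
    def test_occupational_worked_example(self):
        sc = OccupationalScenario(
            dose_rate_mgy_per_h=0.01,
            exposed_hours_per_cycle=8.0,
            elemental_dose_mgy=1.0,
            hit_to_damage_prob=1.0,
        )
        assert occupational_lambda(sc) == pytest.approx(0.08)

    def test_annual_dose_intermediates(self):
        rate = dose_rate_from_annual(20.0, 250.0, 8.0)
        assert rate == pytest.approx(0.01)
        assert working_days_per_elemental_dose(rate, 8.0, 1.0) == pytest.approx(12.5)

    def test_linear_in_damage_probability(self):
        base = OccupationalScenario(0.01, 8.0, 1.0, 1.0)
        half = OccupationalScenario(0.01, 8.0, 1.0, 0.5)
        zero = OccupationalScenario(0.01, 8.0, 1.0, 0.0)
        assert occupational_lambda(half) == pytest.approx(occupational_lambda(base) / 2)
        assert occupational_lambda(zero) == 0.0

    def test_zero_elemental_dose_rejected(self):
        with pytest.raises(ValueError):
            occupational_lambda(OccupationalScenario(0.01, 8.0, 0.0, 1.0))
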