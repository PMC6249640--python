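"""Unit and property tests for the Coxian phase-type mathematics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from coxianreg import (
    CoxianParameters,
    CoxianValidationError,
    DegenerateRatesError,
    absorption_probabilities,
    build_generator,
    canonical_form,
    cumulative_hazard,
    hazard,
    pdf,
    pdf_analytic,
    pdf_matrix,
    phase_time_bounds,
    sample_absorption_times,
    survivor,
)
from coxianreg.core import _sample_paths


class TestParameterValidation:
    @pytest.mark.parametrize(
        "lams, mus, fragment",
        [
            ([0.5, -0.1, 0.0], [0.1, 0.1, 0.2], "lambda_2"),
            ([0.5, 0.1], [0.1, -0.2], "mu_2"),
            ([0.5, 0.1], [0.1, 0.2], "lambda_2"),  # final lambda nonzero
            ([0.5, 0.0], [0.1, 0.0], "mu_2"),  # final phase cannot absorb
            ([0.0, 0.0], [0.0, 0.5], "trapping"),
            ([0.5], [0.1, 0.2], "length mismatch"),
        ],
    )
    def test_invalid_rates_name_the_offender(self, lams, mus, fragment):
        with pytest.raises(CoxianValidationError, match=fragment):
            CoxianParameters(np.array(lams, dtype=float), np.array(mus, dtype=float))

    def test_config_roundtrip(self, ckd_rates):
        again = CoxianParameters.from_config(ckd_rates.to_config())
        np.testing.assert_array_equal(again.lambdas, ckd_rates.lambdas)
        np.testing.assert_array_equal(again.mus, ckd_rates.mus)


class TestGenerator:
    def test_single_phase_is_exponential(self):
        gen = build_generator(CoxianParameters(np.array([0.0]), np.array([0.7])))
        assert gen.Q == pytest.approx(np.array([[-0.7]]))
        assert gen.p.tolist() == [1.0]
        assert gen.q.tolist() == [0.7]

    def test_reference_rates_layout(self, ckd_rates):
        gen = build_generator(ckd_rates)
        np.testing.assert_allclose(
            np.diag(gen.Q), [-(0.060 + 9.02e-11), -0.902, -0.060], rtol=1e-15
        )
        np.testing.assert_allclose(np.diag(gen.Q, k=1), [0.060, 0.467])
        assert gen.Q[2, 0] == 0.0 and gen.Q[0, 2] == 0.0

    def test_row_sums_equal_negative_absorption(self, parameter_battery):
        for params in parameter_battery:
            gen = build_generator(params)
            np.testing.assert_allclose(gen.Q.sum(axis=1), -params.mus, atol=1e-14)
        # the two-phase example with mu = (0, 1)
        gen = build_generator(CoxianParameters(np.array([1.0, 0.0]), np.array([0.0, 1.0])))
        np.testing.assert_allclose(gen.Q.sum(axis=1), [0.0, -1.0], atol=1e-15)


class TestDensity:
    def test_exponential_closed_form(self):
        p = CoxianParameters(np.array([0.0]), np.array([0.5]))
        assert pdf_matrix(p, 0.0) == pytest.approx(0.5, abs=1e-12)
        assert pdf_matrix(p, 2.0) == pytest.approx(0.5 * np.exp(-1.0), rel=1e-12)
        assert pdf_analytic(p, 2.0) == pytest.approx(0.5 * np.exp(-1.0), rel=1e-12)

    def test_negative_time_rejected(self, ckd_rates):
        with pytest.raises(ValueError):
            pdf_matrix(ckd_rates, -1.0)
        with pytest.raises(ValueError):
            survivor(ckd_rates, -0.5)

    def test_analytic_equals_matrix_on_battery(self, parameter_battery):
        t = np.linspace(0.05, 40.0, 20)
        for params in parameter_battery:
            fa = pdf_analytic(params, t)
            fm = pdf_matrix(params, t)
            np.testing.assert_allclose(fa, fm, rtol=1e-10, atol=1e-300)

    def test_analytic_equals_matrix_stiff_reference(self, ckd_rates):
        # mu_1 ~ 9e-11 puts two total rates within 1.5e-9 relative of each
        # other; cancellation in the partial fractions limits the agreement.
        t = np.linspace(0.5, 60.0, 15)
        fa = pdf_analytic(ckd_rates, t)
        fm = pdf_matrix(ckd_rates, t)
        np.testing.assert_allclose(fa, fm, rtol=1e-4)

    def test_degenerate_rates_signal_and_fallback(self):
        tied = CoxianParameters(np.array([0.3, 0.0]), np.array([0.2, 0.5]))
        with pytest.raises(DegenerateRatesError):
            pdf_analytic(tied, 1.0)
        # dispatcher falls back to the matrix form
        assert pdf(tied, 1.0) == pytest.approx(pdf_matrix(tied, 1.0), rel=1e-12)

    def test_density_normalises(self, parameter_battery):
        for params in parameter_battery[::4]:
            sigma_min = params.total_rates.min()
            upper = 60.0 / sigma_min
            total, _ = integrate.quad(
                lambda u: pdf(params, float(u)), 0.0, upper, limit=200
            )
            assert total == pytest.approx(1.0, abs=1e-6)


class TestSurvivorHazard:
    def test_survivor_at_zero_and_exponential(self, parameter_battery):
        for params in parameter_battery[::5]:
            assert survivor(params, 0.0) == pytest.approx(1.0, abs=1e-12)
        p = CoxianParameters(np.array([0.0]), np.array([0.5]))
        assert survivor(p, 2.0) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_survivor_monotone(self, parameter_battery):
        t = np.linspace(0.0, 80.0, 60)
        for params in parameter_battery[::3]:
            S = survivor(params, t)
            assert np.all(np.diff(S) <= 1e-12)

    def test_survivor_consistent_with_density_quadrature(self, ckd_rates):
        # matrix form on both sides: the stiff reference rates limit the
        # analytic expansion to ~1e-5 relative, well short of this oracle
        cdf, _ = integrate.quad(
            lambda u: pdf_matrix(ckd_rates, float(u)), 0.0, 24.0,
            limit=200, epsabs=1e-12, epsrel=1e-12,
        )
        S = survivor(ckd_rates, 24.0, method="matrix")
        assert S == pytest.approx(1.0 - cdf, abs=1e-8)

    def test_hazard_constant_for_exponential(self):
        p = CoxianParameters(np.array([0.0]), np.array([0.5]))
        for t in (0.0, 1.0, 7.3, 100.0):
            assert hazard(p, t) == pytest.approx(0.5, rel=1e-10)

    def test_hazard_matches_definition(self):
        p = CoxianParameters(np.array([1.0, 0.0]), np.array([0.2, 2.0]))
        t = np.linspace(0.1, 12.0, 10)
        np.testing.assert_allclose(
            hazard(p, t), pdf_matrix(p, t) / survivor(p, t, method="matrix"),
            rtol=1e-9,
        )

    def test_hazard_approaches_final_phase_rate(self, ckd_rates):
        # the final-phase absorption rate is 0.06/month; the mixture hazard
        # climbs towards it as survivors concentrate in the last phase
        h200 = hazard(ckd_rates, 200.0)
        h2000 = hazard(ckd_rates, 2000.0)
        assert 0.05 < h200 < 0.06
        assert h200 < h2000 < 0.06

    def test_hazard_bounded_by_absorption_rates(self, parameter_battery):
        t = np.linspace(0.01, 50.0, 25)
        for params in parameter_battery:
            h = np.atleast_1d(hazard(params, t))
            assert np.all(h >= params.mus.min() - 1e-9)
            assert np.all(h <= params.mus.max() + 1e-9)

    def test_hazard_underflow_guard_returns_final_rate(self):
        p = CoxianParameters(np.array([0.0]), np.array([0.5]))
        assert hazard(p, 5000.0) == pytest.approx(0.5)

    def test_cumulative_hazard_basics(self, parameter_battery):
        p = CoxianParameters(np.array([0.0]), np.array([0.5]))
        assert cumulative_hazard(p, 0.0) == 0.0
        assert cumulative_hazard(p, 4.0) == pytest.approx(2.0, rel=1e-10)
        # exact linear continuation through survivor underflow
        assert cumulative_hazard(p, 5000.0) == pytest.approx(2500.0, rel=1e-9)
        for params in parameter_battery[::6]:
            t = np.linspace(0.0, 60.0, 30)
            H = cumulative_hazard(params, t)
            assert np.all(np.diff(H) >= -1e-10)

    def test_cumulative_hazard_matches_hazard_quadrature(self, ckd_rates):
        for t_end in (6.0, 24.0):
            integral, _ = integrate.quad(
                lambda u: hazard(ckd_rates, float(u)), 0.0, t_end, limit=200
            )
            assert cumulative_hazard(ckd_rates, t_end) == pytest.approx(
                integral, abs=1e-6
            )


class TestAbsorption:
    def test_reference_profile(self, ckd_rates):
        pis = absorption_probabilities(ckd_rates).pis
        assert pis[0] == pytest.approx(1.50e-9, rel=5e-3)
        assert pis[1] == pytest.approx(0.482, abs=5e-4)
        assert pis[2] == pytest.approx(0.518, abs=5e-4)

    def test_single_phase_profile(self):
        pis = absorption_probabilities(
            CoxianParameters(np.array([0.0]), np.array([0.3]))
        ).pis
        assert pis.tolist() == [1.0]

    def test_profiles_sum_to_one(self, parameter_battery):
        for params in parameter_battery:
            assert abs(absorption_probabilities(params).pis.sum() - 1.0) < 1e-12

    def test_profile_matches_simulated_exit_frequencies(self):
        params = CoxianParameters(
            np.array([0.9, 0.4, 0.25, 0.0]), np.array([0.3, 0.5, 0.15, 0.4])
        )
        pis = absorption_probabilities(params).pis
        m = 200_000
        _, exits = _sample_paths(params, m, np.random.default_rng(77))
        freq = np.bincount(exits, minlength=5)[1:] / m
        se = np.sqrt(pis * (1 - pis) / m)
        assert np.all(np.abs(freq - pis) <= 3 * se)


class TestPhasePartition:
    def test_reference_partition(self, ckd_rates):
        profile = absorption_probabilities(ckd_rates)
        times = np.sort(np.random.default_rng(0).exponential(20.0, 577))
        part = phase_time_bounds(profile, times)
        assert part.bounds == ((0, 0), (0, 278), (278, 577))
        assert (part.assignments == 2).sum() == 278
        assert (part.assignments == 3).sum() == 299

    def test_single_phase_takes_everything(self):
        from coxianreg import AbsorptionProfile

        part = phase_time_bounds(AbsorptionProfile(np.array([1.0])), np.arange(1.0, 9.0))
        assert part.bounds == ((0, 8),)

    def test_floor_then_remainder_rule(self):
        from coxianreg import AbsorptionProfile

        part = phase_time_bounds(
            AbsorptionProfile(np.array([0.5, 0.5])), np.arange(1.0, 6.0)
        )
        # floor(5 * 0.5) = 2 -> blocks of sizes 2 and 3
        assert part.bounds == ((0, 2), (2, 5))

    def test_input_validation(self, ckd_rates):
        profile = absorption_probabilities(ckd_rates)
        with pytest.raises(CoxianValidationError):
            phase_time_bounds(profile, [])
        with pytest.raises(CoxianValidationError):
            phase_time_bounds(profile, [3.0, 1.0, 2.0])


class TestSampling:
    def test_exponential_mean(self):
        p = CoxianParameters(np.array([0.0]), np.array([0.5]))
        t = sample_absorption_times(p, 100_000, seed=5)
        assert abs(t.mean() - 2.0) <= 3 * 2.0 / np.sqrt(100_000)

    def test_matches_closed_form_survivor(self, ckd_rates):
        t = sample_absorption_times(ckd_rates, 100_000, seed=6)
        for point in (6.0, 12.0, 24.0):
            S = survivor(ckd_rates, point)
            se = np.sqrt(S * (1 - S) / t.size)
            assert abs((t > point).mean() - S) <= 3 * se

    def test_seed_determinism(self, ckd_rates):
        a = sample_absorption_times(ckd_rates, 500, seed=9)
        b = sample_absorption_times(ckd_rates, 500, seed=9)
        np.testing.assert_array_equal(a, b)


class TestCanonicalForm:
    def test_sorts_rates_and_preserves_distribution(self, parameter_battery):
        t = np.linspace(0.05, 30.0, 12)
        for params in parameter_battery[::2]:
            can = canonical_form(params)
            sigma = can.total_rates
            assert np.all(np.diff(sigma) <= 1e-9 * sigma[:-1])
            np.testing.assert_allclose(
                pdf(can, t), pdf(params, t), rtol=1e-7, atol=1e-12
            )


@st.composite
def coxian_params(draw):
    n = draw(st.integers(min_value=1, max_value=4))
    lams = [draw(st.floats(0.05, 4.0)) for _ in range(n - 1)] + [0.0]
    mus = [draw(st.floats(0.05, 4.0)) for _ in range(n)]
    return CoxianParameters(np.array(lams), np.array(mus))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(coxian_params())
def test_distribution_invariants(params):
    """pi sums to 1, survivor decreases from 1, density is nonnegative and
    the hazard is a convex combination of the absorption rates."""
    pis = absorption_probabilities(params).pis
    assert np.all(pis >= 0) and abs(pis.sum() - 1.0) < 1e-12
    t = np.linspace(0.0, 15.0, 25)
    S = survivor(params, t)
    assert S[0] == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.diff(S) <= 1e-10)
    f = pdf(params, t)
    assert np.all(np.asarray(f) >= -1e-12)
    h = np.atleast_1d(hazard(params, t[1:]))
    assert np.all(h >= params.mus.min() - 1e-8)
    assert np.all(h <= params.mus.max() + 1e-8)
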