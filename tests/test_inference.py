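import numpy as np
import pytest
from scipy.special import gammaln

from mshaz.hazard import compute_hazard
from mshaz.inference import (IncidenceTable, expected_cases, fit,
                             generate_synthetic_incidence, loglik,
                             numerical_rank, overdispersion_scale,
                             sensitivity_matrix)
from mshaz.model import (armitage_doll_model, parameter_handles,
                         two_mutation_model)
from mshaz.simulate import empirical_cumulative_incidence, simulate_cohort


def _constant_hazard_spec(h=1e-4):
    # k=1: hazard is exactly X * M
    return armitage_doll_model(1, 1e7, [h / 1e7])


class TestExpectedCases:
    def test_zero_hazard_spec(self, unreachable_spec):
        assert expected_cases(unreachable_spec, (50.0, 55.0), 1e5) == 0.0

    def test_constant_hazard_band(self):
        mu = expected_cases(_constant_hazard_spec(1e-4), (50.0, 55.0), 1e5)
        assert mu == pytest.approx(10.0, rel=1e-8)

    def test_expected_counts_match_simulated_bins(self, tsce_spec):
        # rare-disease bridge: person-years * band-average hazard should
        # reproduce binned Monte-Carlo incidence
        res = simulate_cohort(tsce_spec, 20_000, 90.0, seed=17)
        edges = np.arange(0.0, 91.0, 15.0)
        F = empirical_cumulative_incidence(res, edges)
        counts_mc = np.diff(F) * res.n
        py = res.n * np.diff(edges)   # approx: everyone at risk throughout
        mu = expected_cases(tsce_spec,
                            IncidenceTable(edges[:-1], edges[1:],
                                           np.zeros(len(edges) - 1), py),
                            py)
        assert np.all(np.abs(counts_mc - mu) <= 3 * np.sqrt(mu + 1.0) + 3)


class TestLogLikelihood:
    def test_all_zero_cases_reduces_to_minus_total_expectation(self):
        spec = _constant_hazard_spec(1e-6)
        table = IncidenceTable(np.array([0.0, 5.0]), np.array([5.0, 10.0]),
                               np.zeros(2), np.array([1e4, 1e4]))
        mu = expected_cases(spec, table, table.person_years)
        assert loglik(spec, table) == pytest.approx(-np.sum(mu), rel=1e-10)

    def test_impossible_data_scores_minus_infinity(self, unreachable_spec):
        table = IncidenceTable(np.array([0.0]), np.array([10.0]),
                               np.array([3]), np.array([1e4]))
        assert loglik(unreachable_spec, table) == -np.inf

    def test_doubling_exposure_doubles_loglik_differences(self):
        a = _constant_hazard_spec(1e-4)
        b = _constant_hazard_spec(2e-4)
        lo = np.arange(0.0, 90.0, 5.0)
        table = generate_synthetic_incidence(a, person_years=1e6, seed=4)
        double = IncidenceTable(lo, lo + 5.0, table.cases * 2,
                                table.person_years * 2)
        d1 = loglik(a, table) - loglik(b, table)
        d2 = loglik(a, double) - loglik(b, double)
        assert d2 == pytest.approx(2 * d1, rel=1e-10)

    def test_deviance_against_saturated_model_is_chi_square_scale(self):
        spec = armitage_doll_model(2, 1e7, [1e-6, 1e-6])
        devs = []
        for seed in range(50):
            t = generate_synthetic_incidence(spec, person_years=1e6,
                                             seed=seed)
            mu = expected_cases(spec, t, t.person_years)
            sat = np.sum(np.where(t.cases > 0,
                                  t.cases * np.log(t.cases) - t.cases, 0.0)
                         - gammaln(t.cases + 1.0))
            devs.append(2.0 * (sat - loglik(spec, t)))
        dof = t.n_bands
        assert abs(np.mean(devs) - dof) < 3.0 * np.sqrt(2.0 * dof)


class TestTableValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(age_low=[0, 4], age_high=[5, 10], cases=[1, 1],
             person_years=[1e3, 1e3]),          # overlap
        dict(age_low=[0, 5], age_high=[5, 10], cases=[1, -1],
             person_years=[1e3, 1e3]),          # negative cases
        dict(age_low=[0, 5], age_high=[5, 10], cases=[1, 1],
             person_years=[1e3, 0.0]),          # nonpositive PY
        dict(age_low=[0], age_high=[0], cases=[1], person_years=[1e3]),
    ])
    def test_invalid_tables_rejected(self, kwargs):
        with pytest.raises(ValueError):
            IncidenceTable(**{k: np.asarray(v) for k, v in kwargs.items()})


class TestFit:
    def test_empty_free_set_echoes_input_loglik(self, tsce_spec):
        table = generate_synthetic_incidence(tsce_spec, seed=1)
        res = fit(tsce_spec, table, [])
        assert res.n_params == 0
        assert res.loglik == pytest.approx(loglik(tsce_spec, table))

    def test_identifiable_product_recovered(self):
        gen = armitage_doll_model(2, 1e7, [1e-6, 1e-6])
        table = generate_synthetic_incidence(gen, person_years=1e8, seed=2)
        start = armitage_doll_model(2, 1e7, [3e-7, 1e-6])
        res = fit(start, table, ["M0"], n_starts=4, seed=0)
        product = 1e7 * res.estimates["M0"] * 1e-6
        assert product == pytest.approx(1e-5, rel=0.01)

    def test_misspecified_stage_count_fits_worse_than_generator(self):
        gen = armitage_doll_model(3, 1e7, [1e-6, 1e-5, 1e-5])
        wrong = armitage_doll_model(2, 1e7, [1e-6, 1e-5])
        for seed in range(20):
            table = generate_synthetic_incidence(gen, person_years=1e8,
                                                 seed=100 + seed)
            res = fit(wrong, table, ["M0"], n_starts=2, seed=seed)
            assert res.converged or np.isfinite(res.loglik)
            assert res.loglik < loglik(gen, table)

    def test_nested_models_give_nonnegative_lr_statistic(self):
        gen = armitage_doll_model(2, 1e7, [1e-6, 1e-6])
        table = generate_synthetic_incidence(gen, person_years=1e6, seed=9)
        start = armitage_doll_model(2, 1e7, [5e-7, 2e-6])
        small = fit(start, table, ["M0"], n_starts=2, seed=0)
        big = fit(start, table, ["M0", "M1"], n_starts=4, seed=0)
        assert 2.0 * (big.loglik - small.loglik) >= -1e-6


class TestIdentifiability:
    def test_pool_size_and_initiation_rate_are_one_combination(self):
        spec = _constant_hazard_spec(1e-4)
        grid = np.arange(10.0, 90.0, 10.0)
        S = sensitivity_matrix(spec, ["X", "M0"], grid)
        np.testing.assert_allclose(S[:, 0], S[:, 1], rtol=1e-6)
        assert numerical_rank(S) == 1

    def test_rank_of_identity_and_zero_matrices(self):
        assert numerical_rank(np.eye(3)) == 3
        assert numerical_rank(np.zeros((4, 3))) == 0

    def test_two_stage_rank_insensitive_to_grid_and_threshold(
            self, ident_spec):
        handles = ["X", "M0", "M1", "G1", "D1"]
        S1 = sensitivity_matrix(ident_spec, handles,
                                np.arange(1.0, 101.0, 1.0))
        S2 = sensitivity_matrix(ident_spec, handles,
                                np.arange(1.0, 101.0, 0.5))
        for tol in [1e-8, 1e-7, 1e-6, 1e-5, 1e-4]:
            assert numerical_rank(S1, tol) == 3
            assert numerical_rank(S2, tol) == 3

    def test_finite_difference_step_invariance(self, ident_spec):
        grid = np.arange(5.0, 101.0, 5.0)
        S1 = sensitivity_matrix(ident_spec, ["M1", "G1"], grid,
                                rel_step=1e-4)
        S2 = sensitivity_matrix(ident_spec, ["M1", "G1"], grid,
                                rel_step=2e-4)
        np.testing.assert_allclose(S1, S2, rtol=1e-5, atol=1e-12)

    @pytest.mark.parametrize("name", ["gi-1", "gi-2"])
    def test_gi_models_have_at_least_r_plus_1_redundancies(self, name,
                                                           battery_specs):
        b = next(x for x in battery_specs if x.name == name)
        params = parameter_handles(b.spec)
        S = sensitivity_matrix(b.spec, params, np.arange(2.0, 101.0, 2.0))
        assert numerical_rank(S) <= len(params) - (b.spec.r + 1)


class TestSyntheticTables:
    def test_zero_hazard_gives_all_zero_cases(self, unreachable_spec):
        table = generate_synthetic_incidence(unreachable_spec, seed=3)
        assert table.cases.sum() == 0

    def test_reproducible_given_seed(self, tsce_spec):
        a = generate_synthetic_incidence(tsce_spec, seed=12)
        b = generate_synthetic_incidence(tsce_spec, seed=12)
        np.testing.assert_array_equal(a.cases, b.cases)

    def test_pure_poisson_tables_have_unit_overdispersion_scale(self):
        spec = _constant_hazard_spec(1e-4)
        scales = [overdispersion_scale(
            spec, generate_synthetic_incidence(spec, person_years=1e6,
                                               seed=s)) for s in range(30)]
        # Pearson X^2/dof ~ chi2_18/18 for Poisson data: mean 1, sd ~0.33
        assert abs(np.mean(scales) - 1.0) < 3 * 0.333 / np.sqrt(30)

    def test_poisson_mean_calibration(self):
        # constant hazard 1e-4/yr at PY 1e6 per band: mean cases 100/band
        spec = _constant_hazard_spec(1e-4)
        means = np.mean([generate_synthetic_incidence(
            spec, person_years=1e6, seed=s).cases for s in range(200)],
            axis=0)
        se = 10.0 / np.sqrt(200)
        assert np.all(np.abs(means - 100.0) < 3 * se)
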