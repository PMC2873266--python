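import dataclasses

import numpy as np
import pytest

from mshaz.closed_forms import ArmitageDollParams, armitage_doll_hazard
from mshaz.hazard import (PGFState, backward_rhs, backward_state,
                          compute_hazard, excess_risk_decay,
                          perturbation_jump)
from mshaz.model import (armitage_doll_model, generalized_mvk_model,
                         gi_model, two_mutation_model, validate_model)


class TestClosedFormLimits:
    def test_single_stage_hazard_is_pool_times_rate(self):
        spec = armitage_doll_model(1, 1e7, [1e-7])
        curve = compute_hazard(spec, np.array([0.0, 10.0, 50.0]))
        np.testing.assert_allclose(curve.hazard, 1.0, rtol=1e-10)
        np.testing.assert_allclose(curve.cumulative, [0.0, 10.0, 50.0],
                                   rtol=1e-8)

    def test_unreachable_malignancy_gives_zero_hazard(self, unreachable_spec):
        curve = compute_hazard(unreachable_spec, np.arange(0.0, 101.0, 10.0))
        np.testing.assert_array_equal(curve.hazard, 0.0)
        np.testing.assert_array_equal(curve.cumulative, 0.0)

    def test_two_stage_small_rate_regime_matches_printed_constant(self):
        spec = armitage_doll_model(2, 1e7, [1e-6, 1e-6])
        h50 = compute_hazard(spec, np.array([50.0])).hazard[0]
        assert h50 == pytest.approx(5.0e-4, rel=0.01)

    @pytest.mark.parametrize("k", [3, 5])
    def test_small_rate_hazard_matches_power_law_formula(self, k):
        spec = armitage_doll_model(k, 1e7, [1e-8] * k)
        ages = np.arange(20.0, 80.5, 2.0)
        curve = compute_hazard(spec, ages)
        ref = armitage_doll_hazard(ArmitageDollParams(k, 1e7, (1e-8,) * k),
                                   ages)
        np.testing.assert_allclose(curve.hazard, ref, rtol=5e-3)


class TestEngineInternalConsistency:
    def test_backward_equals_homogeneous_on_constant_specs(self, tsce_spec):
        grid = np.array([5.0, 25.0, 60.0, 100.0])
        hom = compute_hazard(tsce_spec, grid, method="homogeneous")
        bwd = compute_hazard(tsce_spec, grid, method="backward")
        np.testing.assert_allclose(bwd.hazard, hom.hazard, rtol=1e-6)
        np.testing.assert_allclose(bwd.cumulative, hom.cumulative,
                                   rtol=1e-6)

    def test_cumulative_hazard_nondecreasing_and_survival_in_unit_interval(
            self, battery_specs, coarse_grid):
        for b in battery_specs:
            curve = compute_hazard(b.spec, coarse_grid)
            assert np.all(np.diff(curve.cumulative) >= 0), b.name
            assert np.all(curve.hazard >= 0), b.name
            s = curve.survival
            assert s[0] == 1.0 and np.all((s > 0) & (s <= 1)), b.name

    def test_tolerance_invariance(self, tsce_spec):
        grid = np.array([20.0, 50.0, 90.0])
        h1 = compute_hazard(tsce_spec, grid, rtol=1e-8).hazard
        h2 = compute_hazard(tsce_spec, grid, rtol=1e-10).hazard
        np.testing.assert_allclose(h1, h2, rtol=1e-6)

    def test_vacuous_destabilization_reduces_to_r0_model(self):
        base = two_mutation_model(1e7, 1e-7, 1e-6, 0.1, 0.09)
        padded = gi_model(
            k=2, r=1, m=(1,), X=1e7,
            M={(0, 0, 0): 1e-7, (1, 0, 0): 1e-6},
            A={},                          # destabilization unreachable
            G={(1, 0, 0): 0.1, (0, 1, 1): 0.3, (1, 1, 1): 0.3},
            D={(1, 0, 0): 0.09, (0, 1, 1): 0.1, (1, 1, 1): 0.1})
        grid = np.arange(0.0, 110.5, 5.0)
        h0 = compute_hazard(base, grid).hazard
        h1 = compute_hazard(padded, grid).hazard
        assert np.max(np.abs(h1 - h0)) < 1e-10

    def test_latency_shifts_the_curve(self, tsce_spec):
        lagged = validate_model(dataclasses.replace(tsce_spec, latency=3.5))
        grid = np.arange(0.0, 80.5, 0.5)
        base = compute_hazard(tsce_spec, grid)
        shifted = compute_hazard(lagged, grid)
        assert np.all(shifted.hazard[grid < 3.5] == 0.0)
        np.testing.assert_allclose(shifted.hazard[grid >= 3.5],
                                   base.hazard[grid <= 80.0 - 3.5 + 1e-9],
                                   rtol=1e-7)

    def test_two_populations_at_birth_raise_early_hazard(self):
        base = two_mutation_model(1e7, 1e-7, 1e-5, 0.05, 0.06)
        seeded = two_mutation_model(
            1e7, 1e-7, 1e-5, 0.05, 0.06,
            initial_fractions={(0, 0, 0): 1 - 1e-5, (1, 0, 0): 1e-5})
        grid = np.array([1.0, 5.0, 20.0])
        h_base = compute_hazard(base, grid).hazard
        h_seed = compute_hazard(seeded, grid).hazard
        assert np.all(h_seed > h_base)
        # 100 initiated cells at birth, conversion 1e-5/cell-year
        assert h_seed[0] == pytest.approx(100 * 1e-5, rel=0.1)


class TestBackwardRhs:
    def test_s_beyond_t_rejected(self, tsce_spec):
        state = PGFState(phi=np.ones(2), dphi_dt=np.zeros(2), g=0.0, K=0.0)
        with pytest.raises(ValueError):
            backward_rhs(tsce_spec, 10.0, 11.0, state)

    def test_terminal_slope_is_last_stage_mutation_rate(self, tsce_spec):
        # at s = t every phi is 1; the only leak is conversion of the
        # last-stage compartment, so dphi/ds there equals M(1)
        state = PGFState(phi=np.ones(2),
                         dphi_dt=np.array([0.0, -1e-6]), g=0.0, K=0.0)
        deriv = backward_rhs(tsce_spec, 50.0, 50.0, state)
        assert deriv.phi[0] == pytest.approx(0.0, abs=1e-30)
        assert deriv.phi[1] == pytest.approx(1e-6, rel=1e-12)

    def test_boundary_state_invariants(self, tsce_spec):
        state = backward_state(tsce_spec, 60.0, s=60.0)
        np.testing.assert_allclose(state.phi, 1.0)
        assert state.K == 0.0 and state.g == 0.0

    def test_probabilities_stay_in_unit_interval(self, ident_spec):
        state = backward_state(ident_spec, 80.0, s=0.0)
        assert np.all((state.phi >= 0.0) & (state.phi <= 1.0))
        assert np.all(state.dphi_dt <= 0.0)


class TestPerturbationResponse:
    def test_early_stage_perturbation_is_silent_for_three_stages(self):
        spec = generalized_mvk_model(3, 1e7, [1e-7, 1e-5, 1e-6],
                                     [0.1, 0.1], [0.05, 0.05])
        jump = perturbation_jump(spec, "M0", 40.0, 10.0)
        assert jump.relative < 1e-6

    def test_last_stage_mutation_step_scales_the_hazard(self):
        spec = generalized_mvk_model(3, 1e7, [1e-7, 1e-5, 1e-6],
                                     [0.1, 0.1], [0.05, 0.05])
        jump = perturbation_jump(spec, "M2", 40.0, 10.0)
        assert jump.relative > 0.1
        assert jump.relative == pytest.approx(9.0, rel=0.05)

    def test_every_two_stage_parameter_responds_instantly(self):
        spec = two_mutation_model(1e7, 1e-7, 1e-6, 0.1, 0.05)
        for handle in ["X", "M0", "M1", "G1", "D1"]:
            jump = perturbation_jump(spec, handle, 40.0, 10.0)
            assert jump.relative > 1e-6, handle

    def test_identity_perturbation_gives_zero_excess(self, tsce_spec):
        er = excess_risk_decay(tsce_spec, "M0", (20.0, 25.0), 1.0, 60.0)
        np.testing.assert_array_equal(er.excess, 0.0)

    def test_mid_stage_window_excess_is_continuous_at_window_edges(self):
        # for k=3 a transient G(1) change must not step the hazard at the
        # window edges: the response builds through the intermediate pool
        spec = generalized_mvk_model(3, 1e7, [1e-7, 1e-5, 1e-4],
                                     [0.05, 0.05], [0.17, 0.17])
        grid = np.array([19.999, 20.001, 24.999, 25.001, 30.0])
        er = excess_risk_decay(spec, "G1", (20.0, 25.0), 10.0, 30.0,
                               t_grid=grid)
        ex = er.excess
        peak = np.abs(ex).max()
        assert abs(ex[1] - ex[0]) < 0.01 * peak
        assert abs(ex[3] - ex[2]) < 0.01 * peak
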