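"""Co-culture ODE system: rate blocks, right-hand side, integration."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad

from redoxlan import (
    LanParameters,
    RateBlock,
    Trajectory,
    conservation_report,
    default_truth,
    rate_coefficient,
    rhs,
    simulate,
)
from redoxlan.errors import ParameterDomainError


class TestRateCoefficient:
    def test_constant_when_denominators_equal(self):
        block = RateBlock(0.6, 3.0, 3.0, 20.0, 2.0)
        t = np.linspace(0, 200, 50)
        assert np.allclose(rate_coefficient(block, t), 0.2)

    def test_early_value_at_zero(self):
        block = RateBlock(1.2, 4.0, 40.0, 30.0, 3.0)
        assert rate_coefficient(block, 0.0) == pytest.approx(0.3)

    def test_late_asymptote(self):
        block = RateBlock(1.2, 4.0, 40.0, 30.0, 3.0)
        assert rate_coefficient(block, 1e6 * 30.0) == pytest.approx(
            1.2 / 40.0, rel=1e-6
        )

    def test_positive_denominators_required(self):
        with pytest.raises(ParameterDomainError):
            RateBlock(1.0, -1.0, 2.0, 10.0, 2.0)
        with pytest.raises(ParameterDomainError):
            RateBlock(1.0, 1.0, 0.0, 10.0, 2.0)


class TestRhs:
    def test_empty_culture_is_stationary(self, lan_truth):
        d = rhs((0.0, 0.0, 0.5), 10.0, lan_truth)
        assert d == (0.0, 0.0, 0.0)

    def test_no_fe2_stalls_reducer_growth(self, lan_truth):
        d = rhs((0.5, 0.5, 0.0), 10.0, lan_truth)
        assert d[0] == 0.0
        assert d[1] > 0.0  # oxidizer still grows on the full Fe3+ pool

    def test_full_fe2_stalls_oxidizer_growth(self, lan_truth):
        d = rhs((0.5, 0.5, lan_truth.fe_total), 10.0, lan_truth)
        assert d[1] == 0.0
        assert d[0] > 0.0

    def test_nonfinite_state_identified(self, lan_truth):
        with pytest.raises(ValueError, match="cells_R"):
            rhs((0.1, np.nan, 0.5), 10.0, lan_truth)


class TestSimulate:
    def test_frozen_redox_pool(self, lan_truth):
        frozen = dataclasses.replace(
            lan_truth,
            ferate_S=dataclasses.replace(lan_truth.ferate_S, amplitude=0.0),
            ferate_R=dataclasses.replace(lan_truth.ferate_R, amplitude=0.0),
            fe2_0=0.5,
        )
        traj = simulate(frozen, t_max=96.0)
        assert np.allclose(traj.fe2, 0.5, atol=1e-8)

    def test_default_peak_near_reported_value(self, lan_truth):
        traj = simulate(lan_truth, t_max=96.0)
        assert traj.fe2.max() == pytest.approx(0.76, abs=0.01)

    def test_refinement_oracle(self, lan_truth):
        grid = np.linspace(0, 96, 97)
        coarse = simulate(lan_truth, 96.0, grid, rtol=1e-6, atol=1e-8)
        fine = simulate(lan_truth, 96.0, grid, rtol=1e-9, atol=1e-12)
        for name in ("cells_S", "cells_R", "fe2"):
            assert np.max(np.abs(getattr(coarse, name) - getattr(fine, name))) < 1e-5

    def test_closed_form_integral_in_frozen_growth_limit(self, lan_truth):
        # no growth, no consumption: fe2(t) = cells_S0 * int_0^t f_S(s) ds
        frozen = dataclasses.replace(
            lan_truth,
            growth_S=dataclasses.replace(lan_truth.growth_S, amplitude=0.0),
            growth_R=dataclasses.replace(lan_truth.growth_R, amplitude=0.0),
            ferate_R=dataclasses.replace(lan_truth.ferate_R, amplitude=0.0),
        )
        grid = np.array([0.0, 6.0, 12.0, 24.0, 48.0])
        traj = simulate(frozen, 48.0, grid)
        for t_end, fe2_val in zip(grid[1:], traj.fe2[1:]):
            expected = frozen.cells_S0 * quad(
                lambda s: rate_coefficient(frozen.ferate_S, s), 0, t_end,
                epsabs=1e-12, epsrel=1e-12,
            )[0]
            assert fe2_val == pytest.approx(expected, abs=1e-6)

    def test_densities_nonnegative_and_monotone(self, lan_truth):
        traj = simulate(lan_truth, t_max=96.0)
        assert np.all(traj.cells_S >= 0) and np.all(traj.cells_R >= 0)
        assert np.all(np.diff(traj.cells_S) >= -1e-12)
        assert np.all(np.diff(traj.cells_R) >= -1e-12)

    def test_monotone_growth_on_random_admissible_sets(self, rng):
        for _ in range(5):
            params = LanParameters(
                growth_S=RateBlock(rng.uniform(0.05, 0.15), 1.0,
                                   rng.uniform(20, 100), rng.uniform(80, 140),
                                   rng.uniform(3, 6)),
                growth_R=RateBlock(rng.uniform(0.02, 0.05), 1.0,
                                   rng.uniform(10, 40), rng.uniform(80, 140),
                                   rng.uniform(3, 6)),
                ferate_S=RateBlock(rng.uniform(0.5, 1.2), 1.0,
                                   rng.uniform(500, 3000), rng.uniform(90, 120), 6.0),
                ferate_R=RateBlock(rng.uniform(0.01, 0.03), 30.0, 1.0,
                                   rng.uniform(18, 30), 5.0),
            )
            traj = simulate(params, t_max=96.0)
            if traj.clamp_warning:
                # fe2 left [0, fe_total]: the monotonicity precondition fails
                continue
            assert np.all(np.diff(traj.cells_S) >= -1e-10)
            assert np.all(np.diff(traj.cells_R) >= -1e-10)

    def test_rise_then_fall_shape(self, lan_truth):
        traj = simulate(lan_truth, t_max=96.0)
        i_peak = int(np.argmax(traj.fe2))
        assert 0 < i_peak < len(traj.times) - 1
        # single interior maximum: nondecreasing before, nonincreasing after
        assert np.all(np.diff(traj.fe2[: i_peak + 1]) >= -1e-9)
        assert np.all(np.diff(traj.fe2[i_peak:]) <= 1e-9)
        assert traj.fe2[0] == 0.0
        assert traj.fe2[-1] < traj.fe2[i_peak]

    def test_output_grid_validation(self, lan_truth):
        with pytest.raises(ValueError):
            simulate(lan_truth, 96.0, np.array([0.0, 10.0, 5.0]))
        with pytest.raises(ValueError):
            simulate(lan_truth, 96.0, np.array([0.0, 120.0]))


class TestConservation:
    def test_simulated_trajectory_conserves_iron(self, lan_truth):
        traj = simulate(lan_truth, t_max=96.0)
        assert conservation_report(traj, lan_truth.fe_total) == 0.0

    def test_corrupted_channel_detected(self):
        t = np.linspace(0, 10, 5)
        fe2 = np.linspace(0, 1, 5)
        fe3 = 2.0 - fe2
        fe3[2] += 0.1
        traj = Trajectory(t, np.ones(5), np.ones(5), fe2, fe3, fe_total=2.0)
        assert conservation_report(traj, 2.0) == pytest.approx(0.1)

    def test_parameter_invariants(self):
        block = RateBlock(1.0, 1.0, 2.0, 10.0, 2.0)
        with pytest.raises(ParameterDomainError):
            LanParameters(block, block, block, block, fe_total=-1.0)
        with pytest.raises(ParameterDomainError):
            LanParameters(block, block, block, block, fe2_0=3.0)
        with pytest.raises(ParameterDomainError):
            LanParameters(block, block, block, block, cells_S0=-0.1)
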