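"""Rate laws, closures, integration, equilibrium and derived quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import radsorb as rs
from radsorb.errors import (
    MissingParameterError,
    NoDiffusivityRelationError,
    SingularRateError,
)
from radsorb.models import KineticModel as KM


def cond_of(Kd, c0=1e-11, r=1000.0, q0=0.0):
    return rs.ExperimentConditions(c0=c0, Kd=Kd, q0=q0, r=r)


class TestEquilibrium:
    def test_closed_form_fraction_for_fresh_sorbent(self):
        # Kd/(Kd + r) with the mean nHAp distribution coefficient
        eq = rs.equilibrium_state(cond_of(Kd=2.04e4, c0=1.02e-11))
        assert eq.fraction_sorbed == pytest.approx(0.95327, abs=1e-4)

    def test_zero_kd_sorbs_nothing(self):
        eq = rs.equilibrium_state(cond_of(Kd=0.0, c0=3e-11))
        assert eq.fraction_sorbed == 0.0
        assert eq.c_eq == pytest.approx(3e-11)

    def test_kd_equal_r_splits_evenly(self):
        eq = rs.equilibrium_state(cond_of(Kd=1000.0))
        assert eq.fraction_sorbed == pytest.approx(0.5)

    def test_isotherm_and_mass_balance_hold_at_fixed_point(self):
        cond = cond_of(Kd=5.5e3, c0=2e-11, q0=1e-9)
        eq = rs.equilibrium_state(cond)
        assert eq.q_eq == pytest.approx(cond.Kd * eq.c_eq, rel=1e-12)
        assert eq.c_eq + eq.q_eq / cond.r == pytest.approx(cond.total, rel=1e-12)


class TestRate:
    def test_zero_driving_force_at_equilibrium(self):
        cond = cond_of(Kd=2.04e4)
        r = rs.rate(KM.DM, cond.q_eq, cond, rs.RateCoefficient(KM.DM, 0.5))
        assert r == pytest.approx(0.0, abs=1e-30)

    def test_reacted_layer_dimensionless_rate_at_half_saturation(self):
        # u = 0.5, Kd/r = 15.5, kappa = 7.53e-4 /min -> du/dt ~ 0.313 /min
        cond = cond_of(Kd=1.55e4)
        q = 0.5 * cond.q_eq
        dq = rs.rate(KM.RLD, q, cond, rs.RateCoefficient(KM.RLD, 0.753))
        assert dq / cond.q_eq == pytest.approx(0.3136, abs=2e-3)

    @pytest.mark.parametrize("model", [KM.RLD, KM.ID])
    def test_shell_models_singular_at_zero_loading(self, model):
        cond = cond_of(Kd=1e4)
        with pytest.raises(SingularRateError):
            rs.rate(model, 0.0, cond, rs.RateCoefficient(model, 0.5))

    def test_gel_diffusion_singular_at_initial_loading(self):
        cond = cond_of(Kd=1e4, q0=1e-9)
        with pytest.raises(SingularRateError):
            rs.rate(KM.GD, 1e-9, cond, rs.RateCoefficient(KM.GD, 0.5))

    def test_model_coefficient_mismatch_rejected(self):
        cond = cond_of(Kd=1e4)
        with pytest.raises(ValueError):
            rs.rate(KM.DM, 1e-9, cond, rs.RateCoefficient(KM.RLD, 0.5))

    @settings(max_examples=60, deadline=None)
    @given(
        u=st.floats(0.01, 1.99),
        kd_over_r=st.floats(0.5, 200.0),
        model=st.sampled_from(list(KM)),
    )
    def test_rate_sign_follows_distance_to_equilibrium(self, u, kd_over_r, model):
        """Reversibility: uptake below q_eq, desorption above it."""
        cond = cond_of(Kd=kd_over_r * 1000.0)
        q = u * cond.q_eq
        dq = rs.rate(model, q, cond, rs.RateCoefficient(model, 0.3))
        if abs(u - 1.0) < 1e-9:
            assert dq == pytest.approx(0.0, abs=1e-25)
        elif u < 1.0:
            assert dq > 0
        else:
            assert dq < 0


class TestIntegrate:
    def test_initial_point_is_exactly_q0(self, any_model, schedule):
        cond = cond_of(Kd=2.04e4, c0=1.02e-11)
        traj = rs.integrate(any_model, cond, rs.RateCoefficient(any_model, 0.5), schedule)
        assert traj.q[0] == cond.q0

    def test_mass_transfer_matches_exponential_solution(self, schedule):
        cond = cond_of(Kd=2.04e4, c0=1.02e-11)
        coeff = rs.RateCoefficient(KM.DM, 5.03e-1)
        traj = rs.integrate(KM.DM, cond, coeff, schedule)
        kappa = coeff.K_printed / cond.r
        q_exact = cond.q_eq * (1.0 - np.exp(-kappa * cond.A * schedule))
        np.testing.assert_allclose(traj.q[1:], q_exact[1:], rtol=1e-6)

    def test_mass_balance_everywhere(self, any_model, schedule):
        cond = cond_of(Kd=2.04e4, c0=1.02e-11)
        traj = rs.integrate(any_model, cond, rs.RateCoefficient(any_model, 0.5), schedule)
        total = traj.c + traj.q / cond.r
        np.testing.assert_allclose(total, cond.total, rtol=1e-8)

    def test_monotone_rise_toward_common_equilibrium(self, any_model):
        cond = cond_of(Kd=2.04e4, c0=1.02e-11)
        coeff = rs.RateCoefficient(any_model, 0.5)
        t_half = rs.sorption_half_life(any_model, cond, coeff)
        times = np.geomspace(1e-3, 1e5 * t_half, 60)
        traj = rs.integrate(any_model, cond, coeff, times)
        assert np.all(np.diff(traj.q) >= 0)
        assert traj.q[-1] == pytest.approx(cond.q_eq, rel=1e-4)

    def test_reacted_layer_exceeds_90pct_within_one_hour(self, nhap, ntio2):
        for sf in (nhap, ntio2):
            traj = rs.integrate(KM.RLD, sf.mean.cond, sf.mean.K_RLD, np.array([60.0]))
            assert traj.fraction_pct[0] > 90.0

    def test_zero_coefficient_keeps_initial_state(self, schedule):
        cond = cond_of(Kd=2.04e4)
        traj = rs.integrate(KM.RLD, cond, rs.RateCoefficient(KM.RLD, 0.0), schedule)
        assert np.all(traj.q == cond.q0)

    def test_invalid_grid_rejected(self):
        cond = cond_of(Kd=1e4)
        with pytest.raises(ValueError):
            rs.integrate(KM.DM, cond, rs.RateCoefficient(KM.DM, 0.5), [3.0, 2.0])


class TestHalfLife:
    def test_mass_transfer_closed_form(self):
        cond = cond_of(Kd=2.04e4, c0=1.02e-11)
        coeff = rs.RateCoefficient(KM.DM, 5.03e-1)
        t = rs.sorption_half_life(KM.DM, cond, coeff)
        kappa = coeff.K_printed / cond.r
        assert t == pytest.approx(math.log(2) / (kappa * cond.A), rel=1e-6)

    def test_doubling_coefficient_halves_dm_half_life(self):
        cond = cond_of(Kd=2.04e4)
        t1 = rs.sorption_half_life(KM.DM, cond, rs.RateCoefficient(KM.DM, 0.25))
        t2 = rs.sorption_half_life(KM.DM, cond, rs.RateCoefficient(KM.DM, 0.50))
        assert t2 == pytest.approx(t1 / 2, rel=1e-6)

    def test_doubling_coefficient_strictly_shortens_all_models(self, any_model):
        cond = cond_of(Kd=2.04e4)
        t1 = rs.sorption_half_life(any_model, cond, rs.RateCoefficient(any_model, 0.25))
        t2 = rs.sorption_half_life(any_model, cond, rs.RateCoefficient(any_model, 0.50))
        assert t2 < t1

    def test_replicate_mean_half_life_matches_reported(self, nhap, ntio2):
        for sf, (ref, sig) in ((nhap, (0.75, 0.18)), (ntio2, (0.51, 0.32))):
            ts = [
                rs.sorption_half_life(KM.RLD, e.cond, e.K_RLD) for e in sf.experiments
            ]
            assert abs(np.mean(ts) - ref) <= sig

    @pytest.mark.parametrize("model", [KM.RLD, KM.ID, KM.GD])
    def test_start_regularization_insensitivity(self, model):
        """Halving the ε-offset moves t_half by far less than 0.1%."""
        cond = cond_of(Kd=2.04e4, c0=1.02e-11)
        coeff = rs.RateCoefficient(model, 0.5)
        t1 = rs.sorption_half_life(model, cond, coeff, epsilon=1e-8)
        t2 = rs.sorption_half_life(model, cond, coeff, epsilon=5e-9)
        assert abs(t2 - t1) / t1 < 1e-3

    def test_undefined_at_equilibrium_start(self):
        cond = cond_of(Kd=0.0)
        with pytest.raises(ValueError):
            rs.sorption_half_life(KM.DM, cond, rs.RateCoefficient(KM.DM, 0.5))


class TestDiffusivity:
    def test_reacted_layer_inversion_nhap(self, nhap):
        D = rs.coefficient_to_diffusivity(KM.RLD, 5.03e-1, nhap.props)
        assert D == pytest.approx(2.50e-12, rel=0.02)

    def test_reacted_layer_inversion_ntio2(self, ntio2):
        # the specific-mass range 3.90-4.30 brackets the reported value
        lo = rs.coefficient_to_diffusivity(KM.RLD, 4.01e-2, ntio2.props, h_s=3.90)
        hi = rs.coefficient_to_diffusivity(KM.RLD, 4.01e-2, ntio2.props, h_s=4.30)
        assert lo == pytest.approx(1.464e-14, rel=1e-3)
        assert hi == pytest.approx(1.615e-14, rel=1e-3)
        assert rs.coefficient_to_diffusivity(KM.RLD, 4.01e-2, ntio2.props) == (
            pytest.approx(1.60e-14, rel=0.10)
        )

    @pytest.mark.parametrize("model", [KM.RLD, KM.ID, KM.GD, KM.FD])
    def test_round_trip_is_identity(self, model, nhap):
        props = rs.SorbentProperties(
            name="x",
            specific_surface_area=1.0,
            equivalent_diameter_nm=21.7,
            R_eff_cm=21.7e-7,
            specific_mass_range=(3.14, 3.21),
            film_thickness_delta_cm=1e-6,
        )
        K = 0.37
        D = rs.coefficient_to_diffusivity(model, K, props)
        assert rs.diffusivity_to_coefficient(model, D, props) == pytest.approx(K, rel=1e-12)

    @pytest.mark.parametrize("model", [KM.DM, KM.CR])
    def test_models_without_diffusivity_relation(self, model, nhap):
        with pytest.raises(NoDiffusivityRelationError):
            rs.coefficient_to_diffusivity(model, 0.5, nhap.props)

    def test_film_diffusion_needs_film_thickness(self, nhap):
        with pytest.raises(MissingParameterError):
            rs.coefficient_to_diffusivity(KM.FD, 0.5, nhap.props)
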