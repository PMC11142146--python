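"""Core dynamics: damage function, vector field, injections, integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trtsim.model import (DoseSchedule, ModelState, apply_injection,
                          radiation_damage, rhs, simulate)
from trtsim.params import ModelParameters


class TestRadiationDamage:
    def test_zero_state_gives_zero(self, basic):
        state = ModelState(N=0.0, f_FN=0.0, f_FD=0.0)
        assert radiation_damage(state, basic) == 0.0

    def test_self_damage_term(self, basic):
        # alpha * lambda * gamma / nu at full active occupancy
        state = ModelState(N=1.0, f_FN=0.0, f_AN=1.0, f_FD=1.0)
        rd = radiation_damage(state, basic.replace(k_s=1.0))
        assert rd == pytest.approx(500 * 0.07 * 2.1 / 0.015, rel=1e-12)

    @pytest.mark.parametrize("N,D", [(1.0, 1.0), (2.5, 0.3), (0.1, 5.0)])
    def test_crossfire_equals_selfdamage_at_equal_occupancy(self, basic, N, D):
        c = 0.37
        common = dict(N=N, D=D, f_AN=c, f_AD=c, f_FN=1 - c, f_FD=1 - c)
        rd_cross = radiation_damage(ModelState(**common), basic.replace(k_s=0.0))
        rd_self = radiation_damage(ModelState(**common), basic.replace(k_s=1.0))
        assert rd_cross == pytest.approx(rd_self, rel=1e-12)

    def test_unanchored_term(self, basic):
        state = ModelState(a=1.0, p=0.5, N=1.0)
        expected = basic.alpha * basic.k_f * basic.lambda_decay * 1.5
        assert radiation_damage(state, basic) == pytest.approx(expected)

    def test_negative_input_rejected(self, basic):
        with pytest.raises(ValueError):
            radiation_damage(ModelState(a=-1.0, N=1.0), basic)


class TestRhs:
    def test_drug_free_growth_only(self, basic):
        state = ModelState(N=3.0, f_FN=1.0)
        d = rhs(state, basic)
        assert d.N == pytest.approx(0.34 * 3.0)
        assert d.cum_cells_born == pytest.approx(0.34 * 3.0)
        for name in ("a", "b", "p", "D", "f_AN", "cum_blood_decays",
                     "cum_viable_decays", "cum_damaged_decays"):
            assert getattr(d, name) == 0.0

    def test_plasma_clearance_binding_decay(self, basic):
        d = rhs(ModelState(a=1.0, N=3.0, f_FN=1.0), basic)
        # -lambda - kon*gamma*N/V - kappa_c
        assert d.a == pytest.approx(-70.415, rel=1e-12)
        # decayed antibodies feed the inert pool
        assert d.b == pytest.approx(0.07, rel=1e-12)

    def test_active_fraction_decay(self, basic):
        d = rhs(ModelState(N=3.0, f_FN=0.5, f_AN=0.5), basic)
        assert d.f_AN == pytest.approx(-(0.07 + 0.34) * 0.5, rel=1e-12)

    def test_nonfinite_rejected(self, basic):
        with pytest.raises(ValueError):
            rhs(ModelState(a=math.inf, N=1.0), basic)


class TestInjection:
    def test_zero_amount_noop(self, basic):
        s = ModelState(N=3.0)
        s2 = apply_injection(s, 0.0, eta=1780.0, V=1.0)
        assert s2.to_array().tolist() == s.to_array().tolist()

    def test_pure_dose(self):
        s2 = apply_injection(ModelState(N=3.0), 0.03, eta=0.0, V=1.0)
        assert s2.a == pytest.approx(0.03)
        assert s2.b == 0.0

    def test_impure_dose_scaling(self):
        s2 = apply_injection(ModelState(N=3.0), 0.001, eta=1780.0, V=1.0)
        assert s2.a == pytest.approx(0.001)
        assert s2.b == pytest.approx(1.78)

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            apply_injection(ModelState(), -0.1, eta=0.0, V=1.0)


class TestSimulate:
    def test_untreated_exponential_growth(self, basic):
        res = simulate(basic, DoseSchedule.empty(), horizon=10.0)
        assert res.final_state.N == pytest.approx(3 * math.exp(3.4), rel=1e-3)
        assert not res.cured

    def test_nuclide_conservation_without_clearance(self, basic):
        # with clearance off, total undecayed nuclides decay exactly at lambda
        p = basic.replace(kappa_c=1e-12, kappa_p=1e-12)
        res = simulate(p, DoseSchedule.single(0.003, eta=0.0), horizon=30.0,
                       rtol=1e-10, atol=1e-14)
        S = res.states
        total = (S[:, 0] + S[:, 2]) * p.V + p.gamma * (
            S[:, 6] * S[:, 3] + S[:, 8] * S[:, 4])
        expected = 0.003 * np.exp(-p.lambda_decay * res.t)
        drift = np.max(np.abs(total - expected) / expected)
        assert drift < 1e-6

    def test_occupied_fraction_decay_rates(self, pure):
        # after binding: f_AN falls at lambda+rho; once damage transfer ends,
        # f_AD falls at lambda alone
        res = simulate(pure, DoseSchedule.single(0.0048), horizon=40.0,
                       grid_per_day=24, n_floor_factor=0.0, atol=1e-16)

        def logslope(col, t0, t1):
            m = (res.t >= t0) & (res.t <= t1)
            return np.polyfit(res.t[m], np.log(res.states[:, col][m]), 1)[0]

        lam, rho = pure.lambda_decay, pure.rho
        assert logslope(6, 3, 8) == pytest.approx(-(lam + rho), rel=0.01)
        assert logslope(8, 20, 35) == pytest.approx(-lam, rel=0.01)

    def test_binding_phase_plasma_decay_rate(self, pure):
        # small pure dose: plasma concentration initially decays at
        # lambda + kappa_c + kon*gamma*N0/V
        res = simulate(pure, DoseSchedule.single(0.002), horizon=0.1,
                       grid_per_day=2000)
        m = (res.t >= 0.005) & (res.t <= 0.03)
        slope = np.polyfit(res.t[m], np.log(res.states[:, 0][m]), 1)[0]
        assert slope == pytest.approx(-70.415, rel=0.02)

    def test_no_damage_means_monotone_growth(self, basic):
        res = simulate(basic.replace(alpha=1e-12, k_s=0.0),
                       DoseSchedule.single(0.01, eta=0.0), horizon=20.0)
        assert np.all(np.diff(res.states[:, 3]) > 0)

    def test_cumulative_integrals_nondecreasing(self, basic):
        res = simulate(basic, DoseSchedule.single(0.01), horizon=50.0)
        for col in (9, 10, 11, 12):
            assert np.all(np.diff(res.states[:, col]) > -1e-12)

    def test_multi_dose_jumps_applied(self, basic):
        sched = DoseSchedule(((0.0, 0.002), (5.0, 0.002), (10.0, 0.002)))
        res = simulate(basic, sched, horizon=20.0)
        a = res.states[:, 0]
        # plasma concentration jumps upward right after each later injection
        for t_inj in (5.0, 10.0):
            i = np.searchsorted(res.t, t_inj)
            assert a[i] > a[i - 1]

    def test_horizon_before_last_injection_rejected(self, basic):
        with pytest.raises(ValueError):
            simulate(basic, DoseSchedule(((0.0, 0.01), (30.0, 0.01))),
                     horizon=20.0)

    def test_death_endpoint_matches_growth_time(self, basic):
        # untreated: N+D reaches C_d at ln(C_d/N0)/rho
        res = simulate(basic, DoseSchedule.empty(), horizon=60.0)
        expected = math.log(basic.C_d / basic.N0) / basic.rho
        assert res.death_time == pytest.approx(expected, rel=1e-4)
        assert res.cause == "cancer"

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(
        doses=st.lists(st.tuples(st.floats(0.0, 20.0), st.floats(0.0, 0.05)),
                       min_size=1, max_size=4,
                       unique_by=lambda d: round(d[0], 3)),
        eta=st.sampled_from([0.0, 10.0, 1780.0]),
        ks=st.floats(0.0, 1.0),
    )
    def test_fractions_stay_in_unit_interval(self, doses, eta, ks):
        """Receptor fractions are probabilities for any admissible schedule."""
        basic = ModelParameters.basic(k_s=ks)
        sched = DoseSchedule(tuple(sorted(doses)), eta_override=eta)
        res = simulate(basic, sched, horizon=25.0, rtol=1e-6, atol=1e-10,
                       grid_per_day=4, refine_nmin=False)
        S = res.states
        tol = 1e-6
        for col in (5, 6, 7, 8):
            assert np.all(S[:, col] >= -tol)
        assert np.all(S[:, 5] + S[:, 6] <= 1 + tol)
        assert np.all(S[:, 7] + S[:, 8] <= 1 + tol)


class TestScheduleValidation:
    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            DoseSchedule(((1.0, 0.01), (0.5, 0.01)))

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            DoseSchedule(((0.0, -0.01),))

    def test_total_activity(self):
        s = DoseSchedule(((0.0, 0.01), (7.0, 0.005)))
        assert s.total_activity == pytest.approx(0.015)
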