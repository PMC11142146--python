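"""Dose finding, impurity sweeps, PK capacity estimation, personalized rule."""

import numpy as np
import pytest

from trtsim import analytics as an
from trtsim import dosing
from trtsim.fixtures import generate_pk_fixture
from trtsim.model import DoseSchedule, simulate

FAST = dict(rtol=1e-6, atol=1e-12, grid_per_day=8)


@pytest.fixture(scope="module")
def found(pure):
    return dosing.find_minimal_curative_dose(pure, **FAST)


class TestCurativeDose:
    def test_bisection_hits_cure_threshold(self, pure, found):
        assert found.converged
        assert found.n_min == pytest.approx(pure.N_cur, rel=0.05)

    def test_dose_is_minimal(self, pure, found):
        above = simulate(pure, DoseSchedule.single(found.A_cur_pmol * 1.01),
                         365.0, **FAST)
        below = simulate(pure, DoseSchedule.single(found.A_cur_pmol * 0.99),
                         365.0, **FAST)
        assert above.cured and not below.cured

    def test_radiosensitivity_halves_dose(self, pure, found):
        # doubling alpha halves the required energy density
        r2 = dosing.find_minimal_curative_dose(pure.replace(alpha=1000.0),
                                               **FAST)
        assert r2.A_cur_pmol == pytest.approx(found.A_cur_pmol / 2, rel=0.05)


class TestPerCellConversion:
    def test_reference_value(self):
        assert dosing.radioconjugates_per_cell(3.79e-3, 3e7) == pytest.approx(
            76, rel=0.01)

    def test_linearity_and_zero(self):
        assert dosing.radioconjugates_per_cell(0.0, 1e7) == 0.0
        one = dosing.radioconjugates_per_cell(0.01, 1e7)
        assert dosing.radioconjugates_per_cell(0.02, 1e7) == pytest.approx(
            2 * one)


class TestImpuritySweep:
    def test_low_impurity_plateau(self, basic):
        # A_cur barely moves while injected antibodies stay far below the
        # receptor pool; the eta=0 column reproduces the direct search
        table = dosing.impurity_sweep(basic, [0.0, 10.0], rel_tol=1e-3,
                                      **FAST)
        direct = dosing.find_minimal_curative_dose(basic, eta=0.0,
                                                   rel_tol=1e-3, **FAST)
        assert table.A_cur_pmol[0] == pytest.approx(direct.A_cur_pmol,
                                                    rel=0.01)
        assert table.A_cur_pmol[1] == pytest.approx(table.A_cur_pmol[0],
                                                    rel=0.05)
        assert table.cured.all()

    def test_no_unanchored_damage_blocks_cure_past_saturation(self, basic):
        # with k_f=0 and antibodies >> receptors no finite dose cures
        p = basic.replace(k_f=1e-12)
        table = dosing.impurity_sweep(p, [1e5], **FAST)
        assert not table.cured[0]
        assert np.isnan(table.A_cur_pmol[0])


class TestCapacityEstimation:
    def test_noiseless_round_trip(self, basic):
        pk = generate_pk_fixture(basic)
        est = dosing.estimate_binding_capacity(
            pk, basic.k_on, basic.V, basic.lambda_decay, basic.kappa_c)
        assert est == pytest.approx(basic.binding_capacity, rel=0.01)

    def test_zero_capacity_returns_zero(self, basic):
        # no receptor sink: the curve decays at exactly lambda + kappa_c
        t = np.linspace(0.0025, 0.04, 8)
        k = basic.lambda_decay + basic.kappa_c
        pk = dosing.PKObservation(t, 0.01 * np.exp(-k * t))
        est = dosing.estimate_binding_capacity(
            pk, basic.k_on, basic.V, basic.lambda_decay, basic.kappa_c)
        assert est == pytest.approx(0.0, abs=1e-9)

    def test_subclearance_rate_floored_with_warning(self, basic):
        # slower decay than clearance alone cannot be receptor binding
        t = np.linspace(0.0025, 0.04, 8)
        pk = dosing.PKObservation(t, 0.01 * np.exp(-0.05 * t))
        with pytest.warns(UserWarning):
            est = dosing.estimate_binding_capacity(
                pk, basic.k_on, basic.V, basic.lambda_decay, basic.kappa_c)
        assert est == 0.0

    def test_noisy_recovery_median(self, basic):
        # 5% multiplicative noise, 8 samples over 0.1 day
        times = np.linspace(0.0125, 0.1, 8)
        errs = []
        for s in range(100):
            pk = generate_pk_fixture(basic, sampling_times=times,
                                     noise_cv=0.05, seed=s)
            est = dosing.estimate_binding_capacity(
                pk, basic.k_on, basic.V, basic.lambda_decay, basic.kappa_c)
            errs.append(abs(est - basic.binding_capacity)
                        / basic.binding_capacity)
        assert np.median(errs) < 0.10

    def test_too_few_points_rejected(self, basic):
        pk = dosing.PKObservation(np.array([0.0, 0.01]),
                                  np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            dosing.estimate_binding_capacity(pk, 11.15, 1.0, 0.07, 0.1)


class TestPersonalizedDose:
    def test_reference_capacity(self, basic):
        A = dosing.personalized_dose(6.3, 1780.0, basic)
        assert A == pytest.approx((1.5 * 6.3 + 3) / 1781, rel=1e-9)
        assert an.activity_nCi_from_pmol(A, basic.lambda_decay) == \
            pytest.approx(92, rel=0.01)

    def test_zero_capacity_floor_is_capped(self, basic):
        A = dosing.personalized_dose(0.0, 1780.0, basic)
        cap = an.max_safe_dose(0.0, basic)
        assert A == pytest.approx(min(3.0 / 1781.0, cap))

    def test_nondecreasing_in_capacity(self, basic):
        caps = np.linspace(0.0, 60.0, 25)
        doses = [dosing.personalized_dose(c, 1780.0, basic) for c in caps]
        assert all(b >= a - 1e-15 for a, b in zip(doses, doses[1:]))

    def test_never_exceeds_safe_cap(self, basic):
        for c in (0.0, 5.0, 50.0, 500.0, 5e4):
            A = dosing.personalized_dose(c, 1780.0, basic)
            assert A <= an.max_safe_dose(c, basic) + 1e-12


class TestTreatmentMetrics:
    def test_curative_course_accounting(self, pure):
        r = dosing.find_minimal_curative_dose(pure, **FAST)
        m = dosing.treatment_metrics(r.result)
        bound = an.viable_fraction_bound(pure.N0, pure.N_cur)
        assert 0 < m["viable_fraction"] < bound
        assert 0 < m["born_fraction"] < 0.5
        assert m["t_nmin"] > 0
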