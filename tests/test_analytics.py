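"""Closed-form analytics: conversions, survival estimates, safe doses."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from trtsim import analytics as an
from trtsim.params import ModelParameters


class TestActivityConversion:
    def test_lethal_blood_amount_in_nCi(self):
        # 0.0175 pmol of 225Ac carries ~230 nCi
        assert an.activity_nCi_from_pmol(0.0175, 0.07) == pytest.approx(
            230.8, abs=0.1)

    def test_zero(self):
        assert an.activity_nCi_from_pmol(0.0, 0.07) == 0.0

    def test_linear_scaling(self):
        a1 = an.activity_nCi_from_pmol(0.0175, 0.07)
        assert an.activity_nCi_from_pmol(0.0297, 0.07) == pytest.approx(
            a1 * 0.0297 / 0.0175, rel=1e-12)
        assert an.activity_nCi_from_pmol(0.0297, 0.07) == pytest.approx(
            391, rel=0.01)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n=st.floats(1e-6, 1e3), lam=st.floats(0.001, 10.0))
    def test_round_trip(self, n, lam):
        nci = an.activity_nCi_from_pmol(n, lam)
        assert an.pmol_from_activity_nCi(nci, lam) == pytest.approx(
            n, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            an.activity_nCi_from_pmol(-1.0, 0.07)


class TestLabelingRatio:
    def test_reference_ratio(self):
        # 1.85 kBq/ug on a 148 kDa antibody dilutes ~1780-fold
        assert an.eta_from_labeling_ratio(1.85) == pytest.approx(1780, rel=0.01)

    def test_full_labeling_gives_zero_eta(self):
        # ratio approaching one nuclide per antibody
        full = an.eta_from_labeling_ratio(1.85) + 1.0
        ratio = 1.85 * full * (1 - 1e-9)
        assert an.eta_from_labeling_ratio(ratio) == pytest.approx(0.0, abs=1e-6)

    def test_halving_ratio_doubles_eta_plus_one(self):
        e1 = an.eta_from_labeling_ratio(1.85)
        e2 = an.eta_from_labeling_ratio(0.925)
        assert (e2 + 1) == pytest.approx(2 * (e1 + 1), rel=1e-9)

    def test_overlabeling_rejected(self):
        with pytest.raises(ValueError):
            an.eta_from_labeling_ratio(1e9)


class TestReceptorsPerCell:
    def test_reference_density(self):
        assert an.receptors_per_cell(2.1) == pytest.approx(126_000, rel=0.005)

    def test_range_floor(self):
        assert an.receptors_per_cell(0.13) == pytest.approx(8_000, rel=0.03)

    def test_zero(self):
        assert an.receptors_per_cell(0.0) == 0.0


class TestSurvivingFractions:
    def test_no_growth_limit_is_classical_survival(self, pure):
        # rho -> 0: both estimates collapse to exp(-alpha*A/(nu*N0))
        p = pure.replace(rho=1e-9)
        A = 0.004
        x = p.alpha * A / (p.nu * p.N0)
        for f in (an.surviving_fraction_selfdamage,
                  an.surviving_fraction_crossfire):
            assert f(A, p, log=True) == pytest.approx(-x, rel=1e-6)

    def test_strictly_decreasing_in_dose(self, pure):
        doses = [0.002 + 0.001 * i for i in range(12)]
        for f in (an.surviving_fraction_selfdamage,
                  an.surviving_fraction_crossfire):
            vals = [f(A, pure, log=True) for A in doses]
            assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_zero_dose_fraction_is_one(self, pure):
        assert an.surviving_fraction_selfdamage(0.0, pure) == 1.0
        assert an.surviving_fraction_crossfire(0.0, pure) == 1.0

    def test_curative_doses_match_reported_per_cell_span(self, pure):
        # solving estimate = N_cur/N0 reproduces the 76-272 radioconjugates
        # per cell span across the particle-range extremes
        from scipy.optimize import brentq

        from trtsim.dosing import radioconjugates_per_cell

        target = math.log(pure.N_cur / pure.N0)
        for f, expected in ((an.surviving_fraction_crossfire, 76),
                            (an.surviving_fraction_selfdamage, 272)):
            A = brentq(lambda a: f(a, pure, log=True) - target, 1e-4, 0.1)
            assert radioconjugates_per_cell(A, pure.N0 * 1e7) == pytest.approx(
                expected, rel=0.01)

    def test_self_damage_needs_larger_dose(self, pure):
        # redistribution of nuclides to newborn cells weakens self-damage
        for A in (0.004, 0.008, 0.012):
            assert an.surviving_fraction_selfdamage(A, pure) > \
                an.surviving_fraction_crossfire(A, pure)


class TestBloodDecays:
    def test_fragment_dominance(self, basic):
        bd = an.blood_decay_fraction(basic)
        assert bd.intact == pytest.approx(0.07 / 70.415, rel=1e-9)
        assert bd.fragment / bd.total == pytest.approx(0.965, abs=0.005)
        assert 0 < bd.total < 1

    def test_no_cell_death_means_no_fragments(self, basic):
        bd = an.blood_decay_fraction(basic.replace(omega=1e-12))
        assert bd.fragment == pytest.approx(0.0, abs=1e-10)


class TestViableFractionBound:
    def test_reference_bound_under_five_percent(self):
        assert an.viable_fraction_bound(1e7, 0.01) == pytest.approx(
            1 / math.log(1e9), rel=1e-12)
        assert an.viable_fraction_bound(1e7, 0.01) < 0.05

    def test_edge_case_ratio_e(self):
        assert an.viable_fraction_bound(math.e, 1.0) == pytest.approx(1.0)

    def test_decreases_with_tumor_burden(self):
        bounds = [an.viable_fraction_bound(n, 0.01) for n in (1e6, 1e8, 1e10)]
        assert bounds[0] > bounds[1] > bounds[2]

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            an.viable_fraction_bound(0.01, 1e7)


class TestMaxSafeDose:
    def test_zero_capacity_limit(self, basic):
        nci = an.activity_nCi_from_pmol(an.max_safe_dose(0.0, basic),
                                        basic.lambda_decay)
        assert nci == pytest.approx(362, rel=0.01)

    def test_saturated_limit(self, basic):
        nci = an.activity_nCi_from_pmol(an.max_safe_dose(1e12, basic),
                                        basic.lambda_decay)
        assert nci == pytest.approx(1763, rel=0.01)

    def test_monotone_in_capacity(self, basic):
        caps = [0.0, 1.0, 6.3, 50.0, 1e3, 1e6]
        doses = [an.max_safe_dose(c, basic) for c in caps]
        assert all(b >= a for a, b in zip(doses, doses[1:]))
        # the two limits bracket every intermediate capacity
        assert all(doses[0] <= d <= doses[-1] for d in doses)

    def test_lower_impurity_allows_more_at_low_capacity(self, basic):
        a_pure = an.max_safe_dose(6.3, basic, eta=0.0)
        a_dirty = an.max_safe_dose(6.3, basic, eta=1780.0)
        assert a_pure > a_dirty
        # but the limits do not move with impurity
        assert an.max_safe_dose(0.0, basic, eta=0.0) == pytest.approx(
            an.max_safe_dose(0.0, basic, eta=1780.0))


class TestCurability:
    def test_reference_parameters_curable(self, basic):
        c = an.curability_condition(basic)
        assert c.max_kill_rate == pytest.approx(2.75, rel=0.001)
        assert c.curable

    def test_fast_growth_incurable(self, basic):
        c = an.curability_condition(basic.replace(rho=0.7, alpha=50.0))
        assert not c.curable

    def test_large_impurity_incurable(self, basic):
        assert not an.curability_condition(basic, eta=1e6).curable
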