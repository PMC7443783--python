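"""Burden-integral engine: closed form vs quadrature, limits, YLL/YLD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oaburden.engine import (DW_MINSA, DW_WHO, GBD2015, HARVARD1994,
                             DisabilityWeight, MethodSpec, age_weight,
                             burden_integral, burden_integral_quad,
                             method_preset, yld, yll)


class TestMethodSpec:
    def test_presets(self):
        h = method_preset("harvard1994")
        assert (h.K, h.C, h.beta, h.r) == (1.0, 0.16458, 0.04, 0.03)
        g = method_preset("gbd2015")
        assert (g.K, g.r) == (0.0, 0.0)

    def test_unknown_preset(self):
        with pytest.raises(KeyError, match="unknown method"):
            method_preset("gbd2019")

    @pytest.mark.parametrize("kwargs", [{"K": 1.5}, {"K": -0.1}, {"r": -0.01},
                                        {"C": -1.0}, {"beta": -0.04}])
    def test_parameter_bounds(self, kwargs):
        with pytest.raises(ValueError):
            MethodSpec(name="bad", **{"K": 1.0, **kwargs})

    def test_disability_weight_bounds(self):
        with pytest.raises(ValueError):
            DisabilityWeight(1.2, "too-heavy")


class TestAgeWeight:
    def test_vanishes_at_birth_when_weighted(self):
        assert age_weight(0, HARVARD1994) == 0.0

    def test_direct_evaluation_at_25(self):
        # 0.16458 * 25 * e^(-0.04 * 25)
        assert age_weight(25, HARVARD1994) == pytest.approx(1.51364, abs=1e-4)

    def test_unit_weight_when_disabled(self):
        assert age_weight(40, GBD2015) == 1.0

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            age_weight(-1, HARVARD1994)


class TestBurdenIntegral:
    def test_gbd_reduces_to_duration_times_weight(self):
        assert burden_integral(60, 30, 0.165, GBD2015) == 0.165 * 30

    def test_discounted_unweighted_closed_form(self):
        # (1 - e^(-rL)) / r at r=0.03, L=30
        spec = MethodSpec("disc", K=0.0, r=0.03)
        expected = (1 - math.exp(-0.9)) / 0.03
        assert burden_integral(60, 30, 1.0, spec) == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(19.7810, abs=1e-3)

    def test_harvard_matches_quadrature(self):
        closed = burden_integral(60, 20, 1.0, HARVARD1994)
        quad = burden_integral_quad(60, 20, 1.0, HARVARD1994)
        assert closed == pytest.approx(quad, rel=1e-8)

    def test_zero_duration_and_zero_weight(self):
        assert burden_integral(40, 0.0, 1.0, HARVARD1994) == 0.0
        assert burden_integral(40, 20.0, 0.0, HARVARD1994) == 0.0

    @pytest.mark.parametrize("a,L,D", [(-1, 10, 1), (10, -1, 1), (10, 10, 1.5)])
    def test_domain_errors(self, a, L, D):
        with pytest.raises(ValueError):
            burden_integral(a, L, D, GBD2015)

    def test_vectorised_matches_scalar(self):
        a = np.array([20.0, 45.0, 70.0])
        L = np.array([50.0, 30.0, 12.0])
        vec = burden_integral(a, L, 0.28, HARVARD1994)
        for i in range(3):
            assert vec[i] == pytest.approx(
                burden_integral(a[i], L[i], 0.28, HARVARD1994), rel=1e-12
            )

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(
        a=st.floats(0, 100),
        L=st.floats(0, 60),
        K=st.sampled_from([0.0, 0.5, 1.0]),
        r=st.sampled_from([0.0, 0.01, 0.03, 0.07]),
        beta=st.sampled_from([0.0, 0.02, 0.04]),
    )
    def test_closed_form_equals_quadrature(self, a, L, K, r, beta):
        spec = MethodSpec("prop", K=K, beta=beta, r=r)
        closed = burden_integral(a, L, 1.0, spec)
        quad = burden_integral_quad(a, L, 1.0, spec)
        assert closed == pytest.approx(quad, rel=1e-8, abs=1e-10)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=st.floats(0, 90), L=st.floats(0.1, 60), D=st.floats(0.01, 1))
    def test_linearity_in_disability_weight(self, a, L, D):
        full = burden_integral(a, L, 1.0, HARVARD1994)
        assert burden_integral(a, L, D, HARVARD1994) == pytest.approx(D * full, rel=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=st.floats(0, 90), L=st.floats(0.5, 50), dL=st.floats(0.5, 20))
    def test_strictly_increasing_in_duration(self, a, L, dL):
        assert burden_integral(a, L + dL, 1.0, HARVARD1994) > burden_integral(
            a, L, 1.0, HARVARD1994
        )

    def test_undiscounted_weighted_limit(self):
        # r -> 0+ converges to int C x e^(-beta x) dx, by parts with mu=beta
        a, L, C, beta = 30.0, 40.0, 0.16458, 0.04
        direct = (C / beta**2) * (
            math.exp(-beta * a) * (beta * a + 1)
            - math.exp(-beta * (a + L)) * (beta * (a + L) + 1)
        )
        exact = burden_integral(a, L, 1.0, MethodSpec("nw", K=1.0, r=0.0))
        assert exact == pytest.approx(direct, rel=1e-12)
        near = burden_integral(a, L, 1.0, MethodSpec("nw", K=1.0, r=1e-9))
        assert near == pytest.approx(direct, rel=1e-6)


class TestYllYld:
    def test_gbd_yll_is_remaining_life_expectancy(self, tables):
        age = 70.0
        ex = tables["gbd2050"].strata["both"][1][70]
        assert yll(age, "female", GBD2015, tables) == pytest.approx(ex, rel=1e-12)

    def test_yll_zero_when_no_years_remain(self):
        spec = MethodSpec("flat", K=0.0, r=0.0, life_table_ref="gbd2050")
        assert burden_integral(80, 0.0, 1.0, spec) == 0.0

    def test_harvard_yll_is_compositional(self, tables):
        from oaburden.life_tables import remaining_life_expectancy

        ex = remaining_life_expectancy(tables["west26"], 70, "female")
        assert yll(70, "female", HARVARD1994, tables) == pytest.approx(
            burden_integral(70, ex, 1.0, HARVARD1994), rel=1e-12
        )

    def test_yld_is_weighted_duration_under_gbd(self, tables):
        got = yld(60, "male", DW_WHO, GBD2015, tables)
        from oaburden.life_tables import remaining_life_expectancy

        ex = remaining_life_expectancy(tables["gbd2050"], 60)
        assert got == pytest.approx(0.165 * ex, rel=1e-12)

    def test_yld_weight_ratio_exact(self, tables):
        for spec in (HARVARD1994, GBD2015):
            lo = yld(55, "female", DW_WHO, spec, tables)
            hi = yld(55, "female", DW_MINSA, spec, tables)
            assert hi / lo == pytest.approx(0.28 / 0.165, rel=1e-12)

    def test_gbd_yll_non_increasing_in_age(self, tables):
        ages = np.linspace(0, 110, 221)
        vals = [yll(a, "male", GBD2015, tables) for a in ages]
        assert np.all(np.diff(vals) <= 1e-9)

    def test_age_weight_on_yld_flag(self, tables):
        weighted = yld(30, "female", DW_WHO, HARVARD1994, tables)
        unweighted = yld(
            30, "female", DW_WHO,
            method_preset("harvard1994", age_weight_on_yld=False), tables,
        )
        assert weighted != pytest.approx(unweighted)

    def test_missing_life_table_reference(self, tables):
        spec = MethodSpec("odd", K=0.0, life_table_ref="nope")
        with pytest.raises(KeyError, match="nope"):
            yll(70, "female", spec, tables)
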