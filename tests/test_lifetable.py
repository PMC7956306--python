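"""Life-table construction, survival, intensity and expectancy."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad

import ltcfactor as lf
from ltcfactor.lifetable import LifeTableError


class TestBuild:
    def test_single_closing_age(self):
        lt = lf.build_life_table({100: 1.0})
        assert lt.lx(100) == lt.radix
        assert lt.lx(101) == 0.0
        assert lt.omega == 100

    def test_constant_half_q_survivors_halve(self):
        lt = lf.build_life_table({0: 0.5, 1: 0.5, 2: 0.5, 3: 1.0}, radix=8.0)
        assert [lt.lx(a) for a in range(4)] == [8.0, 4.0, 2.0, 1.0]

    def test_table3_mens_column_ingests(self, table3):
        lt = table3.to_life_table("male", "independent")
        assert lt.age_start == 20 and lt.omega == 120
        assert lt.qx(65) == pytest.approx(0.001650)
        # interior interpolated ages are monotone between the printed nodes
        assert 0.001650 < lt.qx(67) < 0.002431

    @pytest.mark.parametrize("schedule,err", [
        ({}, "empty"),
        ({50: 1.2}, "0, 1"),
        ({50: 0.1, 60: 0.2}, "gap"),
    ])
    def test_invalid_schedules_rejected(self, schedule, err):
        with pytest.raises(LifeTableError, match=err):
            lf.build_life_table(schedule)

    def test_five_year_grid_interpolation_recovers_smooth_q(self, gm_table):
        abridged = {int(a): gm_table.qx(a) for a in range(20, 101, 5)}
        rebuilt = lf.build_life_table(abridged, omega=120)
        for age in range(20, 101):
            assert rebuilt.qx(age) == pytest.approx(gm_table.qx(age), rel=0.05)

    def test_extension_to_omega_closes_table(self):
        lt = lf.build_life_table({a: 0.01 * 1.1 ** (a - 60) for a in range(60, 81)},
                                 omega=120)
        assert lt.omega == 120
        assert lt.qx(120) == 1.0
        assert all(np.diff([lt.qx(a) for a in range(80, 120)]) >= 0)

    def test_radix_invariance_of_derived_quantities(self, gm_params):
        a = lf.make_base_table(gm_params)
        b = lf.LifeTable(sex=a.sex, cohort_year=a.cohort_year, state=a.state,
                         age_start=a.age_start, q=a.q, radix=1.0)
        assert a.life_expectancy(40) == pytest.approx(b.life_expectancy(40), abs=1e-12)
        assert a.survival_prob(40, 30) == pytest.approx(b.survival_prob(40, 30), abs=1e-15)


class TestSurvival:
    def test_zero_years_is_certain(self, gm_table):
        assert gm_table.survival_prob(50, 0) == 1.0

    def test_two_year_product(self):
        lt = lf.build_life_table({a: 0.1 for a in range(0, 5)} | {5: 1.0})
        assert lt.survival_prob(0, 2) == pytest.approx(0.81, abs=1e-15)

    def test_survival_to_past_omega_is_zero(self, gm_table):
        assert gm_table.survival_prob(100, gm_table.omega + 1 - 100) == 0.0

    def test_matches_lx_ratio(self, gm_table):
        assert gm_table.survival_prob(30, 40) == pytest.approx(
            gm_table.lx(70) / gm_table.lx(30), rel=1e-12)

    @given(x=st.integers(20, 80), t=st.integers(0, 20), u=st.integers(0, 20))
    def test_semigroup_property(self, x, t, u):
        lt = _GM
        assert lt.survival_prob(x, t) * lt.survival_prob(x + t, u) == pytest.approx(
            lt.survival_prob(x, t + u), abs=1e-12)

    def test_monotone_survivors_and_sF_complement(self, gm_table):
        lx = [gm_table.lx(a) for a in range(20, 122)]
        assert all(a >= b for a, b in zip(lx, lx[1:]))
        for age in (20, 50, 90, 120):
            s = gm_table.survival_function(age)
            assert 0.0 <= s <= 1.0
            assert s + gm_table.death_distribution(age) == pytest.approx(1.0)


# module-level table for hypothesis (fixtures cannot feed @given directly)
_GM = lf.make_base_table(
    lf.GompertzMakehamParams(A=0.0002, B=3e-5, c=1.1, age_start=20, age_end=120))


class TestForceOfMortality:
    @pytest.mark.parametrize("q,mu", [
        (0.0, 0.0),
        (1.0 - math.exp(-1.0), 1.0),
        (0.01, 0.01005034),
    ])
    def test_piecewise_constant_link(self, q, mu):
        lt = lf.LifeTable(sex="male", cohort_year=1970, state="independent",
                          age_start=0, q=np.array([q, 1.0]))
        assert lt.force_of_mortality(0) == pytest.approx(mu, abs=1e-8)

    def test_closing_age_has_no_finite_rate(self, gm_table):
        with pytest.raises(LifeTableError, match="infinite"):
            gm_table.force_of_mortality(gm_table.omega)


class TestExpectancy:
    def test_closure_age(self, gm_table):
        w = gm_table.omega
        assert gm_table.life_expectancy(w, "curtate") == 0.0
        assert gm_table.life_expectancy(w, "complete") == 0.5

    def test_three_age_hand_sum(self, toy_table):
        assert toy_table.life_expectancy(0, "curtate") == pytest.approx(0.75)
        assert toy_table.life_expectancy(0, "complete") == pytest.approx(1.25)

    def test_complete_is_curtate_plus_half(self, gm_table):
        for x in (20, 45, 70, 95):
            assert gm_table.life_expectancy(x, "complete") == pytest.approx(
                gm_table.life_expectancy(x, "curtate") + 0.5, abs=1e-12)

    def test_matches_quadrature_of_continuous_survival(self, gm_params, gm_table):
        """Discrete expectancy vs numerical integration of exp(-int mu)."""
        A, B, c = gm_params.A, gm_params.B, gm_params.c

        def survival(t, x0):
            return math.exp(-(A * t + B * c ** x0 * (c ** t - 1.0) / math.log(c)))

        for x0 in (20, 50, 70):
            exact, _ = quad(survival, 0.0, 120.0 - x0, args=(x0,), limit=200)
            assert gm_table.life_expectancy(x0, "complete") == pytest.approx(
                exact, abs=0.6)

    def test_decreases_under_uniform_mortality_increase(self, gm_table):
        rng = np.random.default_rng(7)
        for _ in range(5):
            bump = rng.uniform(0.001, 0.02)
            q = np.clip(gm_table.q + bump, 0.0, 1.0)
            q[-1] = 1.0
            heavier = lf.LifeTable(sex="male", cohort_year=1970,
                                   state="independent", age_start=20, q=q)
            for x in (20, 60, 90):
                assert heavier.life_expectancy(x) < gm_table.life_expectancy(x)

    def test_annuity_due_count_is_one_plus_truncated_curtate(self, gm_table):
        x, w = 65, 100
        i = x - gm_table.age_start
        tpx = np.cumprod(1.0 - gm_table.q[i:i + (w - x - 1)])
        assert gm_table.annuity_due_count(x, w) == pytest.approx(1.0 + tpx.sum())


class TestCsvRoundTrip:
    def test_write_then_read_preserves_schedule(self, gm_table, tmp_path):
        path = tmp_path / "table.csv"
        lf.write_qx_csv(gm_table, path)
        back = lf.read_qx_csv(path)
        np.testing.assert_allclose(back.q, gm_table.q, rtol=1e-12)
        assert back.sex == "male" and back.state == "independent"
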