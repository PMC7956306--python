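"""Excess-mortality corrections and parameter fitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ltcfactor as lf
from ltcfactor.dependent import MortalityOrderingError, branch_jump


class TestMultiplicative:
    def test_zero_rate_stays_zero(self):
        assert lf.apply_multiplicative(0.0, 3.0) == 0.0

    def test_clipped_at_one(self):
        assert lf.apply_multiplicative(0.4, 3.0) == 1.0

    def test_plain_product(self):
        assert lf.apply_multiplicative(0.01, 2.5) == pytest.approx(0.025)

    def test_lightening_loading_rejected(self):
        with pytest.raises(ValueError):
            lf.apply_multiplicative(0.1, 0.9)


class TestMixed:
    def test_inflection_age_gives_half_delta(self):
        p = lf.SPAIN_SEVERE_MEN
        q = 0.005
        assert lf.apply_mixed(q, p.x_i, p) == pytest.approx(q + p.delta / 2.0, abs=1e-12)

    def test_additive_term_tends_to_delta(self):
        p = lf.SPAIN_SEVERE_MEN
        assert float(p.logistic_term(p.x_i + 500)) == pytest.approx(0.245, abs=1e-9)
        assert abs(float(p.logistic_term(p.x_i + 200)) - p.delta) < 1e-6

    def test_men_preset_at_80(self):
        # direct evaluation: 0.002 + 0.245 / (1 + 1.135**(-17.5))
        got = lf.apply_mixed(0.002, 80.0, lf.SPAIN_SEVERE_MEN)
        assert got == pytest.approx(0.2229125, abs=5e-7)

    def test_monotone_increasing_in_age_below_switch(self):
        p = lf.SPAIN_SEVERE_MEN
        ages = np.arange(20, 95)
        vals = lf.apply_mixed(np.full(ages.shape, 0.001), ages, p)
        assert np.all(np.diff(vals) > 0)

    def test_multiplicative_branch_from_switch_age(self):
        p = lf.SPAIN_SEVERE_MEN
        q = 0.1
        below = lf.apply_mixed(q, p.switch_age - 1, p)
        above = lf.apply_mixed(q, p.switch_age, p)
        assert above > below
        # the loading accounts for beta * q of the difference
        assert branch_jump(q, p) == pytest.approx(p.beta * q)

    def test_mirrored_exponent_convention_decreases_with_age(self):
        p = lf.ExcessParams(delta=0.2, gamma=1.1, x_i=60.0,
                            exponent_convention="mirrored")
        assert float(p.logistic_term(90)) < float(p.logistic_term(30))


class TestDeriveDependentTable:
    def test_identity_correction_preserves_table(self, gm_table):
        dep = lf.derive_dependent_table(
            gm_table, lf.SimpleCorrection(kind="multiplicative", theta=1.0))
        np.testing.assert_allclose(dep.q, gm_table.q, rtol=1e-15)
        assert dep.state == "dependent"

    def test_constant_additive_shift(self):
        base = lf.build_life_table({a: 0.05 for a in range(60, 70)} | {70: 1.0})
        dep = lf.derive_dependent_table(
            base, lf.SimpleCorrection(kind="additive", epsilon=0.1))
        np.testing.assert_allclose(dep.q[:-1], 0.15, rtol=1e-12)

    def test_mixed_preset_orders_mortality_and_expectancy(self, spanish_pair):
        base, dep = spanish_pair
        assert np.all(dep.q >= base.q - 1e-15)
        for x in range(20, 110, 10):
            assert dep.life_expectancy(x) < base.life_expectancy(x)

    def test_negative_additive_reported_as_ordering_violation(self, gm_table):
        with pytest.raises(MortalityOrderingError):
            lf.derive_dependent_table(
                gm_table, lf.SimpleCorrection(kind="additive", epsilon=-0.0001))

    @given(theta=st.floats(1.0, 5.0))
    def test_multiplicative_always_dominates_base(self, theta):
        base = _BASE
        dep = lf.derive_dependent_table(
            base, lf.SimpleCorrection(kind="multiplicative", theta=theta))
        assert np.all(dep.q >= base.q - 1e-15)


_BASE = lf.make_base_table(
    lf.GompertzMakehamParams(A=0.0002, B=3e-5, c=1.1, age_start=20, age_end=120))


def _observations(params, excess, ages):
    base = lf.make_base_table(params)
    dep = lf.derive_dependent_table(base, excess)
    return [(a, base.qx(a), dep.qx(a)) for a in ages]


class TestFit:
    truth = lf.ExcessParams(delta=0.2, gamma=1.1, x_i=60.0, beta=0.1)

    def test_noiseless_recovery_within_1e3(self, gm_params):
        obs = _observations(gm_params, self.truth, range(20, 116, 2))
        res = lf.fit_excess_params(obs)
        est = res.params
        assert est.delta == pytest.approx(self.truth.delta, abs=1e-3)
        assert est.gamma == pytest.approx(self.truth.gamma, abs=1e-3)
        assert est.x_i == pytest.approx(self.truth.x_i, abs=1e-3)
        assert est.beta == pytest.approx(self.truth.beta, abs=1e-3)
        assert res.rss < 1e-10

    def test_zero_excess_data_gives_near_zero_params(self, gm_params):
        base = lf.make_base_table(gm_params)
        obs = [(a, base.qx(a), base.qx(a)) for a in range(20, 116, 3)]
        res = lf.fit_excess_params(obs)
        assert res.params.delta < 1e-3
        assert res.params.beta < 1e-2

    def test_noisy_recovery_of_delta_within_5pct(self, gm_params):
        obs = lf.synthetic.noisy_observations(
            gm_params, self.truth, noise_amplitude=1e-4, n_ages=40,
            seed=lf.DEFAULT_SEED)
        res = lf.fit_excess_params([tuple(row) for row in obs])
        assert res.params.delta == pytest.approx(self.truth.delta, rel=0.05)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 6"):
            lf.ExcessMortalityModel([60, 61, 62], [0.01] * 3, [0.2] * 3)

    def test_results_surface(self, gm_params):
        obs = _observations(gm_params, self.truth, range(20, 116, 5))
        res = lf.ExcessMortalityModel.from_observations(obs).fit()
        assert res.n_obs == len(obs)
        assert res.converged
        assert res.resid().shape == (len(obs),)
        text = res.summary()
        assert "delta" in text and "residual sum of squares" in text

    def test_spain_presets_recoverable_from_their_own_image(self, gm_params):
        """Round-trip through the generator: preset -> pair -> refit."""
        for preset in (lf.SPAIN_SEVERE_MEN, lf.SPAIN_SEVERE_WOMEN):
            base, dep = lf.make_dependent_pair(gm_params, preset)
            obs = [(a, base.qx(a), dep.qx(a)) for a in range(20, 116, 2)]
            res = lf.fit_excess_params(obs)
            assert res.params.delta == pytest.approx(preset.delta, abs=1e-3)
            assert res.params.x_i == pytest.approx(preset.x_i, abs=1e-3)
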