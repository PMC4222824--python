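import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gppval.photosynthesis import (GRAMS_C_PER_MOL, LeafEnv, PhotoParams,
                                   c3_gross_rate, c4_gross_rate,
                                   canopy_daily_gpp, colimit_smooth,
                                   forward_gpp, kinetics_at_temperature)
from gppval.site_io import SiteDailyRecord

import datetime as dt


def _day(t_avg=25.0, par=30.0, **kw):
    base = dict(date=dt.date(2001, 7, 1), t_avg=t_avg, t_max=t_avg + 5,
                t_min=t_avg - 5, rh=60.0, precip=0.0, par=par,
                cloud_frac=0.2, le=80.0, h=40.0)
    base.update(kw)
    return SiteDailyRecord(**base)


class TestKinetics:
    def test_identity_at_25(self, default_params):
        kin = kinetics_at_temperature(default_params, 25.0)
        assert kin.vm == pytest.approx(default_params.vcmax25)
        assert kin.kc == pytest.approx(default_params.kc25)
        assert kin.ko == pytest.approx(default_params.ko25)
        assert kin.gamma_star == pytest.approx(
            default_params.o2 / (2 * default_params.tau25))

    def test_one_q10_decade(self):
        params = PhotoParams(vcmax25=50e-6, q10_vm=2.0)
        assert kinetics_at_temperature(params, 35.0).vm == pytest.approx(100e-6)

    def test_brute_force_at_15(self, default_params):
        p = default_params
        kin = kinetics_at_temperature(p, 15.0)
        f = lambda q10: q10 ** ((15.0 - 25.0) / 10.0)
        assert kin.vm == pytest.approx(p.vcmax25 * f(p.q10_vm), rel=1e-15)
        assert kin.kc == pytest.approx(p.kc25 * f(p.q10_kc), rel=1e-15)
        assert kin.ko == pytest.approx(p.ko25 * f(p.q10_ko), rel=1e-15)
        assert kin.gamma_star == pytest.approx(
            p.o2 / (2 * p.tau25 * f(p.q10_tau)), rel=1e-15)

    def test_tau_falls_with_temperature(self, default_params):
        cold = kinetics_at_temperature(default_params, 10.0)
        warm = kinetics_at_temperature(default_params, 35.0)
        assert warm.gamma_star > cold.gamma_star  # q10_tau < 1


class TestC3:
    def test_zero_at_compensation_point(self, default_params):
        gs = kinetics_at_temperature(default_params, 25.0).gamma_star
        rates = c3_gross_rate(LeafEnv(qp=1e-3, ci=gs, t_leaf=25.0), default_params)
        assert rates.je == 0 and rates.jc == 0 and rates.gross == 0

    def test_zero_below_compensation_point(self, default_params):
        gs = kinetics_at_temperature(default_params, 25.0).gamma_star
        rates = c3_gross_rate(LeafEnv(qp=1e-3, ci=0.5 * gs), default_params)
        assert rates.gross == 0
        assert rates.je >= 0 and rates.jc >= 0

    def test_dark_is_light_limited_zero(self, default_params):
        rates = c3_gross_rate(LeafEnv(qp=0.0, ci=250e-6), default_params)
        assert rates.gross == 0 and rates.limiter == "light"

    def test_against_independent_formula_evaluation(self):
        # reference point: vcmax 65e-6, ci = 0.7*370e-6, qp 1500e-6, 25 C
        p = PhotoParams(vcmax25=65e-6)
        ci, qp = 0.7 * 370e-6, 1500e-6
        rates = c3_gross_rate(LeafEnv(qp=qp, ci=ci, t_leaf=25.0), p)
        gs = p.o2 / (2 * p.tau25)
        je = p.alpha3 * qp * (ci - gs) / (ci + 2 * gs)
        jc = p.vcmax25 * (ci - gs) / (ci + p.kc25 * (1 + p.o2 / p.ko25))
        js = p.tpu_ratio * p.vcmax25
        assert rates.je == pytest.approx(je, rel=1e-14)
        assert rates.jc == pytest.approx(jc, rel=1e-14)
        assert rates.js == pytest.approx(js, rel=1e-14)
        assert rates.gross == pytest.approx(min(je, jc, js), rel=1e-14)
        expected_limiter = {je: "light", jc: "rubisco", js: "triose"}[min(je, jc, js)]
        assert rates.limiter == expected_limiter

    def test_limiter_switches_exactly_once_with_light(self, default_params):
        limiters = [c3_gross_rate(LeafEnv(qp=qp, ci=250e-6), default_params).limiter
                    for qp in np.linspace(0, 3000e-6, 400)]
        switches = sum(1 for a, b in zip(limiters, limiters[1:]) if a != b)
        assert limiters[0] == "light"
        assert switches == 1


class TestC4:
    def test_zero_ci(self, default_params):
        rates = c4_gross_rate(LeafEnv(qp=1e-3, ci=0.0), default_params)
        assert rates.js == 0 and rates.gross == 0

    def test_saturation_plateau(self):
        params = PhotoParams(vcmax25=15e-6)
        rates = c4_gross_rate(LeafEnv(qp=1.0, ci=0.01), params)
        assert rates.gross == pytest.approx(15e-6)
        assert rates.limiter == "rubisco"

    def test_against_brute_force_min(self, default_params):
        p = default_params
        qp, ci, t = 800e-6, 150e-6, 30.0
        rates = c4_gross_rate(LeafEnv(qp=qp, ci=ci, t_leaf=t), p)
        vm = p.vcmax25 * p.q10_vm ** ((t - 25) / 10)
        expected = min(p.alpha4 * qp, vm, p.k_c4_effective * ci)
        assert rates.gross == pytest.approx(expected, rel=1e-14)


class TestCanopy:
    def test_zero_lai(self, default_params):
        assert canopy_daily_gpp(_day(), 0.0, default_params) == 0.0

    def test_negative_lai_raises(self, default_params):
        with pytest.raises(ValueError):
            canopy_daily_gpp(_day(), -1.0, default_params)

    def test_par_doubling_linear_under_light_limitation(self, default_params):
        low = canopy_daily_gpp(_day(par=2.0), 1.0, default_params)
        high = canopy_daily_gpp(_day(par=4.0), 1.0, default_params)
        assert high == pytest.approx(2 * low, rel=1e-12)

    def test_step_by_step_oracle(self):
        p = PhotoParams(vcmax25=40e-6)
        day, lai, k_ext, daylength = _day(t_avg=20.0, par=25.0), 3.0, 0.5, 14.0
        got = canopy_daily_gpp(day, lai, p, "C3", k_ext=k_ext, daylength_h=daylength)
        qp = day.par / (daylength * 3600.0) * (1 - math.exp(-k_ext * lai))
        rates = c3_gross_rate(LeafEnv(qp=qp, ci=p.ci_ca_c3 * p.ca, t_leaf=day.t_avg), p)
        expected = rates.gross * daylength * 3600.0 * GRAMS_C_PER_MOL
        assert got == pytest.approx(expected, rel=1e-10)

    def test_forward_gpp_matches_scalar_path(self, noise_free_site):
        config, series = noise_free_site
        from gppval.site_io import daily_values
        from gppval.solar import daylength_hours
        lai = daily_values(series, "lai")
        vec = forward_gpp(series, PhotoParams(vcmax25=config.true_vcmax), "C3")
        for i in (0, 100, 400, 700):
            rec = list(series.iter_records())[i]
            dl = float(daylength_hours(series.latitude, rec.date.timetuple().tm_yday))
            scalar = canopy_daily_gpp(rec, lai[i], PhotoParams(vcmax25=config.true_vcmax),
                                      "C3", daylength_h=dl)
            assert vec[i] == pytest.approx(scalar, rel=1e-12)


param_st = st.builds(
    PhotoParams,
    vcmax25=st.floats(1e-6, 200e-6),
    alpha3=st.floats(0.01, 0.1),
    tpu_ratio=st.floats(0.1, 1.0),
    ci_ca_c3=st.floats(0.3, 1.0),
)
env_st = st.builds(
    LeafEnv,
    qp=st.floats(0, 3000e-6),
    ci=st.floats(0, 600e-6),
    t_leaf=st.floats(-10, 45),
)


class TestProperties:
    @given(env=env_st, params=param_st)
    @settings(max_examples=150, deadline=None)
    def test_gross_is_min_and_nonnegative(self, env, params):
        for fn in (c3_gross_rate, c4_gross_rate):
            rates = fn(env, params)
            assert rates.gross == min(rates.je, rates.jc, rates.js)
            assert rates.gross >= 0
            assert rates.je >= 0 and rates.jc >= 0 and rates.js >= 0

    @given(env=env_st, params=param_st, factor=st.floats(1.01, 3.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_vcmax(self, env, params, factor):
        lo = c3_gross_rate(env, params).gross
        hi = c3_gross_rate(env, params.with_vcmax(params.vcmax25 * factor)).gross
        assert hi >= lo - 1e-18

    @given(env=env_st, params=param_st, factor=st.floats(1.01, 3.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_light(self, env, params, factor):
        brighter = LeafEnv(env.qp * factor, env.ci, env.t_leaf)
        assert (c3_gross_rate(brighter, params).gross
                >= c3_gross_rate(env, params).gross - 1e-18)
        assert (c4_gross_rate(brighter, params).gross
                >= c4_gross_rate(env, params).gross - 1e-18)

    @given(params=param_st, t=st.floats(-5, 40),
           ci_lo=st.floats(60e-6, 300e-6), factor=st.floats(1.01, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_ci_above_compensation(self, params, t, ci_lo, factor):
        gs = kinetics_at_temperature(params, t).gamma_star
        ci_lo = max(ci_lo, gs * 1.01)
        lo = c3_gross_rate(LeafEnv(500e-6, ci_lo, t), params).gross
        hi = c3_gross_rate(LeafEnv(500e-6, ci_lo * factor, t), params).gross
        assert hi >= lo - 1e-18


class TestSmoothing:
    def test_smooth_below_min(self, default_params):
        je, jc, js = 10e-6, 12e-6, 20e-6
        smooth = colimit_smooth(je, jc, js, 0.95, 0.98)
        assert smooth <= min(je, jc, js)
        assert smooth > 0

    def test_smooth_approaches_hard_min(self):
        je, jc, js = 10e-6, 12e-6, 20e-6
        smooth = colimit_smooth(je, jc, js, 0.999999, 0.999999)
        assert smooth == pytest.approx(min(je, jc, js), rel=1e-3)

    def test_canopy_smoothing_option(self, default_params):
        hard = canopy_daily_gpp(_day(), 2.0, default_params)
        soft = canopy_daily_gpp(_day(), 2.0, default_params, smoothing=(0.95, 0.98))
        assert soft <= hard
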