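"""Saturating enrichment curve and trophic-position estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import troposcale as ts
from troposcale.scaled import ScaledFrameworkError, UndefinedTPError


class TestDeriveScaledParams:
    @pytest.mark.parametrize(
        "beta0,beta1,lim,k",
        [
            (5.92, -0.27, 5.92 / 0.27, -math.log(0.73)),
            (6.0, -0.5, 12.0, math.log(2.0)),
        ],
    )
    def test_worked_values(self, beta0, beta1, lim, k):
        p = ts.derive_scaled_params(ts.DiscriminationLine(beta0, beta1))
        assert p.delta15N_lim == pytest.approx(lim, abs=1e-12)
        assert p.k == pytest.approx(k, abs=1e-12)

    def test_limit_is_fixed_point_of_step_recursion(self):
        # independent oracle: iterate x <- x + b0 + b1*x to convergence
        line = ts.DiscriminationLine(5.92, -0.27)
        p = ts.derive_scaled_params(line)
        x = 0.0
        for _ in range(2000):
            x = x + ts.predict_discrimination(line, x)
        assert x == pytest.approx(p.delta15N_lim, abs=1e-9)

    def test_constant_discrimination_limit(self):
        # beta1 -> 0-: limit diverges, rate vanishes, steps stay ~beta0
        p = ts.derive_scaled_params(ts.DiscriminationLine(5.92, -1e-9))
        assert p.delta15N_lim > 1e9
        assert p.k == pytest.approx(1e-9, rel=1e-3)

    @pytest.mark.parametrize("beta0,beta1", [(5.92, 0.0), (5.92, 0.1),
                                             (5.92, -1.0), (5.92, -1.5),
                                             (-1.0, -0.27)])
    def test_invalid_regimes_raise(self, beta0, beta1):
        with pytest.raises(ScaledFrameworkError):
            ts.derive_scaled_params(ts.DiscriminationLine(beta0, beta1))


class TestPredictDiscrimination:
    def test_intercept_at_zero_diet(self, line):
        assert ts.predict_discrimination(line, 0.0) == pytest.approx(5.92)

    def test_zero_at_saturating_limit(self, line, params):
        assert ts.predict_discrimination(line, params.delta15N_lim) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_arctic_baseline_value(self, line):
        assert ts.predict_discrimination(line, 10.2) == pytest.approx(3.166)


class TestForwardCurve:
    def test_one_step_from_sa_baseline(self, params, sa_base):
        # hand recursion: 5.2 + (5.92 - 0.27*5.2) = 9.716
        assert ts.delta15N_at_tp(params, sa_base, 3.0) == pytest.approx(9.716, abs=1e-9)

    def test_identity_at_baseline(self, params, sa_base):
        assert ts.delta15N_at_tp(params, sa_base, 2.0) == pytest.approx(5.2, abs=1e-12)

    def test_asymptote(self, params, sa_base):
        assert ts.delta15N_at_tp(params, sa_base, 1e6) == pytest.approx(
            params.delta15N_lim, abs=1e-9
        )

    def test_integer_steps_match_iterated_recursion(self, line, params, sa_base):
        x = sa_base.baseline_delta15N
        for n in range(1, 7):
            x = x + ts.predict_discrimination(line, x)
            closed = ts.delta15N_at_tp(params, sa_base, sa_base.baseline_tl + n)
            assert closed == pytest.approx(x, abs=1e-9)

    def test_extrapolation_below_baseline_warns(self, params, sa_base):
        with pytest.warns(UserWarning, match="below the baseline"):
            ts.delta15N_at_tp(params, sa_base, 1.5)

    def test_baseline_above_limit_rejected(self, params):
        bad = ts.BaselineSpec(baseline_delta15N=30.0, baseline_tl=2)
        with pytest.raises(ScaledFrameworkError):
            ts.delta15N_at_tp(params, bad, 3.0)


class TestScaledTP:
    def test_identity_at_baseline(self, params, sa_base):
        assert ts.tp_scaled(params, sa_base, 5.2).tp == pytest.approx(2.0, abs=1e-12)

    def test_inverse_of_forward_example(self, params, sa_base):
        assert ts.tp_scaled(params, sa_base, 9.716).tp == pytest.approx(3.0, abs=1e-9)

    def test_high_consumer_arctic(self, params, arctic_base):
        # closed form cross-checked below by bisection on the forward curve
        est = ts.tp_scaled(params, arctic_base, 18.8)
        assert est.tp == pytest.approx(6.201, abs=5e-4)
        lo, hi = 2.0, 30.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if ts.delta15N_at_tp(params, arctic_base, mid) < 18.8:
                lo = mid
            else:
                hi = mid
        assert est.tp == pytest.approx(0.5 * (lo + hi), abs=1e-9)

    def test_undefined_above_limit(self, params, sa_base):
        with pytest.raises(UndefinedTPError) as err:
            ts.tp_scaled(params, sa_base, params.delta15N_lim + 0.1)
        assert err.value.consumer_delta15N == pytest.approx(params.delta15N_lim + 0.1)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        beta0=st.floats(1.0, 10.0),
        beta1=st.floats(-0.9, -0.05),
        tp=st.floats(2.0, 8.0),
    )
    def test_roundtrip_property(self, beta0, beta1, tp):
        params = ts.derive_scaled_params(ts.DiscriminationLine(beta0, beta1))
        base = ts.BaselineSpec(baseline_delta15N=min(5.2, params.delta15N_lim - 1.0),
                               baseline_tl=2)
        d15n = ts.delta15N_at_tp(params, base, tp)
        assert ts.tp_scaled(params, base, float(d15n)).tp == pytest.approx(tp, abs=1e-9)

    def test_monotone_in_consumer_d15n(self, params, sa_base):
        grid = np.linspace(5.3, params.delta15N_lim - 0.01, 200)
        tps = [ts.tp_scaled(params, sa_base, x).tp for x in grid]
        assert np.all(np.diff(tps) > 0)


class TestAdditiveTP:
    def test_sa_tl2_worked_value(self, sa_base):
        assert ts.tp_additive(18.8, sa_base).tp == pytest.approx(6.0)

    def test_sa_tl3_worked_value(self):
        base3 = ts.BaselineSpec(baseline_delta15N=9.9, baseline_tl=3)
        assert ts.tp_additive(20.1, base3).tp == pytest.approx(6.0)

    def test_identity_at_baseline(self, sa_base):
        assert ts.tp_additive(5.2, sa_base).tp == pytest.approx(2.0)

    def test_nonpositive_delta_const_rejected(self, sa_base):
        with pytest.raises(ValueError):
            ts.tp_additive(10.0, sa_base, delta_const=0.0)


class TestFrameworkProperties:
    def test_additive_limit_of_scaled(self):
        # beta1 -> 0-: the scaled estimator degenerates to additive with
        # constant discrimination beta0
        line = ts.DiscriminationLine(5.92, -1e-6)
        params = ts.derive_scaled_params(line)
        base = ts.BaselineSpec(baseline_delta15N=5.2, baseline_tl=2)
        for d15n in np.linspace(5.2, 20.2, 40):
            scaled_tp = ts.tp_scaled(params, base, float(d15n)).tp
            additive_tp = ts.tp_additive(float(d15n), base, delta_const=5.92).tp
            assert abs(scaled_tp - additive_tp) < 1e-3

    def test_scaled_baseline_invariance(self, params, sa_base):
        # a TL3 baseline placed exactly on the curve gives identical TPs
        b3_val = float(ts.delta15N_at_tp(params, sa_base, 3.0))
        base3 = ts.BaselineSpec(baseline_delta15N=b3_val, baseline_tl=3)
        for d15n in np.linspace(9.8, 21.0, 25):
            tp2 = ts.tp_scaled(params, sa_base, float(d15n)).tp
            tp3 = ts.tp_scaled(params, base3, float(d15n)).tp
            assert tp2 == pytest.approx(tp3, abs=1e-9)

    def test_additive_baseline_discrepancy_closed_form(self):
        # TP(TL3 base) - TP(TL2 base) = 1 - (b3 - b2)/delta_const, constant
        b2 = ts.BaselineSpec(baseline_delta15N=5.2, baseline_tl=2)
        b3 = ts.BaselineSpec(baseline_delta15N=9.9, baseline_tl=3)
        expected = 1.0 - (9.9 - 5.2) / 3.4
        for d15n in (6.0, 12.5, 18.8, 25.0):
            diff = ts.tp_additive(d15n, b3).tp - ts.tp_additive(d15n, b2).tp
            assert diff == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-0.382, abs=5e-4)

    def test_per_step_discrimination_narrows(self, params, sa_base):
        d15n = np.array([ts.delta15N_at_tp(params, sa_base, t) for t in range(2, 9)])
        steps = np.diff(d15n)
        assert np.all(steps > 0)
        assert np.all(np.diff(steps) < 0)


class TestPosteriorPropagation:
    def test_degenerate_posterior_matches_point_estimate(self, params, sa_base):
        b0 = np.full(500, 5.92)
        b1 = np.full(500, -0.27)
        est = ts.tp_with_posterior(b0, b1, sa_base, 15.0)
        point = ts.tp_scaled(params, sa_base, 15.0).tp
        assert est.tp == pytest.approx(point, abs=1e-12)
        assert est.interval[0] == pytest.approx(est.interval[1], abs=1e-12)
        assert est.undefined_fraction == 0.0

    def test_interval_widens_toward_limit(self, sa_base):
        rng = np.random.default_rng(0)
        b1 = -0.27 + 0.03 * rng.standard_normal(4000)
        b0 = np.full_like(b1, 5.92)
        widths = []
        for d15n in (10.0, 14.0, 18.0, 20.5):
            est = ts.tp_with_posterior(b0, b1, sa_base, d15n)
            widths.append(est.interval[1] - est.interval[0])
        assert np.all(np.diff(widths) > 0)

    def test_undefined_fraction_counts_draws_below_consumer(self, sa_base):
        # 10% of draws put the saturating limit below the consumer value
        b0 = np.full(100, 5.92)
        b1 = np.full(100, -0.27)
        b1[:10] = -0.5  # limit 11.84 < consumer 15.0
        est = ts.tp_with_posterior(b0, b1, sa_base, 15.0)
        assert est.undefined_fraction == pytest.approx(0.10)

    def test_all_draws_undefined_raises(self, sa_base):
        with pytest.raises(UndefinedTPError):
            ts.tp_with_posterior([5.92], [-0.5], sa_base, 15.0)
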