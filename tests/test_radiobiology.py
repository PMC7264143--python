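"""Clonogenic survival math: PE, SF, LQ fits, iso-survival doses, mixture model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrtplan import (
    AssayRecord,
    LQParams,
    MixtureFieldSpec,
    SurvivalPoint,
    dose_at_survival,
    fit_lq,
    lq_survival,
    mixture_survival,
    plating_efficiency,
    rer,
    surviving_fraction,
)


def bisect_dose(params: LQParams, level: float, hi: float = 500.0) -> float:
    """Independent bisection oracle for the iso-survival dose."""
    lo = 0.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if lq_survival(params, mid) > level:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestPlatingEfficiency:
    def test_mean_over_dishes(self):
        rec = AssayRecord("c", 0.0, 100, (50, 60, 40))
        assert plating_efficiency(rec) == pytest.approx(0.5)

    def test_all_zero_colonies(self):
        assert plating_efficiency(AssayRecord("c", 0.0, 100, (0, 0, 0))) == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(condition="c", dose_gy=0.0, seeded=0, colonies=(1,)),
            dict(condition="c", dose_gy=-1.0, seeded=10, colonies=(1,)),
            dict(condition="c", dose_gy=0.0, seeded=10, colonies=()),
            dict(condition="c", dose_gy=0.0, seeded=10, colonies=(-1,)),
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AssayRecord(**kwargs)


class TestSurvivingFraction:
    def test_identity_when_pe_equal(self):
        rec = AssayRecord("c", 2.0, 100, (50, 50, 50))
        ctrl = AssayRecord("c", 0.0, 100, (50, 50, 50))
        assert surviving_fraction(rec, ctrl).sf == pytest.approx(1.0)

    def test_ratio_of_plating_efficiencies(self):
        irr = AssayRecord("c", 4.0, 1000, (50, 50, 50))
        ctrl = AssayRecord("c", 0.0, 100, (50, 50, 50))
        assert surviving_fraction(irr, ctrl).sf == pytest.approx(0.1)

    def test_zero_control_is_error(self):
        irr = AssayRecord("c", 4.0, 100, (10,))
        ctrl = AssayRecord("c", 0.0, 100, (0, 0))
        with pytest.raises(ValueError, match="control"):
            surviving_fraction(irr, ctrl)

    def test_spread_propagates_both_records(self):
        irr = AssayRecord("c", 4.0, 100, (40, 50, 60))
        ctrl = AssayRecord("c", 0.0, 100, (90, 100, 110))
        point = surviving_fraction(irr, ctrl)
        rel_i = np.std([40, 50, 60], ddof=1) / 50
        rel_c = np.std([90, 100, 110], ddof=1) / 100
        assert point.sf_sd == pytest.approx(point.sf * math.hypot(rel_i, rel_c))


class TestLQSurvival:
    def test_zero_dose_identity(self, lq_3t):
        assert lq_survival(lq_3t, 0.0) == 1.0

    @pytest.mark.parametrize("cond, dose", [("conventional", 11.02), ("3T", 2.74)])
    def test_ten_percent_survival_doses(self, cond, dose):
        # doses found by the independent bisection oracle on the fitted params
        from mrtplan.reference_params import LQ_9LGS

        params = LQ_9LGS[cond]
        assert lq_survival(params, dose) == pytest.approx(0.10, abs=5e-4)
        assert bisect_dose(params, 0.1) == pytest.approx(dose, abs=5e-3)

    def test_negative_dose_rejected(self, lq_2t):
        with pytest.raises(ValueError):
            lq_survival(lq_2t, -0.1)

    @given(dose=st.floats(0.01, 30), extra=st.floats(0.01, 5))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_decreasing_in_dose(self, dose, extra):
        p = LQParams(0.2, 0.01)
        assert lq_survival(p, dose + extra) < lq_survival(p, dose)


class TestDoseAtSurvival:
    def test_inverse_of_survival(self, lq_2t):
        for level in (0.5, 0.1, 0.01):
            d = dose_at_survival(lq_2t, level)
            assert lq_survival(lq_2t, d) == pytest.approx(level, abs=1e-10)

    def test_matches_bisection_oracle(self, lq_conventional):
        d = dose_at_survival(lq_conventional, 0.1)
        assert d == pytest.approx(11.02, abs=0.005)
        assert d == pytest.approx(bisect_dose(lq_conventional, 0.1), abs=1e-9)

    def test_pure_linear_closed_form(self):
        assert dose_at_survival(LQParams(math.log(10), 0.0), 0.1) == pytest.approx(1.0)

    def test_level_one_is_zero_dose(self, lq_2t):
        assert dose_at_survival(lq_2t, 1.0) == 0.0

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            dose_at_survival(LQParams(0.0, 0.0), 0.1)


class TestFitLQ:
    @pytest.mark.parametrize("cond", ["conventional", "2T", "3T"])
    def test_noiseless_recovery(self, cond):
        from mrtplan.reference_params import LQ_9LGS

        truth = LQ_9LGS[cond]
        points = [
            SurvivalPoint(d, lq_survival(truth, d)) for d in (1, 2, 3, 4, 6, 8)
        ]
        fit = fit_lq(points)
        assert fit.alpha == pytest.approx(truth.alpha, rel=1e-6)
        assert fit.beta == pytest.approx(truth.beta, rel=1e-6, abs=1e-9)

    def test_pure_linear_data_hits_beta_bound(self):
        truth = LQParams(0.4, 0.0)
        points = [SurvivalPoint(d, lq_survival(truth, d)) for d in (1, 2, 4, 8)]
        fit = fit_lq(points)
        assert fit.beta == 0.0
        assert fit.alpha == pytest.approx(0.4, rel=1e-9)

    def test_weighted_fit_uses_spreads(self):
        truth = LQParams(0.2, 0.02)
        points = [
            SurvivalPoint(d, lq_survival(truth, d), sf_sd=0.05 * lq_survival(truth, d))
            for d in (1, 2, 4, 6, 8)
        ]
        fit = fit_lq(points)
        assert fit.alpha == pytest.approx(0.2, rel=1e-6)
        assert fit.alpha_se > 0

    def test_insufficient_points_rejected(self):
        pts = [SurvivalPoint(1.0, 0.8), SurvivalPoint(2.0, 0.6)]
        with pytest.raises(ValueError):
            fit_lq(pts)

    def test_single_positive_dose_rejected(self):
        pts = [SurvivalPoint(2.0, 0.6)] * 3
        with pytest.raises(ValueError):
            fit_lq(pts)


class TestRER:
    def test_identity(self, lq_2t):
        assert rer(lq_2t, lq_2t) == pytest.approx(1.0)

    def test_published_2t_value(self, lq_conventional, lq_2t):
        assert round(rer(lq_conventional, lq_2t), 2) == 1.27

    def test_published_3t_value_within_uncertainty(self, lq_conventional, lq_3t):
        assert rer(lq_conventional, lq_3t) == pytest.approx(4.07, abs=0.28)

    def test_monotone_in_test_alpha(self, lq_conventional):
        lo = rer(lq_conventional, LQParams(0.2, 0.01))
        hi = rer(lq_conventional, LQParams(0.4, 0.01))
        assert hi > lo


class TestMixtureSurvival:
    def test_homogeneous_field_limit(self, lq_2t):
        field = MixtureFieldSpec(f_peak=0.3, pvdr=1.0)
        assert mixture_survival(lq_2t, field, 3.0) == pytest.approx(
            lq_survival(lq_2t, 3.0)
        )

    def test_no_peak_population_limit(self, lq_2t):
        field = MixtureFieldSpec(f_peak=0.0, pvdr=8.0)
        assert mixture_survival(lq_2t, field, 3.0) == pytest.approx(
            lq_survival(lq_2t, 3.0)
        )

    def test_direct_evaluation_oracle(self, lq_2t):
        # 0.875*exp(-0.3128) + 0.125*exp(-6.1312) evaluated independently
        expected = 0.875 * math.exp(-(0.124 * 2 + 0.0162 * 4)) + 0.125 * math.exp(
            -(0.124 * 16 + 0.0162 * 256)
        )
        got = mixture_survival(lq_2t, MixtureFieldSpec(0.125, 8.0), 2.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.640, abs=5e-4)

    @given(
        valley=st.floats(0.1, 10),
        f_peak=st.floats(0.01, 0.99),
        pvdr=st.floats(1.5, 50),
    )
    @settings(derandomize=True, max_examples=50)
    def test_peak_kill_never_raises_survival(self, valley, f_peak, pvdr, lq_2t):
        field = MixtureFieldSpec(f_peak=f_peak, pvdr=pvdr)
        assert mixture_survival(lq_2t, field, valley) <= lq_survival(lq_2t, valley)
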