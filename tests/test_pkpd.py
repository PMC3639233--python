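"""Unit and property tests for the PK profile and the PD effect map."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hybridrx as hx
from hybridrx.pkpd import period_breakpoints


@pytest.fixture
def three_stage():
    # peak 4.8, rise ends at 1, plateau ends at 5, elimination 0.3/time
    return hx.DoseRegimen(tau=12.0, dose=4.8, lambda_d=0.3, p1=1.0, p2=5.0)


@pytest.fixture
def saturating_pd():
    return hx.PDCurve(q=0.1, theta_lower=2.0, theta_upper=10.0)


class TestConcentration:
    def test_three_stage_piecewise_values(self, three_stage):
        reg = three_stage
        assert reg.concentration(0.0) == 0.0  # e^0 - 1
        assert reg.concentration(1.0) == pytest.approx(4.8)  # continuity at p1
        assert reg.concentration(3.0) == pytest.approx(4.8)  # plateau
        assert reg.concentration(5.0 + 2.0) == pytest.approx(4.8 * math.exp(-0.6))
        # periodic reset, no carry-over
        assert reg.concentration(12.0) == 0.0
        assert reg.concentration(24.0 + 0.5) == reg.concentration(0.5)

    def test_decay_only_starts_at_peak(self):
        reg = hx.DoseRegimen(tau=8.0, dose=24.0, lambda_d=0.5, profile="decay_only")
        assert reg.concentration(0.0) == 24.0
        assert reg.concentration(8.0) == 24.0  # reset at the dose instant
        assert reg.concentration(4.0) == pytest.approx(24.0 * math.exp(-2.0))

    def test_continuity_at_stage_boundaries(self, three_stage):
        for b in (three_stage.p1, three_stage.p2):
            lo = three_stage.concentration(b - 1e-12)
            hi = three_stage.concentration(b + 1e-12)
            assert hi == pytest.approx(lo, rel=1e-9)

    def test_negative_time_rejected(self, three_stage):
        with pytest.raises(ValueError):
            three_stage.concentration(-1.0)

    def test_conflicting_lambda_a_overridden_with_warning(self):
        with pytest.warns(UserWarning, match="lambda_a"):
            reg = hx.DoseRegimen(
                tau=12.0, dose=4.8, lambda_d=0.3, p1=1.0, p2=5.0, lambda_a=99.0
            )
        assert reg.lambda_a == pytest.approx(math.log(5.8))


class TestEffect:
    def test_piecewise_branches(self, saturating_pd):
        pd = saturating_pd
        assert pd.effect(1.0) == 0.0  # below MinED
        assert pd.effect(6.0) == pytest.approx(0.4)  # linear range
        assert pd.effect(50.0) == pytest.approx(0.8)  # saturated
        assert pd.saturated_effect == pytest.approx(0.8)

    def test_unsaturated_linear(self):
        pd = hx.PDCurve(q=0.21)
        assert pd.unsaturated
        assert pd.effect(3.0) == pytest.approx(0.63)

    @given(u=st.floats(0, 100), v=st.floats(0, 100))
    @settings(max_examples=200, derandomize=True)
    def test_effect_nondecreasing(self, u, v):
        pd = hx.PDCurve(q=0.1, theta_lower=2.0, theta_upper=10.0)
        lo, hi = sorted((u, v))
        assert pd.effect(lo) <= pd.effect(hi)
        assert pd.effect(min(lo, 1.9)) == 0.0


class TestEmaxApproximation:
    def test_derived_parameters(self):
        pd = hx.emax_to_pd(emax=1.0, ec50=5.0, m=4.0)
        assert pd.q == pytest.approx(0.2)
        assert pd.theta_lower == pytest.approx(2.5)
        assert pd.theta_upper == pytest.approx(7.5)
        # swing constraint holds by construction
        assert pd.saturated_effect == pytest.approx(1.0)

    def test_slope_matches_hill_derivative_at_ec50(self):
        emax, ec50, m = 1.0, 5.0, 4.0
        pd = hx.emax_to_pd(emax, ec50, m)
        h = 1e-6
        hill = lambda c: emax * c**m / (ec50**m + c**m)
        num_slope = (hill(ec50 + h) - hill(ec50 - h)) / (2 * h)
        assert pd.q == pytest.approx(num_slope, rel=1e-6)

    def test_sup_norm_against_hill_curve(self):
        """The worst-case deviation from the Hill curve sits at the MaxED
        corner, where the sigmoid has only reached ~83.5% of Emax; for m=4
        the sup-norm is 1 - (3/2)^4/(1+(3/2)^4) of Emax, about 0.165."""
        emax, ec50, m = 1.0, 5.0, 4.0
        pd = hx.emax_to_pd(emax, ec50, m)
        c = np.linspace(0, 2 * ec50, 2001)
        hill = emax * c**m / (ec50**m + c**m)
        sup = np.max(np.abs(pd.effect(c) - hill))
        corner = emax * (1.0 - 1.5**4 / (1.0 + 1.5**4))
        assert sup == pytest.approx(corner, abs=1e-3)
        assert sup < 0.17 * emax

    def test_negative_lower_threshold_clipped_with_width_preserved(self):
        with pytest.warns(UserWarning, match="MinED"):
            pd = hx.emax_to_pd(emax=1.0, ec50=5.0, m=1.0)  # shallow: lo would be < 0
        assert pd.theta_lower == 0.0
        assert pd.saturated_effect == pytest.approx(1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            hx.emax_to_pd(0.0, 5.0, 4.0)


class TestStageTimes:
    def test_scenario_a_crossings(self):
        # peak 24 above MaxED: all six stage times exist within a long period
        reg = hx.DoseRegimen(tau=12.0, dose=24.0, lambda_d=0.5, p1=1.0, p2=5.0)
        pd = hx.PDCurve(q=0.1, theta_lower=2.0, theta_upper=10.0)
        st_ = hx.stage_times(reg, pd)
        assert st_.scenario == "A"
        la = math.log(25.0)
        assert st_.t1 == pytest.approx(math.log(3.0) / la)
        assert st_.t2 == pytest.approx(math.log(11.0) / la)
        assert (st_.t3, st_.t4) == (1.0, 5.0)
        assert st_.t5 == pytest.approx(5.0 + math.log(2.4) / 0.5)
        assert st_.t6 == pytest.approx(st_.t5 + math.log(5.0) / 0.5)

    def test_scenario_b_skips_maxed_crossings(self):
        reg = hx.DoseRegimen(tau=12.0, dose=4.8, lambda_d=0.3, p1=1.0, p2=5.0)
        pd = hx.PDCurve(q=0.1, theta_lower=2.0, theta_upper=10.0)
        st_ = hx.stage_times(reg, pd)
        assert st_.scenario == "B"
        assert st_.t2 is None and st_.t5 is None
        assert st_.t1 == pytest.approx(math.log(3.0) / math.log(5.8))
        assert st_.t6 == pytest.approx(5.0 + math.log(2.4) / 0.3)

    def test_scenario_c_no_effective_stages(self):
        reg = hx.DoseRegimen(tau=12.0, dose=1.5, lambda_d=0.3, p1=1.0, p2=5.0)
        pd = hx.PDCurve(q=0.1, theta_lower=2.0, theta_upper=10.0)
        st_ = hx.stage_times(reg, pd)
        assert st_.scenario == "C"
        assert list(st_.times()) == []

    def test_decay_only_crossings(self):
        reg = hx.DoseRegimen(tau=8.0, dose=24.0, lambda_d=0.5, profile="decay_only")
        pd = hx.PDCurve(q=0.1, theta_lower=2.0, theta_upper=10.0)
        st_ = hx.stage_times(reg, pd)
        assert st_.scenario == "A"
        assert st_.t5 == pytest.approx(math.log(2.4) / 0.5)
        assert st_.t6 == pytest.approx(st_.t5 + math.log(5.0) / 0.5)

    @pytest.mark.parametrize("k", [0, 3])
    def test_crossing_times_satisfy_pk_law(self, k):
        """Cross-validation: concentration at each located time equals its threshold."""
        reg = hx.DoseRegimen(tau=14.0, dose=24.0, lambda_d=0.5, p1=1.0, p2=5.0)
        pd = hx.PDCurve(q=0.1, theta_lower=2.0, theta_upper=10.0)
        st_ = hx.stage_times(reg, pd, k)
        expected = {"t1": 2.0, "t2": 10.0, "t5": 10.0, "t6": 2.0}
        for name, t in st_.times():
            if name in expected:
                assert reg.concentration(t) == pytest.approx(
                    expected[name], rel=1e-9
                ), name

    def test_degenerate_zero_lower_threshold(self):
        reg = hx.DoseRegimen(tau=12.0, dose=4.8, lambda_d=0.3, p1=1.0, p2=5.0)
        pd = hx.PDCurve(q=0.1, theta_lower=0.0, theta_upper=10.0)
        st_ = hx.stage_times(reg, pd)
        assert st_.t1 == 0.0  # effective from the dose instant
        assert st_.t6 is None  # concentration never drops below 0

    def test_breakpoints_sorted_within_period(self):
        reg = hx.DoseRegimen(tau=14.0, dose=24.0, lambda_d=0.5, p1=1.0, p2=5.0)
        pd = hx.PDCurve(q=0.1, theta_lower=2.0, theta_upper=10.0)
        bps = period_breakpoints(reg, pd, 2)
        assert bps == sorted(bps)
        assert bps[0] == 28.0 and bps[-1] == 42.0


@pytest.mark.parametrize(
    "dose, tau, alpha",
    [(2.8, 7.0, 0.4), (4.8, 12.0, 0.4), (0.0, 5.0, 0.0)],
)
def test_dosing_density(dose, tau, alpha):
    assert hx.dosing_density(dose, tau) == pytest.approx(alpha)


def test_regimen_validation():
    with pytest.raises(ValueError, match="p1"):
        hx.DoseRegimen(tau=3.0, dose=1.0, lambda_d=0.3, p1=1.0, p2=5.0)
    with pytest.raises(ValueError, match="tau"):
        hx.DoseRegimen(tau=0.0, dose=1.0, lambda_d=0.3)
    with pytest.raises(ValueError, match="decay_only"):
        hx.DoseRegimen(tau=8.0, dose=1.0, lambda_d=0.3, p1=1.0, profile="decay_only")
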