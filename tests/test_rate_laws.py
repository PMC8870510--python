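"""Unit tests for the rate-law primitives: fixed-point examples and
monotonicity/boundedness properties."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from warburgsim import (
    activation_factor,
    default_parameters,
    etc_rate,
    inhibition_factor,
    load_rate,
    pfk_rate,
    reversible_mdh_rate,
    saturating_rate,
)

conc = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)
pos_conc = st.floats(min_value=1e-3, max_value=50.0, allow_nan=False)


@pytest.mark.parametrize(
    "vmax, km, s, expected",
    [
        (1.0, 1.0, 1.0, 0.5),       # half saturation
        (2.0, 1.0, 0.0, 0.0),       # no substrate, no flux
        (1.0, 0.5, 1e3, 1.0),       # saturated within 1e-3
    ],
)
def test_saturating_rate_examples(vmax, km, s, expected):
    assert saturating_rate(vmax, km, s) == pytest.approx(expected, abs=1e-3)


def test_saturating_rate_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        saturating_rate(1.0, 1.0, -0.1)
    with pytest.raises(ValueError):
        saturating_rate(1.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        saturating_rate(-1.0, 1.0, 1.0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(vmax=pos_conc, km=pos_conc, s1=conc, s2=conc)
def test_saturating_rate_bounded_and_monotone(vmax, km, s1, s2):
    lo, hi = sorted((s1, s2))
    r_lo, r_hi = saturating_rate(vmax, km, lo), saturating_rate(vmax, km, hi)
    assert 0.0 <= r_lo <= r_hi <= vmax


@pytest.mark.parametrize(
    "x, ki, n, expected",
    [
        (0.0, 2.0, 4.0, 1.0),
        (2.0, 2.0, 4.0, 0.5),     # half inhibition at x = ki
        (3.0, 3.0, 2.0, 0.5),
        (4.0, 2.0, 4.0, 1.0 / 17.0),
    ],
)
def test_inhibition_factor_examples(x, ki, n, expected):
    assert inhibition_factor(x, ki, n) == pytest.approx(expected, rel=1e-12)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(ki=pos_conc, n=st.floats(min_value=1, max_value=8), x1=conc, x2=conc)
def test_inhibition_strictly_decreasing(ki, n, x1, x2):
    lo, hi = sorted((x1, x2))
    f_lo, f_hi = inhibition_factor(lo, ki, n), inhibition_factor(hi, ki, n)
    assert 0.0 < f_hi <= f_lo <= 1.0
    if hi > lo:
        assert f_hi < f_lo


@pytest.mark.parametrize(
    "x, ka, n, amp, expected",
    [
        (0.0, 1.0, 2.0, 5.0, 1.0),
        (1.0, 1.0, 2.0, 5.0, 3.0),   # midpoint: 1 + (amp-1)/2
        (1e3, 1.0, 2.0, 5.0, 5.0),   # saturated within 1e-3
    ],
)
def test_activation_factor_examples(x, ka, n, amp, expected):
    assert activation_factor(x, ka, n, amp) == pytest.approx(expected, abs=1e-3)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(ka=pos_conc, amp=st.floats(min_value=1, max_value=30),
       x1=conc, x2=conc)
def test_activation_bounded_and_increasing(ka, amp, x1, x2):
    lo, hi = sorted((x1, x2))
    f_lo = activation_factor(lo, ka, 4.0, amp)
    f_hi = activation_factor(hi, ka, 4.0, amp)
    assert 1.0 <= f_lo <= f_hi <= amp


class TestPFK:
    def test_reduces_to_half_vmax_without_effectors(self):
        # at F6P = Km, saturating ATP and no FBP the allosteric factors are 1
        p = default_parameters()
        p.k_i_atp = 1e6  # effectively no inhibition in this construction
        km = p.km[("R3", "F6P")]
        rate = pfk_rate(km, 1e4, 0.0, p)
        assert rate == pytest.approx(0.5 * p.activity["PFK"] * p.vmax["R3"],
                                     rel=1e-3)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(atp1=st.floats(min_value=1.0, max_value=5.0),
           atp2=st.floats(min_value=1.0, max_value=5.0),
           f6p=pos_conc, fbp=conc)
    def test_decreasing_in_atp_where_inhibition_dominates(self, atp1, atp2, f6p, fbp):
        # above ~1 mM the allosteric Hill inhibition dominates the ATP
        # substrate factor; below that PFK is genuinely substrate-limited
        p = default_parameters()
        lo, hi = sorted((atp1, atp2))
        if hi - lo < 1e-9:
            return
        assert pfk_rate(f6p, hi, fbp, p) <= pfk_rate(f6p, lo, fbp, p)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(fbp1=conc, fbp2=conc, f6p=pos_conc,
           atp=st.floats(min_value=0.1, max_value=5.0))
    def test_increasing_in_fbp_and_f6p(self, fbp1, fbp2, f6p, atp):
        p = default_parameters()
        lo, hi = sorted((fbp1, fbp2))
        assert pfk_rate(f6p, atp, hi, p) >= pfk_rate(f6p, atp, lo, p)
        assert pfk_rate(2 * f6p, atp, lo, p) >= pfk_rate(f6p, atp, lo, p)


class TestReversibleMDH:
    def test_forward_only_without_products(self, params):
        assert reversible_mdh_rate(1.0, 0.0, 0.0, 1.0, params) > 0

    def test_no_forward_term_without_substrates(self, params):
        assert reversible_mdh_rate(0.0, 0.5, 0.5, 0.0, params) <= 0

    def test_zero_at_equilibrium_ratio(self, params):
        # net rate vanishes when (OAA*NADH)/(MAL*NAD) = kf/kr
        mal, nad = 0.8, 1.2
        nadh = 0.3
        oaa = params.mdh_kf * mal * nad / (params.mdh_kr * nadh)
        assert reversible_mdh_rate(mal, oaa, nadh, nad, params) == pytest.approx(
            0.0, abs=1e-12)

    def test_rejects_negative_concentrations(self, params):
        with pytest.raises(ValueError):
            reversible_mdh_rate(-1.0, 0.1, 0.1, 0.1, params)


class TestETC:
    def test_anoxia_shuts_the_chain(self):
        assert etc_rate(100.0, 0.1, 1.0, 0.0, 0.3, 2.0, 1.0) == 0.0

    def test_no_phosphate_acceptor_no_flux(self):
        assert etc_rate(100.0, 0.1, 1.0, 1.0, 0.3, 0.0, 1.0) == 0.0

    def test_increasing_in_carrier(self):
        rates = [etc_rate(100.0, 0.1, c, 0.8, 0.3, 2.0, 1.0)
                 for c in (0.01, 0.1, 0.5, 1.2)]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_rejects_oxygen_outside_unit_interval(self):
        with pytest.raises(ValueError):
            etc_rate(100.0, 0.1, 1.0, 1.5, 0.3, 2.0, 1.0)


def test_load_vanishes_at_zero_atp(params):
    assert load_rate(0.0, params) == 0.0
    assert load_rate(3.0, params) > 0


def test_load_monotone_in_atp(params):
    rates = [load_rate(a, params) for a in (0.1, 0.5, 1.0, 3.0, 5.0)]
    assert all(b > a for a, b in zip(rates, rates[1:]))
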