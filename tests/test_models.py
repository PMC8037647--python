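"""Forward-model unit and property tests, including equivalence to an
independent arbitrary-precision evaluation."""

import math

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

from rdsearch.models import (
    SINC_TERM_MAX,
    AngularConvention,
    CpmgProfile,
    FieldContext,
    ResidueDataset,
    ThreeStateParams,
    TwoStateParams,
    chi2_total,
    r2_eff,
    three_state_r2,
    two_state_r2,
)

from conftest import random_three_state


class TestR2Eff:
    @pytest.mark.parametrize(
        "i, i0, t, expected",
        [
            (100.0, 100.0, 0.06, 0.0),
            (100.0 * math.exp(-1.0), 100.0, 0.06, 1.0 / 0.06),
            (50.0, 100.0, 0.06, math.log(2.0) / 0.06),  # 11.5525 s^-1
        ],
    )
    def test_constant_time_decay(self, i, i0, t, expected):
        assert r2_eff(i, i0, t) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("kwargs", [
        {"intensity": -1.0, "intensity_ref": 1.0, "t_relax": 0.06},
        {"intensity": 1.0, "intensity_ref": 0.0, "t_relax": 0.06},
        {"intensity": 1.0, "intensity_ref": 1.0, "t_relax": -0.1},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            r2_eff(**kwargs)


class TestTwoStateModel:
    def test_zero_shift_gives_flat_baseline(self):
        p = TwoStateParams(r20=3.0, kex=500.0, dw_fc=0.0)
        nu = np.geomspace(25, 1000, 14)
        assert np.allclose(two_state_r2(p, nu), 3.0)

    def test_high_pulsing_limit_is_baseline(self):
        p = TwoStateParams(r20=1.5, kex=800.0, dw_fc=400.0)
        assert two_state_r2(p, 1e6 * p.kex) == pytest.approx(1.5, abs=1e-6)

    def test_low_pulsing_limit_is_full_amplitude(self):
        p = TwoStateParams(r20=0.0, kex=800.0, dw_fc=400.0)
        amp = p.p_f * p.p_c * p.dw_fc**2 / p.kex
        assert two_state_r2(p, 1e-4) == pytest.approx(amp, rel=1e-4)

    def test_monotone_nonincreasing_in_nu(self):
        rng = np.random.default_rng(7)
        nu = np.geomspace(1.0, 5000.0, 400)
        for _ in range(25):
            p = random_three_state(rng)
            vals = two_state_r2(TwoStateParams(p.r20, p.kex, p.dw_fc), nu)
            assert np.all(np.diff(vals) <= 1e-12)

    def test_radians_convention_scales_amplitude(self):
        p = TwoStateParams(r20=0.0, kex=800.0, dw_fc=100.0)
        hz = two_state_r2(p, 50.0, convention=AngularConvention.HZ_DIRECT)
        rad = two_state_r2(p, 50.0, convention=AngularConvention.RADIANS)
        assert rad == pytest.approx((2 * math.pi) ** 2 * hz, rel=1e-12)


class TestThreeStateModel:
    def test_reduces_to_two_state_without_slow_process(self):
        nu = np.geomspace(25, 1000, 14)
        base = ThreeStateParams(r20=2.0, kex=800.0, dw_fc=300.0, kzb=0.0, dw_bz=900.0)
        assert np.allclose(three_state_r2(base, nu),
                           two_state_r2(base, nu), atol=1e-14)
        tiny = ThreeStateParams(r20=2.0, kex=800.0, dw_fc=300.0, kzb=10.0, dw_bz=1e-12)
        assert np.allclose(three_state_r2(tiny, nu),
                           two_state_r2(tiny, nu), atol=1e-12)

    def test_sinc_zero_crossing_gives_full_slow_term(self):
        nu = 50.0
        p = ThreeStateParams(r20=0.0, kex=800.0, dw_fc=0.0, kzb=10.0,
                             dw_bz=4.0 * nu * math.pi)
        assert three_state_r2(p, nu) == pytest.approx(10.0, rel=1e-12)

    def test_slow_term_bounds_and_vanishing_at_high_nu(self):
        rng = np.random.default_rng(11)
        nu = np.geomspace(1.0, 5000.0, 300)
        for _ in range(25):
            p = random_three_state(rng)
            extra = three_state_r2(p, nu) - two_state_r2(p, nu)
            assert np.all(extra >= -1e-12)
            assert np.all(extra <= SINC_TERM_MAX * p.kzb + 1e-12)
        p = random_three_state(rng)
        extra_inf = three_state_r2(p, 1e8) - two_state_r2(p, 1e8)
        assert abs(extra_inf) < 1e-6


class TestFieldScaling:
    def test_dispersion_amplitude_scales_with_field_ratio_squared(self):
        p = TwoStateParams(r20=0.0, kex=800.0, dw_fc=400.0)
        f800 = FieldContext(800.0, reference_mhz=800.0)
        f900 = FieldContext(900.0, reference_mhz=800.0)
        nu = 1e-3
        assert (two_state_r2(p, nu, f900) / two_state_r2(p, nu, f800)
                == pytest.approx((900 / 800) ** 2, rel=1e-6))

    def test_at_field_round_trip(self):
        p = ThreeStateParams(r20=1.0, kex=500.0, dw_fc=400.0, kzb=5.0, dw_bz=800.0)
        back = p.at_field(900.0, 800.0).at_field(800.0, 900.0)
        assert back.dw_fc == pytest.approx(p.dw_fc, rel=1e-15)
        assert back.dw_bz == pytest.approx(p.dw_bz, rel=1e-15)
        assert back.kex == p.kex and back.kzb == p.kzb


def _make_dataset(rid, params, nu, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    profiles = []
    for mhz in (800.0, 900.0):
        f = FieldContext(mhz, reference_mhz=800.0)
        y = three_state_r2(params, nu, f) + (rng.normal(0, noise, nu.size) if noise else 0)
        profiles.append(CpmgProfile(rid, f, nu, np.asarray(y)))
    return ResidueDataset(rid, profiles)


class TestChi2Total:
    def test_zero_at_generating_parameters(self):
        nu = np.geomspace(25, 1000, 14)
        p = ThreeStateParams(r20=2.0, kex=900.0, dw_fc=390.0, kzb=9.9, dw_bz=1450.0)
        ds = _make_dataset("A", p, nu)
        assert chi2_total({"A": p}, [ds]) == pytest.approx(0.0, abs=1e-16)

    def test_single_point_residual(self):
        nu = np.array([100.0])
        p = ThreeStateParams(r20=0.0, kex=900.0, dw_fc=0.0, kzb=0.0, dw_bz=0.0)
        prof = CpmgProfile("A", FieldContext(800.0), nu, np.array([2.0]))
        ds = ResidueDataset("A", [prof])
        assert chi2_total({"A": p}, [ds]) == pytest.approx(4.0)

    def test_permutation_invariance(self):
        nu = np.geomspace(25, 1000, 14)
        rng = np.random.default_rng(3)
        params = {rid: random_three_state(rng) for rid in "ABC"}
        ds = [_make_dataset(rid, params[rid], nu, noise=0.4, seed=i)
              for i, rid in enumerate("ABC")]
        a = chi2_total(params, ds)
        b = chi2_total(params, ds[::-1])
        # shuffle points within a profile too
        perm = rng.permutation(14)
        ds2 = []
        for d in ds:
            profs = []
            for p in d.profiles:
                order = np.argsort(p.nu_cpmg[perm])
                profs.append(CpmgProfile(p.residue_id, p.field,
                                         p.nu_cpmg[perm][order],
                                         p.r2_eff[perm][order]))
            ds2.append(ResidueDataset(d.residue_id, profs))
        c = chi2_total(params, ds2)
        assert a == pytest.approx(b, rel=1e-14)
        assert a == pytest.approx(c, rel=1e-12)

    def test_mismatched_residue_sets_rejected(self):
        nu = np.geomspace(25, 1000, 5)
        p = ThreeStateParams(r20=0.0, kex=900.0, dw_fc=100.0)
        ds = _make_dataset("A", p, nu)
        with pytest.raises(ValueError, match="residue sets"):
            chi2_total({"B": p}, [ds])


def _oracle_value(p: ThreeStateParams, nu: float, ratio: float, factor: float):
    """Arbitrary-precision scalar evaluation via sympy."""
    R = sp.Rational
    w_fc = sp.Float(p.dw_fc, 50) * sp.Float(ratio, 50) * sp.Float(factor, 50)
    w_bz = sp.Float(p.dw_bz, 50) * sp.Float(ratio, 50) * sp.Float(factor, 50)
    kex, kzb = sp.Float(p.kex, 50), sp.Float(p.kzb, 50)
    nu_ = sp.Float(nu, 50)
    fast = (sp.Float(p.p_f, 50) * sp.Float(p.p_c, 50) * w_fc**2 / kex
            * (1 - (4 * nu_ / kex) * sp.tanh(kex / (4 * nu_))))
    x = w_bz / (4 * nu_)
    slow = kzb * (1 - sp.sin(x) / x) if p.dw_bz != 0 else sp.Integer(0)
    return float((sp.Float(p.r20, 50) + fast + slow).evalf(50))


@pytest.mark.parametrize("convention", list(AngularConvention))
def test_forward_models_match_high_precision_oracle(convention):
    """<= 1e-10 relative agreement on 100 random parameter sets."""
    rng = np.random.default_rng(2024)
    f900 = FieldContext(900.0, reference_mhz=800.0)
    for _ in range(100):
        p = random_three_state(rng)
        nu = float(rng.uniform(10.0, 1200.0))
        got = three_state_r2(p, nu, f900, convention)
        want = _oracle_value(p, nu, 900.0 / 800.0, convention.factor)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-10)


@settings(max_examples=60, derandomize=True)
@given(
    kex=st.floats(10.0, 3000.0),
    dw=st.floats(0.0, 1500.0),
    nu1=st.floats(5.0, 2000.0),
    nu2=st.floats(5.0, 2000.0),
)
def test_two_state_dispersion_decreases_with_pulsing_rate(kex, dw, nu1, nu2):
    p = TwoStateParams(r20=0.0, kex=kex, dw_fc=dw)
    lo, hi = sorted((nu1, nu2))
    assert two_state_r2(p, lo) >= two_state_r2(p, hi) - 1e-9
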