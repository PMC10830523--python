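"""Rectangular/parabolic channel hydrodynamics and force calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from padkin import flow

# Finite-width correction of the duct pressure-flow relation at w/h = 10,
# summed independently with mpmath at 40 digits (odd n to 20001):
# 1 / (1 - sum 192 h/(n^5 pi^5 w) tanh(n pi w / 2h)) = 1.0672642066968662
SERIES_FACTOR_W10 = 1.0672642066968662


class TestPressureDrop:
    def test_zero_flow(self, channel, water37):
        assert flow.pressure_drop_rect(0.0, channel, water37) == 0.0

    def test_wide_channel_limit_matches_2d(self, water37):
        geom = flow.ChannelGeometry(length=19e-3, width=1.0, h0=1e-4)
        dp = flow.pressure_drop_rect(1e-9, geom, water37)
        dp_2d = 12 * water37.eta * geom.length * 1e-9 / (geom.width * geom.h0**3)
        assert dp == pytest.approx(dp_2d, rel=1e-3)

    def test_series_factor_w_over_h_10(self, channel, water37):
        """At w/h = 10 the pressure drop exceeds the 2D value by the
        independently summed series factor."""
        dp = flow.pressure_drop_rect(25e-9, channel, water37)
        dp_2d = 12 * water37.eta * channel.length * 25e-9 / (channel.width * channel.h0**3)
        assert dp / dp_2d == pytest.approx(SERIES_FACTOR_W10, abs=1e-10)

    def test_monotone_in_q(self, channel, water37):
        qs = np.linspace(0, 50e-9, 11)
        dps = [flow.pressure_drop_rect(q, channel, water37) for q in qs]
        assert np.all(np.diff(dps) > 0)

    def test_invalid_geometry(self):
        with pytest.raises(flow.GeometryError):
            flow.ChannelGeometry(length=-1.0, width=1e-3, h0=1e-4)


class TestVelocityProfiles:
    def test_no_slip_walls(self, channel, water37):
        assert flow.velocity_profile_rect(0.0, 0.0, 25e-9, channel, water37) == 0.0
        assert flow.velocity_profile_rect(0.0, channel.h0, 25e-9, channel, water37) \
            == pytest.approx(0.0, abs=1e-12)

    def test_lattice_unit_center_velocity(self, channel, water37, lattice_scaling):
        """Center velocity converts to 0.053846 lattice units for the reference
        channel and Q = 25 uL/s."""
        v = flow.velocity_profile_rect(0.0, channel.h0 / 2, 25e-9, channel, water37)
        assert flow.to_sim_units(v, lattice_scaling) == pytest.approx(0.053846, abs=1e-5)

    def test_lattice_unit_particle_center_velocity(self, channel, water37, lattice_scaling):
        v = flow.velocity_profile_rect(0.0, 1.5e-6, 25e-9, channel, water37)
        assert flow.to_sim_units(v, lattice_scaling) == pytest.approx(0.003182, abs=1e-5)

    def test_outside_channel_raises(self, channel, water37):
        with pytest.raises(flow.GeometryError):
            flow.velocity_profile_rect(0.0, 2 * channel.h0, 1e-9, channel, water37)

    def test_2d_center_velocity(self, channel, water37):
        """v_max = 1.5 Q / (w h) = 0.375 m/s for Q = 25 uL/s."""
        v = flow.velocity_profile_2d(channel.h0 / 2, 25e-9, channel, water37)
        assert v == pytest.approx(0.375, rel=1e-12)

    def test_2d_at_particle_height(self, channel, water37):
        """6 Q r (h - r) / (w h^3) = 8.865e-4 m/s for Q = 1 uL/s, r = 1.5 um."""
        v = flow.velocity_profile_2d(1.5e-6, 1e-9, channel, water37)
        assert v == pytest.approx(8.865e-4, rel=1e-4)

    def test_center_ratio_3d_2d_equals_series_factor(self, channel, water37):
        """The finite-width correction of the center velocity equals the
        pressure-drop series factor (cosh suppression is ~1e-7 at w/h=10)."""
        v3 = flow.velocity_profile_rect(0.0, channel.h0 / 2, 25e-9, channel, water37)
        v2 = flow.velocity_profile_2d(channel.h0 / 2, 25e-9, channel, water37)
        assert v3 / v2 == pytest.approx(SERIES_FACTOR_W10, abs=1e-4)

    @pytest.mark.parametrize("w_over_h", [1, 10, 100])
    def test_cross_section_integral_recovers_q(self, water37, w_over_h):
        geom = flow.ChannelGeometry(length=19e-3, width=w_over_h * 1e-4, h0=1e-4)
        q = 25e-9
        assert flow.cross_section_flow(geom, water37, q) == pytest.approx(q, rel=1e-3)

    def test_2d_3d_ratio_tends_to_one(self, water37):
        """The 2D approximation becomes exact as w/h grows."""
        ratios = []
        for w_over_h in (10, 100, 1000):
            geom = flow.ChannelGeometry(length=19e-3, width=w_over_h * 1e-4, h0=1e-4)
            v3 = flow.velocity_profile_rect(0.0, geom.h0 / 2, 1e-9, geom, water37)
            v2 = flow.velocity_profile_2d(geom.h0 / 2, 1e-9, geom, water37)
            ratios.append(v3 / v2)
        assert np.all(np.diff(ratios) < 0)
        assert ratios[-1] == pytest.approx(1.0, abs=1e-3)

    def test_series_overflow_safe(self, water37):
        """Extreme aspect ratio: hyperbolic arguments far beyond float range."""
        geom = flow.ChannelGeometry(length=19e-3, width=1.0, h0=1e-6)
        v = flow.velocity_profile_rect(0.0, geom.h0 / 2, 1e-12, geom, water37)
        assert np.isfinite(v) and v > 0


class TestEffectiveHeightAndC1:
    def test_flat_lid(self):
        geom = flow.ChannelGeometry(length=1e-2, width=5e-3, h0=165e-6)
        assert flow.effective_height(geom) == pytest.approx(165e-6, rel=1e-14)
        assert flow.correction_c1(geom) == pytest.approx(1.0, rel=1e-12)

    def test_sagging_lid_lowers_h_eff(self):
        # 10 um lower at the side walls (y = +-w/2) than in the center
        w = 5e-3
        geom = flow.ChannelGeometry(length=1e-2, width=w, h0=165e-6,
                                    beta=-10e-6 / (w / 2) ** 2)
        assert flow.effective_height(geom) < geom.h0
        assert flow.correction_c1(geom) > 1.0

    def test_measured_channel_correction(self):
        """h0 = 165 um, h_eff = 155 um gives C1 about 1.2."""
        c1 = flow.correction_c1_from_heights(165e-6, 155e-6)
        assert c1 == pytest.approx(1.206, abs=0.001)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(alpha=st.floats(-0.002, 0.002), beta_um=st.floats(-15.0, 5.0))
    def test_closed_form_matches_quadrature(self, alpha, beta_um):
        """Cubic-mean height: closed form vs numerical quadrature, 1e-10 relative."""
        w, h0 = 5e-3, 165e-6
        beta = beta_um * 1e-6 / (w / 2) ** 2
        try:
            geom = flow.ChannelGeometry(length=1e-2, width=w, h0=h0,
                                        alpha=alpha, beta=beta)
        except flow.GeometryError:
            return
        val, _ = quad(lambda y: geom.height(y) ** 3, -w / 2, w / 2)
        assert flow.effective_height(geom) == pytest.approx((val / w) ** (1 / 3),
                                                            rel=1e-10)

    def test_approx_vs_exact_c1_wide_channel(self):
        """The wide-channel form agrees with the pressure-ratio form within 1%
        for w/h0 > 20."""
        w = 5e-3
        geom = flow.ChannelGeometry(length=1e-2, width=w, h0=165e-6,
                                    beta=-12e-6 / (w / 2) ** 2)
        approx = flow.correction_c1(geom)
        exact = flow.correction_c1(geom, exact=True)
        assert approx == pytest.approx(exact, rel=0.01)

    def test_parabolic_profile_reduces_to_rect(self, channel, water37):
        for z in (1.5e-6, 2.5e-5, 5e-5):
            vp = flow.velocity_profile_parabolic(0.0, z, 25e-9, channel, water37)
            vr = flow.velocity_profile_rect(0.0, z, 25e-9, channel, water37)
            assert vp == pytest.approx(vr, rel=1e-12)

    def test_sagging_lid_speeds_up_center(self, water37):
        w = 5e-3
        geom = flow.ChannelGeometry(length=1e-2, width=w, h0=165e-6,
                                    beta=-10e-6 / (w / 2) ** 2)
        rect = flow.ChannelGeometry(length=1e-2, width=w, h0=165e-6)
        z = 80e-6
        v_par = flow.velocity_profile_parabolic(0.0, z, 1e-9, geom, water37)
        v_rect = flow.velocity_profile_rect(0.0, z, 1e-9, rect, water37)
        assert v_par > v_rect
        # the center speed-up matches the pressure-ratio C1 closely
        assert v_par / v_rect == pytest.approx(flow.correction_c1(geom, exact=True),
                                               rel=1e-6)


class TestForceCalibration:
    def test_zero_flow_zero_force(self, channel, water37):
        assert flow.drag_force(0.0, channel, water37, 1.5e-6) == 0.0

    def test_uncorrected_force_at_1ul_per_s(self, channel, water37):
        """36 pi eta Q r^2 (h - r) / (w h^3) = 17.35 pN at Q = 1 uL/s."""
        f = flow.drag_force(1e-9, channel, water37, 1.5e-6, c1=1.0, c2=1.0)
        assert f == pytest.approx(1.735e-11, rel=1e-3)

    def test_linearity_in_q(self, channel, water37):
        """F(Q) over 0.1-50 uL/s: straight line through the origin."""
        qs = np.linspace(0.1e-9, 50e-9, 25)
        fs = np.array([flow.drag_force(q, channel, water37, 1.5e-6) for q in qs])
        slope, intercept = np.polyfit(qs, fs, 1)
        pred = slope * qs + intercept
        ss_res = np.sum((fs - pred) ** 2)
        ss_tot = np.sum((fs - fs.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999999
        assert abs(intercept) < 1e-12 * fs.max()

    def test_doubling_q_doubles_f(self, channel, water37):
        f1 = flow.drag_force(1e-9, channel, water37, 1.5e-6)
        f2 = flow.drag_force(2e-9, channel, water37, 1.5e-6)
        assert f2 == pytest.approx(2 * f1, rel=1e-14)

    def test_oversized_particle_rejected(self, channel, water37):
        with pytest.raises(flow.GeometryError):
            flow.drag_force(1e-9, channel, water37, channel.h0 / 2)

    def test_flow_rate_for_force_round_trip(self, channel, water37):
        q0 = 3.3e-9
        f = flow.drag_force(q0, channel, water37, 1.5e-6)
        assert flow.flow_rate_for_force(f, channel, water37, 1.5e-6) \
            == pytest.approx(q0, rel=1e-12)

    def test_flow_rate_for_50pn(self, channel, water37):
        """Uncorrected, 50 pN needs about 2.88 uL/s in the reference channel."""
        q = flow.flow_rate_for_force(50e-12, channel, water37, 1.5e-6, c1=1.0, c2=1.0)
        assert q == pytest.approx(2.88e-9, rel=2e-3)

    def test_motor_velocity(self):
        assert flow.motor_velocity(0.0, 6.135e-3) == 0.0
        r = 6.135e-3
        assert flow.motor_velocity(math.pi * r**2, r) == pytest.approx(1.0)
        assert flow.motor_velocity(2.88e-9, r) == pytest.approx(2.44e-5, rel=2e-3)


class TestUnitScaling:
    def test_zero_velocity(self, lattice_scaling):
        assert flow.to_sim_units(0.0, lattice_scaling) == 0.0

    def test_lattice_spacing(self, lattice_scaling):
        assert lattice_scaling.lattice_spacing == pytest.approx(1.5e-6 / 16)

    def test_nu_sim_rescaling_bound(self):
        """Holding v_sim fixed, nu_sim = 1 at 25 uL/s maps to exactly 250 at
        0.1 uL/s (the reported upper end of the viscosity sweep)."""
        assert flow.nu_sim_for_flow(0.1e-9, flow_rate_ref=25e-9) == pytest.approx(250.0)
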