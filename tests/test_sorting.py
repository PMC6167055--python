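"""Sorting ratio, tube-radius routes and coverage binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guvkit.sorting import (SortingMeasurement, bin_by_coverage, fit_rc,
                            radius_from_fluorescence, radius_from_force,
                            radius_from_tension, ratio_to_radius_anchor,
                            sorting_ratio)
from guvkit.units import KBT_J


class TestSortingRatio:
    def test_equal_channel_ratios_give_unity(self):
        m = SortingMeasurement(3.0, 10.0, 6.0, 20.0)
        assert sorting_ratio(m) == pytest.approx(1.0)

    def test_below_detection_maps_to_zero(self):
        m = SortingMeasurement(0.1, 10.0, 6.0, 20.0, below_detection=True)
        assert sorting_ratio(m) == 0.0

    def test_zero_vesicle_intensity_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            SortingMeasurement(3.0, 0.0, 6.0, 20.0)

    @settings(max_examples=25, deadline=None)
    @given(gain_p=st.floats(0.1, 100), gain_m=st.floats(0.1, 100))
    def test_per_channel_gain_invariance(self, gain_p, gain_m):
        base = SortingMeasurement(3.0, 10.0, 6.0, 20.0)
        scaled = SortingMeasurement(3.0 * gain_p, 10.0 * gain_p,
                                    6.0 * gain_m, 20.0 * gain_m)
        assert sorting_ratio(scaled) == pytest.approx(sorting_ratio(base),
                                                      rel=1e-9)


class TestRadiusRoutes:
    def test_tension_route_inverse_identity(self):
        r0, sigma = 50.0, 0.07  # nm, mN/m
        kappa = 2 * (sigma * 1e-3) * (r0 * 1e-9) ** 2
        assert radius_from_tension(kappa, sigma) == pytest.approx(r0)

    def test_tension_route_value(self):
        # kappa = 85 kBT, sigma = 0.07 mN/m -> ~50 nm
        assert radius_from_tension(85 * KBT_J, 0.07) == pytest.approx(50.0,
                                                                      rel=0.01)

    def test_quadrupling_tension_halves_radius(self):
        r1 = radius_from_tension(85 * KBT_J, 0.05)
        r2 = radius_from_tension(85 * KBT_J, 0.20)
        assert r1 == pytest.approx(2 * r2)

    def test_force_route_inverse_identity(self):
        r0, sigma = 25.0, 0.05
        f_pn = 4 * np.pi * (sigma * 1e-3) * (r0 * 1e-9) * 1e12
        assert radius_from_force(f_pn, sigma) == pytest.approx(r0)

    def test_force_route_value(self):
        # f = 12.57 pN at sigma = 0.05 mN/m -> ~20 nm
        assert radius_from_force(12.57, 0.05) == pytest.approx(20.0, rel=0.01)

    def test_fluorescence_route_values(self):
        assert radius_from_fluorescence(0.5, 200.0) == pytest.approx(100.0)
        assert radius_from_fluorescence(0.1, 312.0) == pytest.approx(31.2)
        r, sd = radius_from_fluorescence(0.5, 200.0, rc_sd_nm=50.0)
        assert (r, sd) == (pytest.approx(100.0), pytest.approx(25.0))

    @settings(max_examples=50, deadline=None)
    @given(r0=st.floats(10.0, 200.0), sigma=st.floats(0.01, 0.5))
    def test_three_routes_agree_on_self_consistent_inputs(self, r0, sigma):
        kappa = 2 * (sigma * 1e-3) * (r0 * 1e-9) ** 2
        f_pn = 4 * np.pi * (sigma * 1e-3) * (r0 * 1e-9) * 1e12
        rc, ratio = 200.0, r0 / 200.0
        rs = [radius_from_tension(kappa, sigma),
              radius_from_force(f_pn, sigma),
              radius_from_fluorescence(ratio, rc)]
        assert np.ptp(rs) < 1e-9 * r0

    @pytest.mark.parametrize("fn", [radius_from_tension, radius_from_force])
    def test_degenerate_inputs_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(1.0, 0.0)


class TestFitRc:
    def test_exact_line(self):
        pairs = [(r, 250.0 * r) for r in (0.1, 0.2, 0.4)]
        rc, sd = fit_rc(pairs)
        assert rc == pytest.approx(250.0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_two_collinear_points(self):
        rc, sd = fit_rc([(0.1, 20.0), (0.3, 60.0)])
        assert rc == pytest.approx(200.0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_ratios_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_rc([(0.0, 10.0), (0.0, 20.0)])

    def test_recovery_from_force_route_radii(self, rng):
        # reference radii from the force route at matched tensions
        rc_true = 200.0
        ratios = rng.uniform(0.05, 0.5, size=50)
        sigma = 0.05
        forces = 4 * np.pi * (sigma * 1e-3) * (rc_true * ratios * 1e-9) * 1e12
        radii = [radius_from_force(f, sigma) for f in forces]
        rc, _ = fit_rc(list(zip(ratios, radii)))
        assert rc == pytest.approx(rc_true, rel=1e-9)


def test_anchor_conversion_is_approximate_and_positive():
    assert ratio_to_radius_anchor(0.4) == pytest.approx(30.0, rel=0.15)
    with pytest.raises(ValueError):
        ratio_to_radius_anchor(0.0)


class TestBinByCoverage:
    def make(self, s, phi):
        below = s == 0
        return SortingMeasurement(s * 1.0 if not below else 0.0, 1.0, 1.0, 1.0,
                                  phi_v_percent=phi, below_detection=below)

    def test_low_coverage_lands_in_first_bin(self):
        out = bin_by_coverage([self.make(2.0, 1.0)])
        assert out["bin"].iloc[0] == "[0, 2)%"

    def test_all_below_detection_flagged(self):
        out = bin_by_coverage([self.make(0.0, 1.0), self.make(0.0, 1.5)])
        assert bool(out["no_detected_sorting"].iloc[0])
        assert out["n_below_detection"].iloc[0] == 2

    def test_zero_excluded_from_dispersion(self, rng):
        ss = rng.normal(2.0, 0.3, size=40)
        ms = [self.make(float(s), 1.0) for s in ss] + [self.make(0.0, 1.0)]
        out = bin_by_coverage(ms)
        se = 0.3 / np.sqrt(40)
        assert out["mean_S"].iloc[0] == pytest.approx(2.0, abs=2 * se + 0.05)
        assert out["n_below_detection"].iloc[0] == 1

    def test_coverage_outside_bins_is_unbinned(self):
        out = bin_by_coverage([self.make(1.0, 3.0)], bin_edges=(0.0, 2.0))
        assert out["bin"].iloc[0] == "unbinned"
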