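"""Generator correctness: seed determinism, closed-form values, degeneracies."""

import numpy as np
import pytest

from guvkit.pipeline import scene_sorting_ratio
from guvkit.synthetic import (FrapTruth, SyntheticScene, TetherTruth,
                              TitrationTruth, render_scene,
                              simulate_class_counts, simulate_frap,
                              simulate_tether_series, simulate_titration)


class TestSeedDeterminism:
    def test_scene_bit_identical(self):
        a, _ = render_scene(SyntheticScene(seed=42))
        b, _ = render_scene(SyntheticScene(seed=42))
        assert np.array_equal(a, b)

    def test_tables_bit_identical(self):
        t = TitrationTruth(seed=5)
        assert simulate_titration(t).equals(simulate_titration(t))
        f = FrapTruth(seed=5)
        assert simulate_frap(f).equals(simulate_frap(f))
        assert simulate_class_counts([0.5, 0.5], 40, seed=5).equals(
            simulate_class_counts([0.5, 0.5], 40, seed=5))

    def test_different_seed_differs(self):
        a, _ = render_scene(SyntheticScene(seed=1))
        b, _ = render_scene(SyntheticScene(seed=2))
        assert not np.array_equal(a, b)


class TestTitration:
    def test_midpoint_is_half_saturation(self):
        t = TitrationTruth(phi_max=12, kd=1.2, concentrations_um=[1.2],
                           noise_cv=0)
        assert simulate_titration(t)["phi_percent"].iloc[0] == pytest.approx(6.0)

    def test_hyperbola_value_at_4um(self):
        # 12 * 4 / (4 + 1.2) = 9.2307...
        t = TitrationTruth(phi_max=12, kd=1.2, concentrations_um=[4.0],
                           noise_cv=0)
        assert simulate_titration(t)["phi_percent"].iloc[0] == pytest.approx(
            12 * 4 / 5.2)

    def test_zero_concentration_zero_coverage(self):
        t = TitrationTruth(concentrations_um=[0.0], noise_cv=0)
        assert simulate_titration(t)["phi_percent"].iloc[0] == 0.0

    def test_empty_concentrations_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            TitrationTruth(concentrations_um=[])


class TestFrap:
    def test_immobile_trace_flat_after_correction(self):
        t = FrapTruth(mobile_fraction=0.0, noise_sd=0.0)
        df = simulate_frap(t)
        corrected = df["bleached"] / df["reference"]
        assert np.allclose(corrected, 0.0)

    def test_full_recovery_approaches_one(self):
        t = FrapTruth(mobile_fraction=1.0, recovery_tau_s=1.0, n_frames=100,
                      acq_bleach_rate=0.0, noise_sd=0.0)
        df = simulate_frap(t)
        assert df["bleached"].iloc[-1] / df["reference"].iloc[-1] \
            == pytest.approx(1.0, abs=1e-8)

    def test_shared_bleaching_in_both_channels(self):
        t = FrapTruth(mobile_fraction=0.5, acq_bleach_rate=0.01, noise_sd=0.0)
        df = simulate_frap(t)
        decay = df["reference"] / t.prebleach_level
        assert np.allclose(decay, (1 - 0.01) ** np.arange(t.n_frames))


class TestTetherSeries:
    def test_no_adhesion_no_contact_angle(self):
        t = TetherTruth(gamma_true_j_m2=0.0)
        df = simulate_tether_series(t, [0.05, 0.1, 0.2])
        assert np.allclose(df["theta_rad"], 0.0)

    def test_half_tension_gives_sixty_degrees(self):
        # gamma = sigma/2 -> cos(theta) = 1/2 -> theta = 60 deg
        t = TetherTruth(gamma_true_j_m2=0.05e-3)
        df = simulate_tether_series(t, [0.1])
        assert df["theta_rad"].iloc[0] == pytest.approx(np.pi / 3)

    def test_impossible_geometry_rejected(self):
        t = TetherTruth(gamma_true_j_m2=1e-4)
        with pytest.raises(ValueError, match="no contact angle"):
            simulate_tether_series(t, [0.05])  # 5e-5 N/m < gamma


class TestClassCounts:
    def test_degenerate_distribution(self):
        counts = simulate_class_counts([1.0, 0.0, 0.0], 60, seed=0)
        assert list(counts) == [60, 0, 0]

    def test_zero_tubes(self):
        assert simulate_class_counts([0.5, 0.5], 0, seed=0).sum() == 0

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            simulate_class_counts([1.0], -1, seed=0)

    def test_mean_counts_match_probabilities(self):
        # law of large numbers over 2000 draws at the nanotube class split
        p = (0.685, 0.065, 0.25)
        draws = np.array([simulate_class_counts(p, 60, seed=s).to_numpy()
                          for s in range(2000)])
        assert np.allclose(draws.mean(axis=0), np.array(p) * 60, atol=0.15)


class TestSceneRendering:
    def test_oversized_guv_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            render_scene(SyntheticScene(guv_radius_um=20.0))

    def test_guv_only_has_no_tube_roi(self):
        image, record = render_scene(SyntheticScene(scene_kind="guv_only"))
        assert "tube_profile_line" not in record
        with pytest.raises(ValueError, match="no tube ROI"):
            scene_sorting_ratio(image, record)

    def test_rendering_linearity_in_protein_gain(self):
        base = SyntheticScene(psf_sigma_px=0.0, noise_sd=0.0,
                              background_level=50.0)
        doubled = SyntheticScene(psf_sigma_px=0.0, noise_sd=0.0,
                                 background_level=50.0,
                                 gain_protein=2 * base.gain_protein)
        img1, rec1 = render_scene(base)
        img2, rec2 = render_scene(doubled)
        # protein channel above background doubles; membrane unchanged
        assert np.allclose(img2[1] - 50.0, 2 * (img1[1] - 50.0))
        assert np.array_equal(img1[0], img2[0])
        # sorting recovery is gain-invariant
        assert scene_sorting_ratio(img2, rec2) == pytest.approx(
            scene_sorting_ratio(img1, rec1), rel=1e-6)

    def test_noiseless_closure_of_sorting(self, noiseless_scene):
        _, image, record = noiseless_scene
        assert scene_sorting_ratio(image, record) == pytest.approx(1.0,
                                                                   rel=1e-6)

    def test_sorting_recovery_through_blur(self):
        scene = SyntheticScene(tube_ratio_membrane=0.4, sorting_true=8.0,
                               psf_sigma_px=1.0, noise_sd=1.0, seed=3)
        image, record = render_scene(scene)
        assert scene_sorting_ratio(image, record) == pytest.approx(8.0,
                                                                   rel=0.10)
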