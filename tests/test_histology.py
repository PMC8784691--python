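"""Histology quantification: segmentation, fractions, orientation, profiles."""

import numpy as np
import pytest
from skimage.transform import rotate

from rvbiomech import histology as hist
from rvbiomech import synthetic as syn
from rvbiomech.exceptions import ValidationError


def stripe_section(angle, frac=0.3, size=192, noise=0.0, seed=0):
    spec = syn.HistologySpec(
        n_sections=1, image_size=size, orientation_by_depth=angle,
        collagen_fraction_by_depth=frac, color_noise_sd=noise, seed=seed,
    )
    return syn.gen_histology_stack(spec).sections[0]


class TestSegmentation:
    def test_exact_colors_give_exact_masks(self):
        sec = stripe_section(30.0, frac=0.25)
        masks = hist.segment_trichrome(sec)
        truth = np.all(sec.rgb == syn.COLLAGEN_COLOR, axis=-1)
        assert np.array_equal(masks.collagen, truth)
        assert np.array_equal(masks.myofiber, ~truth)

    def test_all_white_image_empty_masks(self):
        white = np.full((64, 64, 3), 255, dtype=np.uint8)
        masks = hist.segment_trichrome(white)
        assert not masks.collagen.any() and not masks.myofiber.any()

    def test_noisy_image_per_phase_error_below_two_percent(self):
        sec = stripe_section(10.0, frac=0.3, noise=12.75)  # ~5% of 255
        masks = hist.segment_trichrome(sec)
        truth = np.all(
            np.abs(sec.rgb.astype(int) - np.array(syn.COLLAGEN_COLOR)) < 64, axis=-1
        )
        err = np.mean(masks.collagen != truth)
        assert err < 0.02

    def test_overlapping_thresholds_rejected(self):
        bad = hist.TrichromeThresholds(
            collagen=((0, 200), (0, 255), (100, 255)),
            myofiber=((100, 255), (0, 255), (0, 200)),
        )
        with pytest.raises(ValidationError, match="overlap"):
            bad.validate()

    def test_masks_disjoint(self):
        sec = stripe_section(-40.0, frac=0.4, noise=10.0)
        masks = hist.segment_trichrome(sec)
        assert not (masks.collagen & masks.myofiber).any()


class TestAreaFractions:
    def test_pixel_counting(self):
        sec = stripe_section(0.0, frac=0.3)
        c, m = hist.area_fractions(hist.segment_trichrome(sec))
        assert c == pytest.approx(30.0, abs=0.01)  # exact to pixel rounding
        assert m == pytest.approx(70.0, abs=0.01)

    def test_roi_ratio_invariance_on_uniform_mixture(self):
        rng = np.random.default_rng(0)
        rgb = np.where(
            rng.random((128, 128, 1)) < 0.2,
            np.array(syn.COLLAGEN_COLOR), np.array(syn.MYOFIBER_COLOR),
        ).astype(np.uint8)
        full = hist.area_fractions(hist.segment_trichrome(rgb))
        half_roi = np.zeros((128, 128), dtype=bool)
        half_roi[:, :64] = True
        half = hist.area_fractions(hist.segment_trichrome(rgb, roi=half_roi))
        assert half[0] == pytest.approx(full[0], abs=1.5)

    def test_integer_rescale_invariance(self):
        sec = stripe_section(25.0, frac=0.3, size=96)
        big = np.kron(sec.rgb, np.ones((2, 2, 1), dtype=np.uint8))
        a = hist.area_fractions(hist.segment_trichrome(sec))
        b = hist.area_fractions(hist.segment_trichrome(big))
        assert a[0] == pytest.approx(b[0], abs=1e-9)

    def test_empty_roi_rejected(self):
        sec = stripe_section(0.0)
        masks = hist.segment_trichrome(sec, roi=np.zeros(sec.rgb.shape[:2], bool))
        with pytest.raises(ValidationError):
            hist.area_fractions(masks)

    def test_fractions_sum_at_most_hundred(self):
        sec = stripe_section(60.0, frac=0.05, noise=15.0)
        c, m = hist.area_fractions(hist.segment_trichrome(sec))
        assert c + m <= 100.0 + 1e-9


class TestOrientationCoherency:
    @pytest.mark.parametrize("angle", [0.0, 30.0, -30.0, 45.0, -45.0, 90.0])
    def test_stripe_angle_recovered(self, angle):
        sec = stripe_section(angle, frac=0.3)
        mask = hist.segment_trichrome(sec).collagen
        est, coh = hist.orientation_coherency(mask)
        diff = abs((est - angle + 90.0) % 180.0 - 90.0)
        assert diff < 2.0
        assert coh > 90.0

    def test_rotation_equivariance(self):
        base = hist.segment_trichrome(stripe_section(0.0, frac=0.5, size=256)).collagen
        for theta in (20.0, 55.0):
            rot = rotate(base.astype(float), theta)[48:-48, 48:-48]
            est, _ = hist.orientation_coherency(rot)
            assert abs((est - theta + 90.0) % 180.0 - 90.0) < 2.0

    def test_intensity_scaling_invariance(self):
        g = hist.segment_trichrome(stripe_section(35.0, frac=0.4)).collagen.astype(float)
        a = hist.orientation_coherency(g)
        b = hist.orientation_coherency(10.0 * g)
        assert a[0] == pytest.approx(b[0], abs=1e-9)
        assert a[1] == pytest.approx(b[1], abs=1e-9)

    def test_isotropic_noise_low_coherency(self, rng):
        _, coh = hist.orientation_coherency(rng.random((192, 192)))
        assert coh < 10.0

    def test_uniform_image_undefined(self):
        angle, coh = hist.orientation_coherency(np.ones((100, 100)))
        assert np.isnan(angle) and coh == 0.0

    def test_small_image_rejected(self):
        with pytest.raises(ValidationError):
            hist.orientation_coherency(np.ones((10, 10)), sigma=4.0)

    def test_coherency_bounded(self, rng):
        for img in (rng.random((64, 64)), np.eye(64)):
            _, coh = hist.orientation_coherency(img, sigma=2.0)
            assert 0.0 <= coh <= 100.0


class TestTransmuralProfile:
    @staticmethod
    def metrics(depth, orient, collagen=3.4, coherency=50.0):
        return hist.SectionMetrics(
            collagen_fraction=collagen, myofiber_fraction=100 - collagen,
            orientation=orient, coherency=coherency, depth_um=depth,
        )

    def test_linear_interpolation_midpoint(self):
        prof = hist.transmural_profile(
            [self.metrics(0.0, 0.0), self.metrics(100.0, 40.0)]
        )
        mid = prof.table.loc[prof.table["thickness_pct"] == 50.0, "orientation"]
        assert float(mid.iloc[0]) == pytest.approx(20.0, abs=1e-9)

    def test_constant_metrics_constant_profile(self):
        prof = hist.transmural_profile(
            [self.metrics(d, 15.0) for d in (0, 30, 60, 90)]
        )
        assert np.allclose(prof.table["orientation"], 15.0)
        regions = prof.regions.set_index("region")
        assert regions.loc["Epi", "orientation"] == pytest.approx(15.0)
        assert regions.loc["Endo", "coherency"] == pytest.approx(50.0)

    def test_single_section_rejected(self):
        with pytest.raises(ValidationError):
            hist.transmural_profile([self.metrics(0.0, 0.0)])

    def test_axial_wraparound_interpolation(self):
        """Interpolating between +80 and -80 deg must cross 90, not 0."""
        prof = hist.transmural_profile(
            [self.metrics(0.0, 80.0), self.metrics(100.0, -80.0)]
        )
        mid = float(
            prof.table.loc[prof.table["thickness_pct"] == 50.0, "orientation"].iloc[0]
        )
        assert abs(abs(mid) - 90.0) < 1e-6

    def test_generator_ramp_recovered_within_two_degrees(self):
        ramp = lambda d: 45.0 * d
        stack = syn.gen_histology_stack(
            syn.HistologySpec(
                n_sections=11, image_size=160, orientation_by_depth=ramp,
                collagen_fraction_by_depth=0.3, seed=2,
            )
        )
        metrics = hist.analyze_stack(stack.sections, orientation_phase="collagen")
        prof = hist.transmural_profile(metrics)
        expected = 45.0 * prof.table["thickness_pct"].to_numpy() / 100.0
        diff = np.abs(
            (prof.table["orientation"].to_numpy() - expected + 90.0) % 180.0 - 90.0
        )
        assert np.all(diff < 2.0)
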