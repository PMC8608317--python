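"""Band decomposition and the CSF threshold filter."""

import numpy as np
import pytest

from conftest import make_grating
from hazvis.exceptions import ConfigurationError, InvalidInputError
from hazvis.filtering import (
    FilterConfig,
    LuminanceImage,
    apply_lowvision_filter,
    band_contrast,
    count_suprathreshold_pixels,
    decompose_bands,
)
from hazvis.vision import VisionParams, build_csf


class TestLuminanceImage:
    def test_rejects_negative(self):
        with pytest.raises(InvalidInputError):
            LuminanceImage(np.full((4, 4), -1.0), 10.0)

    def test_rejects_nonfinite(self):
        bad = np.ones((4, 4))
        bad[0, 0] = np.nan
        with pytest.raises(InvalidInputError):
            LuminanceImage(bad, 10.0)

    def test_rejects_bad_ppd(self):
        with pytest.raises(InvalidInputError):
            LuminanceImage(np.ones((4, 4)), 0.0)


class TestDecomposeBands:
    def test_uniform_image_all_in_baseband(self):
        img = LuminanceImage(np.full((64, 64), 50.0), 16.0)
        stack = decompose_bands(img)
        for band in stack.bands:
            assert np.max(np.abs(band)) < 1e-9 * 50.0
        np.testing.assert_allclose(stack.baseband, img.values, rtol=1e-9)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(7)
        img = LuminanceImage(rng.uniform(1, 200, (96, 80)), 20.0)
        stack = decompose_bands(img)
        err = np.max(np.abs(stack.reconstruct() - img.values))
        assert err < 1e-6 * img.values.mean()

    def test_grating_energy_in_matching_band(self):
        img = make_grating(frequency_cpd=2.0, contrast=0.5)
        stack = decompose_bands(img)
        energies = [float(np.sum(b**2)) for b in stack.bands]
        best = stack.centers[int(np.argmax(energies))]
        # the 2 cpd grating lands in the band whose center is nearest 2 cpd
        nearest = min(stack.centers, key=lambda c: abs(np.log2(c / 2.0)))
        assert best == nearest
        assert max(energies) > 0.5 * sum(energies)

    def test_centers_octave_spaced_below_nyquist(self):
        img = LuminanceImage(np.ones((128, 128)), 20.0)
        stack = decompose_bands(img)
        ratios = np.diff(np.log2(stack.centers))
        np.testing.assert_allclose(ratios, 1.0, atol=1e-9)
        assert stack.centers[-1] <= img.nyquist

    def test_too_many_bands_rejected(self):
        img = LuminanceImage(np.ones((32, 32)), 8.0)
        with pytest.raises(ConfigurationError):
            decompose_bands(img, n_bands=12)


class TestBandContrast:
    def test_zero_band_zero_contrast(self):
        c = band_contrast(np.zeros((8, 8)), np.full((8, 8), 10.0))
        assert np.all(c == 0)

    def test_grating_contrast_amplitude(self):
        """A sinusoid of Michelson contrast c has band-limited contrast
        amplitude close to c."""
        img = make_grating(frequency_cpd=2.0, contrast=0.3)
        stack = decompose_bands(img)
        k = int(np.argmin([abs(np.log2(c / 2.0)) for c in stack.centers]))
        contrast = band_contrast(stack.bands[k], stack.lowpasses[k])
        # interior amplitude (edges suffer from padding transitions)
        interior = contrast[32:-32, 32:-32]
        assert np.max(np.abs(interior)) == pytest.approx(0.3, rel=0.15)

    def test_luminance_scale_invariance(self):
        img = make_grating(frequency_cpd=2.0, contrast=0.4, mean=50.0)
        img2 = LuminanceImage(img.values * 2.0, img.ppd)
        s1, s2 = decompose_bands(img), decompose_bands(img2)
        c1 = band_contrast(s1.bands[-1], s1.lowpasses[-1])
        c2 = band_contrast(s2.bands[-1], s2.lowpasses[-1])
        np.testing.assert_allclose(c1, c2, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            band_contrast(np.zeros((4, 4)), np.ones((5, 5)))


class TestLowVisionFilter:
    def test_normal_vision_near_identity(self, step_render, normal_csf):
        out = apply_lowvision_filter(step_render.luminance, normal_csf)
        corr = np.corrcoef(out.values.ravel(), step_render.luminance.values.ravel())[0, 1]
        assert corr > 0.99

    def test_grating_above_cutoff_removed(self):
        """A 10 cpd grating is invisible to a viewer whose cutoff is 3 cpd."""
        img = make_grating(frequency_cpd=10.0, contrast=0.05, mean=80.0, ppd=32.0)
        csf = build_csf(VisionParams(1.0, 1.0))  # cutoff 3 cpd
        out = apply_lowvision_filter(img, csf)
        interior = out.values[16:-16, 16:-16]
        assert np.ptp(interior) < 0.02 * 80.0
        assert interior.mean() == pytest.approx(80.0, rel=0.02)

    def test_mean_luminance_preserved(self, step_render, severe_vision):
        csf = build_csf(severe_vision)
        out = apply_lowvision_filter(step_render.luminance, csf)
        assert out.values.mean() == pytest.approx(step_render.luminance.values.mean(), rel=0.01)

    def test_fewer_edges_after_severe_filtering(self, step_render, severe_vision):
        """Severe low vision leaves strictly fewer detectable boundaries."""
        from hazvis.boundaries import detect_luminance_boundaries

        csf = build_csf(severe_vision)
        filtered = apply_lowvision_filter(step_render.luminance, csf)
        n_raw = detect_luminance_boundaries(step_render.luminance).n_pixels
        n_filt = detect_luminance_boundaries(
            filtered, reference=step_render.luminance
        ).n_pixels
        assert 0 <= n_filt < n_raw

    @pytest.mark.parametrize("soft", [True, False])
    def test_monotone_in_acuity(self, step_render, soft):
        """Worsening acuity (CS fixed) never increases the count of
        above-threshold band pixels."""
        config = FilterConfig(soft_threshold=soft)
        counts = [
            count_suprathreshold_pixels(
                step_render.luminance, build_csf(VisionParams(a, 0.68)), config
            )
            for a in (0.0, 0.6, 1.2, 1.62)
        ]
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_uniform_image_is_fixed_point(self, normal_csf):
        img = LuminanceImage(np.full((64, 64), 90.0), 16.0)
        out = apply_lowvision_filter(img, normal_csf)
        np.testing.assert_allclose(out.values, img.values, rtol=1e-9)

    def test_idempotent_when_nothing_retained(self, severe_vision, rng):
        """A scene whose oscillatory content is entirely subthreshold maps
        to its smooth baseband, which the filter then leaves (nearly)
        unchanged: the filter is idempotent at its fixed points."""
        x = np.linspace(0, 1, 96)
        smooth = 60.0 + 30.0 * x[None, :] + 10.0 * x[:, None]
        noisy = smooth * (1.0 + 0.002 * rng.standard_normal((96, 96)))
        img = LuminanceImage(noisy, 16.0)
        csf = build_csf(severe_vision)
        once = apply_lowvision_filter(img, csf)
        twice = apply_lowvision_filter(once, csf)
        assert np.max(np.abs(twice.values - once.values)) < 0.01 * smooth.mean()

    def test_iteration_contracts_to_fixed_point(self, step_render, moderate_vision):
        """Repeated filtering converges: each pass changes the image less
        (one-step idempotence is impossible for a threshold filter, since
        band content near its zero crossings is always subthreshold)."""
        csf = build_csf(moderate_vision)
        x = step_render.luminance
        changes = []
        for _ in range(5):
            nxt = apply_lowvision_filter(x, csf)
            changes.append(float(np.max(np.abs(nxt.values - x.values))))
            x = nxt
        assert changes[-1] < 0.1 * changes[0]
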