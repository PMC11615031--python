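"""Feature operators on constructed images with analytic ground truth:
surface detection, layering, hyperreflectivity, effacement, irregularity,
imaging depth and the attenuation estimator."""

import numpy as np
import pytest

import coloct
from coloct.features import (FeatureConfig, SurfaceUndefinedError,
                             attenuation_coefficient, detect_surface,
                             effacement, hyperreflectivity, imaging_depth,
                             segment_layers, surface_irregularity)


PITCH = 0.005  # mm per pixel of constructed images


def make_image(surface_mm, depth_mm=2.0, width=80, amp_surface=1.0,
               mu=1.5, noise_amp=1e-4, band=None, sub=None, rng=None,
               gain_profile=None):
    """Synthetic Cartesian image: background above an exponential-decay
    tissue block below per-column ``surface_mm``; optional bright band
    (top, bottom, linear gain) and distinct submucosa (top, mu, gain)."""
    rng = rng or np.random.default_rng(0)
    nrows = int(depth_mm / PITCH)
    z = np.arange(nrows) * PITCH
    surface = np.broadcast_to(np.asarray(surface_mm, float), (width,))
    img = np.full((nrows, width), noise_amp)
    img += rng.normal(0, noise_amp / 4, img.shape)
    img = np.abs(img)
    for c in range(width):
        s = surface[c]
        depth = z - s
        tissue = depth >= 0
        a = amp_surface * np.exp(-mu * depth[tissue])
        if gain_profile is not None:
            a = a * gain_profile(depth[tissue])
        if sub is not None:
            sub_top, sub_mu, sub_gain = sub
            deep = depth[tissue] >= sub_top
            a[deep] = (amp_surface * sub_gain
                       * np.exp(-mu * sub_top
                                - sub_mu * (depth[tissue][deep] - sub_top)))
        if band is not None:
            top, bot, band_gain = band
            in_band = (depth[tissue] >= top) & (depth[tissue] < bot)
            a[in_band] *= band_gain
        img[tissue, c] = np.maximum(a, noise_amp)
    return coloct.CartesianImage(img, PITCH, origin=(0.0, 0.0))


class TestDetectSurface:
    def test_flat_surface_recovered_within_two_pixels(self):
        img = make_image(0.4)
        s = detect_surface(img)
        ok = ~np.isnan(s)
        assert ok.mean() > 0.9
        assert np.all(np.abs(s[ok] - 0.4) <= 2 * PITCH + 1e-9)

    def test_pure_noise_is_undefined(self):
        rng = np.random.default_rng(1)
        img = coloct.CartesianImage(
            np.abs(rng.normal(0, 1e-4, (200, 60))), PITCH, (0.0, 0.0))
        with pytest.raises(SurfaceUndefinedError):
            detect_surface(img)

    def test_sinusoidal_surface_tracks_truth(self):
        cols = np.arange(120)
        truth = 0.5 + 0.1 * np.sin(2 * np.pi * cols / 60.0)
        img = make_image(truth, width=120)
        s = detect_surface(img)
        ok = ~np.isnan(s)
        r = np.corrcoef(s[ok], truth[ok])[0, 1]
        assert r > 0.95


class TestSegmentLayers:
    def test_band_found_and_located(self):
        img = make_image(0.4, band=(0.3, 0.4, 3.0), sub=(0.4, 2.0, 1.0))
        s = detect_surface(img)
        seg = segment_layers(img, s)
        assert seg.band_fraction >= 0.9
        ok = ~np.isnan(seg.lpmm_band[0])
        # band top within 3 pixels of truth (surface + 0.3)
        assert np.nanmedian(np.abs(seg.lpmm_band[0][ok] - 0.7)) <= 3 * PITCH

    def test_uniform_interior_has_no_band(self):
        img = make_image(0.4)
        s = detect_surface(img)
        seg = segment_layers(img, s)
        assert seg.band_fraction < 0.2
        assert np.all(seg.quality <= 0.5)
        assert effacement(seg) is True

    def test_masks_are_disjoint(self):
        img = make_image(0.4, band=(0.3, 0.4, 3.0), sub=(0.4, 2.0, 1.0))
        seg = segment_layers(img, detect_surface(img))
        assert not np.any(seg.epithelium_mask & seg.submucosa_mask)


class TestHyperreflectivity:
    def test_equal_backscatter_compensates_to_zero(self):
        cfg = FeatureConfig(attenuation_compensation=True)
        img = make_image(0.4, mu=1.5, sub=(0.4, 1.5, 1.0))
        seg = segment_layers(img, detect_surface(img, cfg), cfg)
        ratio, flag = hyperreflectivity(img, seg, cfg)
        assert abs(ratio) <= 1.0
        assert flag is False

    def test_double_backscatter_reads_three_db(self):
        cfg = FeatureConfig(attenuation_compensation=True)
        # epithelium amplitude x sqrt(2) = backscatter x 2 = +3 dB
        img = make_image(0.4, mu=1.5, amp_surface=np.sqrt(2.0),
                         sub=(0.4, 2.0, 1.0 / np.sqrt(2.0) * np.sqrt(2.0)))
        # build: sub gain relative to amp_surface; want sub amplitude = 1.0
        img2 = make_image(0.4, mu=1.5, amp_surface=np.sqrt(2.0),
                          sub=(0.4, 2.0, 1.0 / np.sqrt(2.0)))
        seg = segment_layers(img2, detect_surface(img2, cfg), cfg)
        ratio, flag = hyperreflectivity(img2, seg, cfg)
        assert ratio == pytest.approx(3.0, abs=1.0)
        assert flag is False or ratio > 3.0  # flag consistent with threshold

    def test_constant_image_gives_exactly_zero_uncompensated(self):
        img = coloct.CartesianImage(np.full((100, 40), 0.5), PITCH,
                                    (0.0, 0.0))
        epi = np.zeros((100, 40), bool)
        sub = np.zeros((100, 40), bool)
        epi[10:30] = True
        sub[50:80] = True
        seg = coloct.LayerSegmentation(
            surface_depth=np.full(40, 0.05),
            lpmm_band=np.full((2, 40), np.nan), epithelium_mask=epi,
            submucosa_mask=sub, quality=np.ones(40))
        cfg = FeatureConfig(attenuation_compensation=False,
                            axial_smooth_px=0, lateral_smooth_px=0)
        ratio, flag = hyperreflectivity(img, seg, cfg)
        assert ratio == pytest.approx(0.0, abs=1e-12)
        assert flag is False

    def test_monotone_in_epithelial_gain(self):
        cfg = FeatureConfig(attenuation_compensation=True)
        ratios = []
        for gain in (1.0, 1.5, 2.0, 3.0, 4.0):
            img = make_image(0.4, mu=1.5, amp_surface=np.sqrt(gain),
                             sub=(0.4, 2.0, 1.0 / np.sqrt(gain)))
            seg = segment_layers(img, detect_surface(img, cfg), cfg)
            ratios.append(hyperreflectivity(img, seg, cfg)[0])
        assert np.all(np.diff(ratios) > -0.25)  # non-decreasing up to noise
        assert ratios[-1] > ratios[0] + 4.0


class TestEffacement:
    def test_boundary_is_strict(self):
        surf = np.zeros(10)
        band = np.full((2, 10), np.nan)
        band[:, :3] = [[0.3]] * 2  # exactly at the 0.3 default threshold
        seg = coloct.LayerSegmentation(
            surface_depth=surf, lpmm_band=band,
            epithelium_mask=np.zeros((5, 10), bool),
            submucosa_mask=np.zeros((5, 10), bool), quality=np.ones(10))
        assert seg.band_fraction == pytest.approx(0.3)
        assert effacement(seg) is False  # strict <


class TestSurfaceIrregularity:
    def _smooth(self, n=80):
        x = np.arange(n)
        return 0.5 + 1e-4 * x  # gentle tilt, quadratic removes it

    def _rough(self, rng, n=80, amp=0.05):
        return self._smooth(n) + rng.normal(0, amp, n)

    def test_all_smooth_set(self):
        frac, flag = surface_irregularity([self._smooth() for _ in range(5)])
        assert frac == 0.0 and flag is False

    def test_six_of_ten_rough(self):
        rng = np.random.default_rng(2)
        profiles = [self._rough(rng) for _ in range(6)] \
            + [self._smooth() for _ in range(4)]
        frac, flag = surface_irregularity(profiles)
        assert frac == pytest.approx(0.6)
        assert flag is True

    def test_half_is_irregular(self):
        """'At least 50%' means a fraction of exactly 0.5 flags true."""
        rng = np.random.default_rng(3)
        profiles = [self._rough(rng) for _ in range(5)] \
            + [self._smooth() for _ in range(5)]
        frac, flag = surface_irregularity(profiles)
        assert frac == pytest.approx(0.5)
        assert flag is True

    def test_monotone_in_roughness_amplitude(self):
        rng = np.random.default_rng(4)
        fracs = []
        for amp in (0.0, 0.01, 0.02, 0.04, 0.08):
            profiles = [self._smooth() + rng.normal(0, amp, 80)
                        for _ in range(8)]
            fracs.append(surface_irregularity(profiles)[0])
        assert np.all(np.diff(fracs) >= 0)

    def test_all_undefined_raises(self):
        with pytest.raises(SurfaceUndefinedError):
            surface_irregularity([np.full(20, np.nan)])


class TestImagingDepth:
    def test_shallow_block_measured_to_its_thickness(self):
        # non-attenuating bright block 0.6 mm thick over noise
        img = make_image(0.3, mu=0.0, depth_mm=2.0,
                         gain_profile=lambda d: (d < 0.6).astype(float))
        d = imaging_depth(img)
        assert d == pytest.approx(0.6, abs=0.05)

    def test_pure_noise_undefined(self):
        rng = np.random.default_rng(5)
        img = coloct.CartesianImage(
            np.abs(rng.normal(0, 1e-4, (200, 60))), PITCH, (0.0, 0.0))
        with pytest.raises(SurfaceUndefinedError):
            imaging_depth(img)


class TestAttenuationCoefficient:
    @pytest.mark.parametrize("mu", [0.5, 1.0, 2.0, 4.0])
    def test_noiseless_exponential_recovered_within_one_percent(self, mu):
        z = np.arange(400) * PITCH
        profile = np.exp(-mu * z)  # amplitude ~ exp(-mu z): I ~ exp(-2 mu z)
        est, r2 = attenuation_coefficient(profile, PITCH, (0.1, 1.5))
        assert est == pytest.approx(mu, rel=0.01)
        assert r2 > 0.999

    def test_constant_profile_gives_zero(self):
        est, _ = attenuation_coefficient(np.ones(200), PITCH, (0.1, 0.8))
        assert est == 0.0

    def test_window_shorter_than_five_pixels_rejected(self):
        with pytest.raises(ValueError, match="5 axial"):
            attenuation_coefficient(np.ones(200), PITCH, (0.1, 0.11))

    def test_speckled_average_of_100_ascans_within_five_percent(self):
        """Exponential-intensity speckle around exp(-2 mu z): averaging 100
        A-scans tames the multiplicative noise."""
        mu = 2.0
        rng = np.random.default_rng(7)
        z = np.arange(400) * PITCH
        mean_int = np.exp(-2 * mu * z)
        inten = rng.exponential(1.0, (100, z.size)) * mean_int
        profile = np.sqrt(inten.mean(axis=0))
        est, _ = attenuation_coefficient(profile, PITCH, (0.1, 1.0))
        assert est == pytest.approx(mu, rel=0.05)
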