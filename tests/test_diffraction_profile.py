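"""Centering, radial averaging, normalization, background ratio and
band detection against brute-force and generator oracles."""

import dataclasses

import numpy as np
import pytest

from _oracles import radial_bin_means
from capsheet.diffraction_profile import (DEFAULT_BAND_SCORE_THRESHOLD,
                                          ProfileRatio, RadialProfile,
                                          analyze_pair, background_ratio,
                                          d_to_q, detect_band, estimate_center,
                                          normalize_profile, q_to_d,
                                          radial_average)
from capsheet.image_io import DiffractionCalibration, DiffractionImage
from capsheet.synthetic_data import (DEFAULT_MINERAL_BAND, DiffractionSpec,
                                     gen_diffraction_pair)


def _image(values, nyquist=1.75):
    values = np.asarray(values, dtype=float)
    cal = DiffractionCalibration(nyquist_q=nyquist,
                                 image_size=values.shape[0])
    return DiffractionImage(values=values, calibration=cal)


class TestEstimateCenter:
    def test_symmetric_pattern_centered(self):
        target, _, truth = gen_diffraction_pair(DiffractionSpec())
        est = estimate_center(target)
        assert abs(est[0] - truth.center[0]) < 0.5
        assert abs(est[1] - truth.center[1]) < 0.5

    @pytest.mark.parametrize("offset", [(5.0, -3.0), (8.0, 8.0), (-6.0, 2.0)])
    def test_injected_offset_recovered(self, offset):
        spec = DiffractionSpec(center_offset=offset, poisson_noise=True,
                               seed=13)
        target, _, truth = gen_diffraction_pair(spec)
        est = estimate_center(target)
        assert abs(est[0] - truth.center[0]) < 1.0
        assert abs(est[1] - truth.center[1]) < 1.0

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="center"):
            estimate_center(_image(np.ones((32, 32))))


class TestRadialAverage:
    def test_constant_image_gives_constant_bins(self):
        img = _image(np.full((64, 64), 3.5))
        prof = radial_average(img, (31.5, 31.5))
        np.testing.assert_allclose(prof.intensity, 3.5)
        assert np.all(np.diff(prof.q) > 0)

    def test_agrees_with_brute_force_grouping(self, rng):
        """Bin means match a per-pixel loop on a 64×64 random image."""
        img = _image(rng.random((64, 64)))
        center = (31.5, 31.5)
        prof = radial_average(img, center)
        oracle = radial_bin_means(img.values, center, n_bins=200)
        q_px = img.calibration.q_per_pixel
        for q, mean in zip(prof.q, prof.intensity):
            r = int(round(q / q_px))
            assert mean == pytest.approx(oracle[r], rel=1e-10)

    def test_delta_ring_peaks_at_its_radius(self):
        n = 512
        ii, jj = np.indices((n, n), dtype=float)
        center = ((n - 1) / 2, (n - 1) / 2)
        rbin = np.rint(np.hypot(ii - center[0], jj - center[1]))
        img = _image(np.where(rbin == 120, 1.0, 0.0))
        prof = radial_average(img, center)
        peak_r = prof.q[np.argmax(prof.intensity)] / img.calibration.q_per_pixel
        assert abs(peak_r - 120) <= 1

    def test_miscentering_broadens_a_delta_ring(self):
        """Averaging about a 5 px mis-centered origin strictly lowers the
        ring's peak bin mean — the centering step matters."""
        n = 512
        ii, jj = np.indices((n, n), dtype=float)
        center = ((n - 1) / 2, (n - 1) / 2)
        rbin = np.rint(np.hypot(ii - center[0], jj - center[1]))
        img = _image(np.where(rbin == 120, 1.0, 0.0))
        good = radial_average(img, center)
        bad = radial_average(img, (center[0] + 5, center[1]))
        assert bad.intensity.max() < good.intensity.max()

    def test_rotated_image_has_identical_profile(self):
        spec = DiffractionSpec(image_size=128,
                               mineral_band=DEFAULT_MINERAL_BAND)
        target, _, truth = gen_diffraction_pair(spec)
        rot = _image(np.rot90(target.values))
        p1 = radial_average(target, truth.center)
        p2 = radial_average(rot, truth.center)
        np.testing.assert_allclose(p1.intensity, p2.intensity, rtol=1e-12)

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError):
            radial_average(_image(np.ones((32, 32))), (100.0, 0.0))


class TestNormalize:
    def _profile(self, q, intensity):
        return RadialProfile(q=np.asarray(q, float),
                             intensity=np.asarray(intensity, float),
                             n_pixels=np.ones(len(q), dtype=int))

    def test_constant_profile_becomes_ones(self):
        q = np.linspace(0.05, 0.5, 200)
        norm = normalize_profile(self._profile(q, np.full(200, 7.0)))
        np.testing.assert_allclose(norm.intensity, 1.0)
        band = norm.normalization_band
        sel = (norm.q >= band[0]) & (norm.q <= band[1])
        assert norm.intensity[sel].mean() == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        q = np.linspace(0.05, 0.5, 80)
        intensity = rng.random(80) + 0.5
        a = normalize_profile(self._profile(q, intensity))
        b = normalize_profile(self._profile(q, 2 * intensity))
        np.testing.assert_allclose(a.intensity, b.intensity)

    def test_division_arithmetic(self):
        """Band mean 4.0 maps a bin of intensity 6.0 to 1.5."""
        q = np.linspace(0.09, 0.12, 10)
        intensity = np.full(10, 4.0)
        intensity[-1] = 6.0
        band_sel = (q >= 0.094) & (q <= 0.113)
        intensity[band_sel] = 4.0  # keep band mean exactly 4
        norm = normalize_profile(self._profile(q, intensity))
        assert norm.intensity[-1] == pytest.approx(6.0 / 4.0)

    def test_too_few_band_bins_rejected(self):
        q = np.array([0.05, 0.1, 0.3])
        with pytest.raises(ValueError, match="band"):
            normalize_profile(self._profile(q, [1, 1, 1]))

    def test_zero_band_mean_rejected(self):
        q = np.linspace(0.09, 0.12, 10)
        with pytest.raises(ValueError):
            normalize_profile(self._profile(q, np.zeros(10)))


class TestBackgroundRatio:
    def test_identity_pair_is_unity(self):
        target, background, truth = gen_diffraction_pair(DiffractionSpec())
        p = normalize_profile(radial_average(target, truth.center))
        q = normalize_profile(radial_average(background, truth.center))
        ratio = background_ratio(p, q)
        np.testing.assert_allclose(ratio.ratio[ratio.valid], 1.0)
        np.testing.assert_allclose(ratio.d * ratio.q, 1.0)

    def test_ice_positions_dampened_in_matched_pair(self, banded_pair_spec):
        """Noise off, matched rings: the ratio at the 3.71 Å ice position is
        1 within ±0.05 even though the target carries the mineral band."""
        target, background, truth = gen_diffraction_pair(banded_pair_spec)
        p = normalize_profile(radial_average(target, truth.center))
        q = normalize_profile(radial_average(background, truth.center))
        ratio = background_ratio(p, q)
        at_ice = ratio.ratio[np.argmin(np.abs(ratio.d - 3.71))]
        assert at_ice == pytest.approx(1.0, abs=0.05)

    def test_multiplicative_perturbation_recovered(self):
        """target = background × (1 + g(q)) gives ratio 1 + g(q) exactly."""
        _, background, truth = gen_diffraction_pair(DiffractionSpec())
        qpx = background.calibration.q_per_pixel
        n = background.shape[0]
        ii, jj = np.indices((n, n), dtype=float)
        qmap = np.hypot(ii - truth.center[0], jj - truth.center[1]) * qpx
        g = 0.08 * np.sin(12 * qmap)
        target = _image(background.values * (1 + g))
        p = normalize_profile(radial_average(target, truth.center))
        b = normalize_profile(radial_average(background, truth.center))
        ratio = background_ratio(p, b)
        # normalization rescales by the band mean of (1+g); undo it
        band_sel = (ratio.q >= 0.094) & (ratio.q <= 0.113)
        scale = np.mean(1 + 0.08 * np.sin(12 * ratio.q[band_sel]))
        expected = (1 + 0.08 * np.sin(12 * ratio.q)) / scale
        np.testing.assert_allclose(ratio.ratio[ratio.valid],
                                   expected[ratio.valid], rtol=2e-3)

    def test_binning_mismatch_rejected(self):
        t, b, truth = gen_diffraction_pair(DiffractionSpec())
        p = normalize_profile(radial_average(t, truth.center))
        q = normalize_profile(radial_average(b, truth.center,
                                             q_min_exclude=0.05))
        with pytest.raises(ValueError, match="binning"):
            background_ratio(p, q)

    def test_unnormalized_profiles_rejected(self):
        t, b, truth = gen_diffraction_pair(DiffractionSpec())
        p = radial_average(t, truth.center)
        q = radial_average(b, truth.center)
        with pytest.raises(ValueError, match="normalized"):
            background_ratio(p, q)


class TestDSpacing:
    @pytest.mark.parametrize("q, d", [(0.4, 2.5), (0.3125, 3.2), (1.0, 1.0)])
    def test_reciprocal_pairs(self, q, d):
        assert q_to_d(q) == pytest.approx(d)
        assert d_to_q(d) == pytest.approx(q)

    def test_round_trip_identity(self, rng):
        x = rng.uniform(0.1, 2.0, 20)
        np.testing.assert_allclose(d_to_q(q_to_d(x)), x)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            q_to_d(0.0)


class TestDetectBand:
    def _flat_ratio(self):
        q = np.linspace(0.2, 0.5, 200)
        return ProfileRatio(q=q, d=1 / q, ratio=np.ones(200),
                            valid=np.ones(200, dtype=bool))

    def test_flat_ratio_scores_zero(self):
        det = detect_band(self._flat_ratio())
        assert det.score == pytest.approx(0.0, abs=1e-12)
        assert not det.detected

    def test_injected_band_detected_with_formula_score(self, banded_pair_spec):
        """A noise-free 0.10-amplitude band at 2.85 Å is detected; the score
        equals the band-averaged injected excess computed directly from the
        generative formula (flank-baseline subtracted, independent fit)."""
        target, background, truth = gen_diffraction_pair(banded_pair_spec)
        ratio, det = analyze_pair(target, background, center=truth.center)
        assert det.detected

        d_c, amp, w = banded_pair_spec.mineral_band
        bump = amp * np.exp(-((ratio.q - 1 / d_c) ** 2) / (2 * w ** 2))
        flank = ((ratio.d >= 2.30) & (ratio.d <= 2.45)) | \
                ((ratio.d >= 3.40) & (ratio.d <= 3.60))
        # independent linear baseline via normal equations
        A = np.vstack([ratio.q[flank], np.ones(flank.sum())]).T
        slope, icpt = np.linalg.lstsq(A, 1 + bump[flank], rcond=None)[0]
        band = (ratio.d >= 2.5) & (ratio.d <= 3.2)
        expected = np.mean(1 + bump[band] - (slope * ratio.q[band] + icpt))
        assert det.score == pytest.approx(expected, abs=2e-3)
        assert det.score > 3 * DEFAULT_BAND_SCORE_THRESHOLD / 3

    def test_bump_outside_band_not_detected(self):
        """Excess at the 3.71 Å ice position only (outside the band) must
        not trigger detection."""
        spec = DiffractionSpec(mineral_band=(3.71, 0.10, 0.008), seed=2)
        target, background, truth = gen_diffraction_pair(spec)
        _, det = analyze_pair(target, background, center=truth.center)
        assert not det.detected

    def test_invalid_flank_coverage_rejected(self):
        ratio = self._flat_ratio()
        bad_valid = ratio.valid.copy()
        bad_valid[(ratio.d >= 3.40) & (ratio.d <= 3.60)] = False
        broken = dataclasses.replace(ratio, valid=bad_valid)
        with pytest.raises(ValueError, match="flank"):
            detect_band(broken)
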