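"""Noise estimation, Rician-corrected SNR, smoothing, masking, ROI means."""

import numpy as np
import pytest

from fluorox.image_io import GridSpec, MagnitudeSeries, RoiSet
from fluorox.preprocessing import (
    RICIAN_SD_FACTOR,
    SnrSeries,
    build_validity_mask,
    estimate_noise,
    magnitude_to_snr,
    preprocess_session,
    roi_mean_snr,
    smooth_snr,
)

STUDY_TRS = np.array([318.0, 719.0, 1398.0, 5000.0])


def _rician(a, sigma, size, rng):
    return np.hypot(a + rng.normal(0, sigma, size), rng.normal(0, sigma, size))


class TestNoiseEstimation:
    def test_sigma_g_formula(self):
        """sigma_g = sigma_m / sqrt(2 - pi/2); for sigma_m = 1 this is
        about 1.5264."""
        vol = np.zeros((30, 30, 2))
        rng = np.random.default_rng(0)
        mask = np.zeros_like(vol, dtype=bool)
        mask[:10, :10, 0] = True
        vol[mask] = rng.normal(0, 1.0, mask.sum())
        est = estimate_noise(vol, mask)
        assert est.sigma_g == pytest.approx(est.sigma_m / RICIAN_SD_FACTOR, rel=1e-12)
        assert 1.0 / RICIAN_SD_FACTOR == pytest.approx(1.5264, abs=5e-4)

    def test_recovers_true_sigma_from_rician_background(self):
        """The Rayleigh SD is sigma_g sqrt(2 - pi/2), so inverting it
        recovers the true Gaussian noise SD within 2% at 1e5 voxels."""
        rng = np.random.default_rng(42)
        vol = _rician(0.0, 2.0, (100, 100, 10), rng)
        est = estimate_noise(vol, np.ones_like(vol, dtype=bool))
        assert est.sigma_g == pytest.approx(2.0, rel=0.02)

    def test_small_or_degenerate_roi_rejected(self):
        vol = np.ones((5, 5, 5))
        tiny = np.zeros_like(vol, dtype=bool)
        tiny[0, 0, :3] = True
        with pytest.raises(ValueError, match="too small"):
            estimate_noise(vol, tiny)
        with pytest.raises(ValueError, match="zero variance"):
            estimate_noise(vol, np.ones_like(vol, dtype=bool))


class TestSnrConversion:
    @pytest.mark.parametrize(
        "si_over_sigma, expected",
        [(1.0, 0.0), (np.sqrt(2.0), 1.0), (0.5, 0.0), (np.sqrt(5.0), 2.0)],
    )
    def test_pointwise_formula_and_clamp(self, si_over_sigma, expected):
        sigma = 1.7
        out = magnitude_to_snr(np.array([[[si_over_sigma * sigma]]]), sigma)
        assert out[0, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            magnitude_to_snr(np.ones((2, 2, 2)), 0.0)

    @pytest.mark.parametrize("true_snr", [3.0, 5.0, 10.0])
    def test_corrected_estimator_less_biased_than_naive(self, true_snr):
        """On Rician magnitudes the Gudbjartsson-Patz estimator has smaller
        absolute bias than SI_m/sigma at every tested SNR level."""
        rng = np.random.default_rng(int(true_snr * 100))
        sigma = 1.0
        si = _rician(true_snr * sigma, sigma, 100_000, rng)
        naive_bias = np.mean(si / sigma) - true_snr
        corrected = np.sqrt(np.maximum(si**2 - sigma**2, 0)) / sigma
        corrected_bias = np.mean(corrected) - true_snr
        assert abs(corrected_bias) < abs(naive_bias)


class TestSmoothing:
    def test_constant_volume_unchanged(self):
        vol = np.full((20, 20, 4), 3.3)
        assert np.allclose(smooth_snr(vol, 3.0), vol, atol=1e-10)

    def test_delta_mass_is_preserved(self):
        """The discretized Gaussian kernel integrates to 1."""
        vol = np.zeros((41, 41, 1))
        vol[20, 20, 0] = 1.0
        out = smooth_snr(vol, 3.0)
        assert out[:, :, 0].sum() == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(40, 40, 3))
        assert smooth_snr(vol, 3.0).var() < vol.var()

    def test_in_plane_smoothing_does_not_mix_slices(self):
        vol = np.zeros((10, 10, 3))
        vol[:, :, 1] = 1.0
        out = smooth_snr(vol, 2.0, in_plane=True)
        assert np.all(out[:, :, 0] == 0) and np.all(out[:, :, 2] == 0)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            smooth_snr(np.zeros((4, 4, 1)), 0.0)


class TestValidityMask:
    def _series(self, tr4_map):
        vols = np.stack([np.full_like(tr4_map, 20.0)] * 3 + [tr4_map])
        return vols

    def test_uniform_maps(self):
        high = self._series(np.full((6, 6, 2), 10.0))
        assert build_validity_mask(high, STUDY_TRS).all()
        low = self._series(np.full((6, 6, 2), 4.9))
        assert not build_validity_mask(low, STUDY_TRS).any()

    def test_half_plane_threshold_is_exact(self):
        tr4 = np.full((8, 8, 1), 4.0)
        tr4[:4] = 6.0
        mask = build_validity_mask(self._series(tr4), STUDY_TRS)
        assert mask[:4].all() and not mask[4:].any()

    def test_threshold_boundary_is_inclusive(self):
        tr4 = np.full((4, 4, 1), 5.0)
        assert build_validity_mask(self._series(tr4), STUDY_TRS).all()

    def test_missing_tr4_image_rejected(self):
        vols = np.zeros((3, 4, 4, 1))
        with pytest.raises(ValueError, match="5000"):
            build_validity_mask(vols, [318.0, 719.0, 1398.0])


class TestRoiMeans:
    def _snr_series(self, volumes, validity):
        return SnrSeries(
            tr_ms=STUDY_TRS, volumes=volumes, affine=np.eye(4), validity=validity
        )

    def _rois(self, labels):
        return RoiSet(labels=labels, affine=np.eye(4),
                      label_map={1: ("M1", "M1-P1")})

    def test_uniform_roi_mean(self):
        shape = (6, 6, 2)
        vols = np.full((4,) + shape, 8.0)
        labels = np.zeros(shape, dtype=np.int16)
        labels[2:4, 2:4, :] = 1
        means, n = roi_mean_snr(
            self._snr_series(vols, np.ones(shape, bool)), self._rois(labels), 1
        )
        assert n == 8
        assert np.allclose(means, 8.0)

    def test_fully_excluded_roi_flagged_unusable(self):
        shape = (6, 6, 2)
        vols = np.full((4,) + shape, 8.0)
        labels = np.zeros(shape, dtype=np.int16)
        labels[0, 0, 0] = 1
        means, n = roi_mean_snr(
            self._snr_series(vols, np.zeros(shape, bool)), self._rois(labels), 1
        )
        assert means is None and n == 0

    def test_unknown_label_rejected(self):
        shape = (4, 4, 1)
        series = self._snr_series(np.zeros((4,) + shape), np.ones(shape, bool))
        with pytest.raises(KeyError):
            roi_mean_snr(series, self._rois(np.zeros(shape, np.int16)), 99)


class TestSessionChain:
    def test_order_of_operations_matches_manual_chain(self):
        """preprocess_session must apply: SNR conversion (native grid) ->
        interpolation -> smoothing -> TR4 thresholding, in that order."""
        from fluorox.image_io import resample_between_grids
        from fluorox.preprocessing import magnitude_to_snr as to_snr

        rng = np.random.default_rng(5)
        f19 = GridSpec(shape=(16, 16, 4), spacing=(2.0, 2.0, 4.0))
        anat = GridSpec(shape=(32, 32, 8), spacing=(1.0, 1.0, 2.0))
        vols = rng.uniform(0, 20, size=(4,) + f19.shape)
        noise_mask = np.zeros(f19.shape, bool)
        noise_mask[:4, :4, :] = True
        vols[:, noise_mask] = np.hypot(
            rng.normal(0, 1.5, (4, noise_mask.sum())),
            rng.normal(0, 1.5, (4, noise_mask.sum())),
        )
        series = MagnitudeSeries(tr_ms=STUDY_TRS, volumes=vols, affine=f19.affine())
        out = preprocess_session(series, noise_mask, anat.shape, anat.affine(),
                                 smooth_sd_px=2.0)

        sigma = estimate_noise(vols[-1], noise_mask).sigma_g
        manual = []
        for v in vols:
            s = to_snr(v, sigma)
            s = resample_between_grids(s, f19.affine(), anat.shape, anat.affine(), 3)
            manual.append(smooth_snr(np.maximum(s, 0.0), 2.0))
        manual = np.stack(manual)
        assert np.allclose(out.volumes, manual, atol=1e-10)
        assert np.array_equal(out.validity, manual[-1] >= 5.0)
        assert out.provenance["sigma_g"] == pytest.approx(sigma)

    def test_synthetic_roi_means_track_true_curve(self, small_bundle, small_config):
        """At modest noise the preprocessed ROI means stay within a few
        standard errors of the true recovery curve S0 (1 - exp(-TR/T1))."""
        from fluorox.synthetic import saturation_recovery_signal

        key = next(iter(small_bundle.sessions))
        mother, oxy = key
        series = small_bundle.sessions[key]
        snr = preprocess_session(
            series, small_bundle.noise_mask_f19,
            small_bundle.rois.labels.shape, small_bundle.rois.affine,
        )
        truth = small_bundle.truth
        checked = 0
        for lab, (m, plac) in small_bundle.rois.label_map.items():
            if m != mother:
                continue
            means, n = roi_mean_snr(snr, small_bundle.rois, lab)
            if means is None:
                continue
            t = truth[(truth.placenta_id == plac) & (truth.oxygen_percent == oxy)]
            curve = saturation_recovery_signal(
                series.tr_ms, float(t.true_s0.iloc[0]), float(t.true_t1_s.iloc[0])
            ) / small_config.sigma_g
            # smoothing dilutes the ROI mean multiplicatively; compare shape
            ratio = means / curve
            assert np.all(ratio > 0.3) and np.all(ratio < 1.6)
            assert ratio.max() / ratio.min() < 1.35
            checked += 1
        assert checked >= 2
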