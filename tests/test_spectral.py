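"""Welch cross-spectra, coherence estimator and connectivity matrices."""

import numpy as np
import pytest
from scipy import signal as sps

from cohnet import (
    CONDITIONS,
    AcquisitionConfig,
    ConfigurationError,
    DegenerateInputError,
    InputError,
    RoiTimeSeriesSet,
    SpectralConfig,
    band_average,
    coherence_spectrum,
    connectivity_matrix,
    cross_spectral_density,
)
from cohnet.spectral import CoherenceSpectrum


class TestSpectralConfig:
    def test_segment_count_on_default_trial(self, acq, spectral_cfg):
        assert spectral_cfg.n_segments(acq.n_samples) == 7

    def test_single_segment_rejected(self):
        cfg = SpectralConfig(segment_length=258, overlap_fraction=0.0)
        with pytest.raises(ConfigurationError, match="K"):
            cfg.require_averaging(258)

    def test_single_segment_estimator_is_identically_one(self):
        # the algebraic identity motivating the rejection: with one segment
        # |X Y*|^2 == |X|^2 |Y|^2 bin-for-bin, so Coh2 would be 1 everywhere
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 64))
        fx, fy = np.fft.rfft(x), np.fft.rfft(y)
        num = np.abs(fx * np.conj(fy)) ** 2
        den = np.abs(fx) ** 2 * np.abs(fy) ** 2
        assert np.allclose(num, den)

    def test_segment_longer_than_series_rejected(self):
        with pytest.raises(ConfigurationError):
            SpectralConfig(segment_length=512).n_segments(258)


class TestCrossSpectralDensity:
    def test_auto_spectrum_real_nonnegative(self, acq, spectral_cfg, rng):
        x = rng.standard_normal(acq.n_samples)
        _, cs = cross_spectral_density(x, x, spectral_cfg, acq)
        assert np.allclose(cs.imag, 0.0)
        assert np.all(cs.real >= 0.0)

    def test_hermitian_symmetry(self, acq, spectral_cfg, rng):
        x, y = rng.standard_normal((2, acq.n_samples))
        _, cxy = cross_spectral_density(x, y, spectral_cfg, acq)
        _, cyx = cross_spectral_density(y, x, spectral_cfg, acq)
        assert np.allclose(cxy, np.conj(cyx))

    def test_white_noise_density_level(self, acq, spectral_cfg):
        # one-sided density of unit-variance white noise ~ var / nyquist
        means = []
        for seed in range(50):
            x = np.random.default_rng(seed).standard_normal(acq.n_samples)
            _, cs = cross_spectral_density(x, x, spectral_cfg, acq)
            means.append(cs.real[1:-1].mean() * acq.nyquist_hz / x.var())
        assert np.mean(means) == pytest.approx(1.0, abs=0.05)

    def test_matches_scipy_csd(self, acq, spectral_cfg, rng):
        x, y = rng.standard_normal((2, acq.n_samples))
        f_mine, cs = cross_spectral_density(x, y, spectral_cfg, acq)
        f_sp, cs_sp = sps.csd(
            x, y, fs=acq.sampling_freq_hz, nperseg=64, noverlap=32,
            window="hann", detrend="constant",
        )
        assert np.allclose(f_mine, f_sp)
        assert np.allclose(np.conj(cs), cs_sp, atol=1e-12)

    def test_length_mismatch_rejected(self, acq, spectral_cfg, rng):
        with pytest.raises(InputError):
            cross_spectral_density(
                rng.standard_normal(258), rng.standard_normal(100), spectral_cfg, acq
            )


class TestCoherenceSpectrum:
    def test_identity_pair_is_one_everywhere(self, acq, spectral_cfg, rng):
        x = rng.standard_normal(acq.n_samples)
        spec = coherence_spectrum(x, x.copy(), spectral_cfg, acq)
        assert np.allclose(spec.coh2, 1.0)

    def test_linear_relation_invariance(self, acq, spectral_cfg, rng):
        x = rng.standard_normal(acq.n_samples)
        spec = coherence_spectrum(x, -2.0 * x, spectral_cfg, acq)
        assert np.allclose(spec.coh2, 1.0)

    def test_bounded_and_below_nyquist(self, acq, spectral_cfg, rng):
        for _ in range(20):
            x, y = rng.standard_normal((2, acq.n_samples))
            spec = coherence_spectrum(x, y, spectral_cfg, acq)
            assert np.all((spec.coh2 >= 0.0) & (spec.coh2 <= 1.0))
            assert spec.freqs_hz.max() <= acq.nyquist_hz + 1e-12
            assert spec.freqs_hz.min() > 0.0

    def test_matches_scipy_coherence(self, acq, spectral_cfg, rng):
        x, y = rng.standard_normal((2, acq.n_samples))
        spec = coherence_spectrum(x, y, spectral_cfg, acq)
        f_sp, c_sp = sps.coherence(
            x, y, fs=acq.sampling_freq_hz, nperseg=64, noverlap=32,
            window="hann", detrend="constant",
        )
        assert np.allclose(spec.coh2, c_sp[1:], atol=1e-10)

    def test_zero_variance_segment_rejected(self, acq, spectral_cfg):
        x = np.zeros(acq.n_samples)
        y = np.random.default_rng(0).standard_normal(acq.n_samples)
        with pytest.raises(DegenerateInputError):
            coherence_spectrum(x, y, spectral_cfg, acq)

    def test_shared_latent_recovers_closed_form(self):
        # a_i = a_j = 1, unit variances -> Coh2 = 0.25 at every frequency
        n = 4096
        acq = AcquisitionConfig(1.5, n)
        cfg = SpectralConfig()
        vals = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            s = r.standard_normal(n)
            x, y = s + r.standard_normal(n), s + r.standard_normal(n)
            vals.append(band_average(coherence_spectrum(x, y, cfg, acq), (0.15, 0.33)))
        k = cfg.n_segments(n)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        # small positive estimator bias of order (1-C)^2/K is allowed for
        assert np.mean(vals) == pytest.approx(0.25, abs=3 * se + 2.0 / k)


class TestBandAverage:
    def _spec(self, freqs, coh2):
        return CoherenceSpectrum(("a", "b"), np.asarray(freqs), np.asarray(coh2))

    def test_constant_spectrum(self):
        spec = self._spec([0.1, 0.2, 0.3], [0.4, 0.4, 0.4])
        assert band_average(spec, (0.05, 0.35)) == pytest.approx(0.4)

    def test_two_bin_mean(self):
        spec = self._spec([0.1, 0.2, 0.25, 0.3], [0.9, 0.2, 0.6, 0.9])
        assert band_average(spec, (0.15, 0.27)) == pytest.approx(0.4)

    def test_full_band_equals_global_mean(self, acq, spectral_cfg, rng):
        x, y = rng.standard_normal((2, acq.n_samples))
        spec = coherence_spectrum(x, y, spectral_cfg, acq)
        full = band_average(spec, (spec.freqs_hz[0], acq.nyquist_hz))
        assert full == pytest.approx(spec.coh2.mean())

    def test_empty_band_rejected(self):
        spec = self._spec([0.1, 0.2], [0.5, 0.5])
        with pytest.raises(ConfigurationError):
            band_average(spec, (0.3, 0.32))

    def test_inclusive_bounds(self):
        spec = self._spec([0.15, 0.33], [0.2, 0.8])
        assert band_average(spec, (0.15, 0.33)) == pytest.approx(0.5)


def _ts(values, labels, cond="ACCD"):
    return RoiTimeSeriesSet(
        values=np.asarray(values, float),
        roi_labels=tuple(labels),
        subject_id=1,
        trial_index=1,
        condition=CONDITIONS[cond],
    )


class TestConnectivityMatrix:
    LABELS = ("rACC", "pInsL", "pInsR", "MCC", "aInsL", "SII")

    def test_identical_rows_give_all_ones(self, acq, spectral_cfg, rng):
        x = rng.standard_normal(acq.n_samples)
        ts = _ts(np.tile(x, (6, 1)), self.LABELS)
        cm = connectivity_matrix(ts, spectral_cfg, acq)
        off = cm.offdiag_values()
        assert np.allclose(off, 1.0)
        assert np.all(np.diag(cm.values) == 0.0)

    def test_symmetric_with_15_unique_pairs(self, acq, spectral_cfg, rng):
        ts = _ts(rng.standard_normal((6, acq.n_samples)), self.LABELS)
        cm = connectivity_matrix(ts, spectral_cfg, acq)
        assert np.array_equal(cm.values, cm.values.T)
        assert len(cm.offdiag_values()) == 15
        assert len(cm.offdiag_pairs()) == 15

    def test_control_roi_excluded_by_default(self, acq, spectral_cfg, rng):
        labels = self.LABELS + ("UNR",)
        ts = _ts(rng.standard_normal((7, acq.n_samples)), labels)
        cm = connectivity_matrix(ts, spectral_cfg, acq)
        assert "UNR" not in cm.roi_labels
        assert cm.n_rois == 6

    def test_missing_roi_rejected(self, acq, spectral_cfg, rng):
        ts = _ts(rng.standard_normal((6, acq.n_samples)), self.LABELS)
        with pytest.raises(InputError):
            connectivity_matrix(ts, spectral_cfg, acq, roi_labels=("rACC", "nope"))

    def test_shared_latent_matrix_matches_pairwise_oracle(self, acq, spectral_cfg):
        # every pair's entry must match theoretical coherence up to
        # Monte-Carlo spread and the K=7 bias floor
        from cohnet import CohortSpec, coupling_model_for, theoretical_coherence
        from cohnet import build_trial_design, simulate_subject

        spec = CohortSpec()
        cond = CONDITIONS["ACCU"]
        model = coupling_model_for(spec, cond, learner=True)
        design = build_trial_design(acq, cond)
        k = spectral_cfg.n_segments(acq.n_samples)
        mats = []
        for seed in range(40):
            trials = simulate_subject(model, [design] * 6, acq, seed=seed)
            mats.append(connectivity_matrix(trials[0], spectral_cfg, acq).values)
        mean_cm = np.mean(mats, axis=0)
        labels = connectivity_matrix(
            simulate_subject(model, [design] * 6, acq, seed=0)[0], spectral_cfg, acq
        ).roi_labels
        for i in range(6):
            for j in range(i + 1, 6):
                theory = theoretical_coherence(model, labels[i], labels[j])
                # estimator bias for weakly coherent pairs ~ 1/K
                assert abs(mean_cm[i, j] - theory) < 3.0 / k + 0.05

    def test_bias_floor_for_independent_series(self, acq, spectral_cfg):
        k = spectral_cfg.n_segments(acq.n_samples)
        means = []
        for seed in range(100):
            ts = _ts(
                np.random.default_rng(seed).standard_normal((6, acq.n_samples)),
                self.LABELS,
            )
            means.append(connectivity_matrix(ts, spectral_cfg, acq).offdiag_values().mean())
        assert 0.5 / k <= np.mean(means) <= 3.0 / k
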