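"""Preprocessing stages: OD conversion, bandpass contract, despiking, MBLL."""

import numpy as np
import pytest

from oracles import tone_amplitude

from nirsconn.errors import ConfigurationError, InvalidInputError
from nirsconn.preprocess import (
    DEFAULT_FS,
    MbllParams,
    RawIntensityRecording,
    WaveletParams,
    bandpass,
    intensity_to_od,
    mbll,
    mbll_forward,
    preprocess_subject,
    wavelet_despike,
)
from nirsconn.synthetic import GroundTruth, NoiseSpec, hb_to_intensity, simulate_hb
from nirsconn.connectivity import cor_matrix

FS = DEFAULT_FS


def _rec(intensities, **kw):
    return RawIntensityRecording(np.asarray(intensities, dtype=float), **kw)


class TestIntensityToOd:
    def test_constant_trace_gives_zero_od(self):
        rec = _rec(np.full((3, 2, 100), 4.2))
        assert np.allclose(intensity_to_od(rec), 0.0)

    def test_tenfold_drop_gives_unit_od(self):
        vals = np.ones((1, 2, 1000))
        vals[0, 0, 500] = 0.1
        rec = _rec(vals)
        od = intensity_to_od(rec)
        ref = vals[0, 0].mean()
        assert od[0, 0, 500] == pytest.approx(1.0 + np.log10(ref), abs=1e-12)

    def test_matches_direct_formula(self, rng):
        vals = rng.uniform(0.5, 2.0, size=(4, 2, 256))
        od = intensity_to_od(_rec(vals))
        expect = -np.log10(vals / vals.mean(axis=2, keepdims=True))
        assert np.max(np.abs(od - expect)) <= 1e-12
        # referencing to the mean: mean of 10^(-dOD) is 1 per trace
        assert np.allclose((10.0 ** -od).mean(axis=2), 1.0)

    def test_nonpositive_sample_rejected_with_location(self):
        vals = np.ones((2, 2, 50))
        vals[1, 0, 7] = -1.0
        with pytest.raises(InvalidInputError, match="channel 2"):
            _rec(vals)


class TestBandpass:
    def test_hemodynamic_tone_passes(self):
        t = np.arange(int(300 * FS)) / FS
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, FS)
        core = slice(int(0.1 * x.size), int(0.9 * x.size))
        assert tone_amplitude(y[core], FS, 0.05) == pytest.approx(1.0, rel=0.1)

    def test_cardiac_tone_attenuated(self):
        t = np.arange(int(300 * FS)) / FS
        x = np.sin(2 * np.pi * 1.2 * t)
        y = bandpass(x, FS)
        rms_in = np.sqrt(np.mean(x**2))
        assert np.sqrt(np.mean(y**2)) <= 0.1 * rms_in

    def test_linear_drift_removed(self):
        n = int(300 * FS)
        x = np.linspace(-1.0, 1.0, n)
        y = bandpass(x, FS)
        core = slice(int(0.1 * n), int(0.9 * n))
        assert np.sqrt(np.mean(y[core] ** 2)) <= 0.05 * np.sqrt(np.mean(x[core] ** 2))

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidInputError):
            bandpass(np.zeros(10), FS)


class TestWaveletDespike:
    def test_clean_signal_essentially_unchanged(self, quiet_noise):
        hb = simulate_hb(GroundTruth(np.eye(4)), duration_s=120, noise=quiet_noise, seed=2)
        x = hb.values[0]
        y = wavelet_despike(x)
        assert np.corrcoef(x, y)[0, 1] >= 0.99

    def test_planted_spike_suppressed(self, quiet_noise):
        hb = simulate_hb(GroundTruth(np.eye(2)), duration_s=120, noise=quiet_noise, seed=4)
        clean = hb.values[0]
        spiked = clean.copy()
        k = spiked.size // 2
        spiked[k:k + 4] += 10.0 * clean.std()
        corrected = wavelet_despike(spiked)
        before = np.max(np.abs(spiked - clean))
        after = np.max(np.abs(corrected - clean))
        assert after <= 0.3 * before

    def test_zero_input_zero_output(self):
        y = wavelet_despike(np.zeros(256))
        assert np.allclose(y, 0.0)
        assert y.size == 256

    def test_length_preserved_odd_sizes(self):
        for n in (65, 127, 300):
            assert wavelet_despike(np.sin(np.arange(n) / 7.0)).size == n

    def test_nonfinite_input_rejected(self):
        x = np.zeros(128)
        x[3] = np.nan
        with pytest.raises(InvalidInputError):
            wavelet_despike(x)


class TestMbll:
    def test_zero_od_zero_concentrations(self):
        oxy, deoxy = mbll(np.zeros((3, 2, 50)))
        assert np.allclose(oxy.values, 0) and np.allclose(deoxy.values, 0)

    def test_known_concentrations_recovered(self, rng):
        oxy_in = rng.normal(0, 1e-3, size=(5, 200))
        deoxy_in = rng.normal(0, 5e-4, size=(5, 200))
        od = mbll_forward(oxy_in, deoxy_in)
        oxy, deoxy = mbll(od)
        assert np.max(np.abs(oxy.values - oxy_in)) <= 1e-9
        assert np.max(np.abs(deoxy.values - deoxy_in)) <= 1e-9

    def test_linearity_under_scaling(self, rng):
        od = rng.normal(0, 0.01, size=(2, 2, 64))
        o1, d1 = mbll(od)
        o3, d3 = mbll(3.0 * od)
        assert np.allclose(o3.values, 3.0 * o1.values)
        assert np.allclose(d3.values, 3.0 * d1.values)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ConfigurationError):
            MbllParams(extinction=np.array([[1.0, 2.0], [2.0, 4.0]]))


class TestPreprocessSubject:
    def test_end_to_end_correlation_recovery(self, modular_truth, quiet_noise):
        # noise-free synthetic recordings; 20 seeds averaged.  The bound is
        # the Monte-Carlo sampling error of a 0.02-0.1 Hz process at 300 s
        # (per-edge SD ~ 0.33*(1-rho^2) plus the finite-sample bias of r)
        iu = np.triu_indices(22, k=1)
        mats = []
        for seed in range(20):
            hb = simulate_hb(modular_truth, noise=quiet_noise, seed=100 + seed)
            rec = hb_to_intensity(hb)
            oxy = preprocess_subject(rec)
            mats.append(cor_matrix(oxy).values)
        avg = np.mean(mats, axis=0)
        assert np.abs(avg - modular_truth.correlation)[iu].mean() <= 0.08

    def test_pipeline_deterministic(self, modular_truth):
        hb = simulate_hb(modular_truth, duration_s=90, seed=8)
        rec = hb_to_intensity(hb)
        a = preprocess_subject(rec)
        b = preprocess_subject(rec)
        assert np.array_equal(a.values, b.values)

    def test_spiky_recording_correlations_survive_despiking(self, modular_truth, quiet_noise):
        iu = np.triu_indices(22, k=1)
        spiky_noise = NoiseSpec(osc_amplitudes=(0.0, 0.0, 0.0), drift_slope_sd=0.0,
                                white_sd=0.0, spike_rate_per_min=5.0,
                                spike_amplitude_sd=3.0)
        err_clean, err_spiky = [], []
        for seed in range(5):
            clean = simulate_hb(modular_truth, noise=quiet_noise, seed=300 + seed)
            spiky = simulate_hb(modular_truth, noise=spiky_noise, seed=300 + seed)
            for hb, sink in ((clean, err_clean), (spiky, err_spiky)):
                oxy = preprocess_subject(hb_to_intensity(hb))
                err = np.abs(cor_matrix(oxy).values - modular_truth.correlation)[iu].mean()
                sink.append(err)
        assert np.mean(err_spiky) <= 2.0 * np.mean(err_clean) + 1e-3

    def test_channel_permutation_equivariance(self, modular_truth):
        hb = simulate_hb(modular_truth, duration_s=90, seed=13)
        rec = hb_to_intensity(hb)
        perm = np.random.default_rng(0).permutation(22)
        rec_perm = RawIntensityRecording(rec.intensities[perm],
                                         fs_hz=rec.fs_hz,
                                         baseline_intensity=rec.baseline_intensity[perm])
        a = preprocess_subject(rec)
        b = preprocess_subject(rec_perm)
        assert np.allclose(b.values, a.values[perm], atol=1e-12)
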