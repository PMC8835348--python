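"""Rendering, forward propagation and time-alignment tests."""

import numpy as np
import pytest
import scipy.fft as sfft
from scipy.signal import fftconvolve

import transaural as ta
from transaural.design import DesignConfig
from transaural.reproduction import (
    BinauralTarget,
    LoudspeakerSignals,
    ReproducedSignals,
    forward,
    make_target,
    render,
    reproduce,
    time_align,
)
from transaural.signals import AudioSignal, ImpulseResponseSet

FS = 48_000


class TestMakeTarget:
    def test_zero_signal_gives_zero_target(self, anechoic_plant):
        silent = AudioSignal(np.zeros(256), FS)
        target = make_target(0, silent, anechoic_plant)
        assert not np.any(target.signal.samples)

    def test_impulse_gives_lowpassed_plant_column(self, anechoic_plant):
        kernel = DesignConfig().lowpass_kernel(FS)
        impulse = AudioSignal(np.r_[1.0, np.zeros(15)], FS)
        target = make_target(2, impulse, anechoic_plant, kernel)
        for m in range(2):
            expected = fftconvolve(
                fftconvolve(anechoic_plant.irs[m, 2], np.r_[1.0, np.zeros(15)]), kernel
            )
            np.testing.assert_allclose(target.signal.samples[:, m], expected, atol=1e-12)

    def test_invalid_source_index(self, anechoic_plant):
        with pytest.raises(IndexError):
            make_target(99, AudioSignal(np.zeros(16), FS), anechoic_plant)

    def test_out_of_band_energy_matches_kernel_prediction(self, anechoic_plant):
        """Above-8-kHz energy equals what the kernel's frequency response
        predicts from the pre-lowpass spectrum, and is negligible."""
        kernel = DesignConfig().lowpass_kernel(FS)
        speech = ta.speech_like_signal(0.5, FS, seed=2)
        raw = make_target(0, speech, anechoic_plant)
        filtered = make_target(0, speech, anechoic_plant, kernel)
        x = filtered.signal.samples[:, 0]
        n = x.shape[0]
        freqs = np.fft.rfftfreq(n, 1.0 / FS)
        spectrum = sfft.rfft(x)
        # independent spectral route: pre-lowpass spectrum times kernel response
        pre = sfft.rfft(raw.signal.samples[:, 0], n)
        predicted = pre * np.exp(
            -2j * np.pi * freqs * (kernel.shape[0] - 1) / 2 / FS
        ) * np.abs(sfft.rfft(kernel, n))
        stop = freqs > 8000.0
        e_stop = float((np.abs(spectrum[stop]) ** 2).sum())
        e_stop_pred = float((np.abs(predicted[stop]) ** 2).sum())
        assert e_stop == pytest.approx(e_stop_pred, rel=0.15)
        e_pass = float((np.abs(spectrum[~stop]) ** 2).sum())
        assert 10 * np.log10(e_stop / e_pass) <= -30.0


class TestRender:
    def test_zero_target_zero_feeds(self, anechoic_results):
        target = BinauralTarget(AudioSignal(np.zeros((64, 2)), FS))
        q = render(target, anechoic_results.bank)
        assert not np.any(q.signal.samples)

    def test_impulse_target_selects_filter_column(self, anechoic_results):
        d = np.zeros((1, 2))
        d[0, 0] = 1.0
        q = render(BinauralTarget(AudioSignal(d, FS)), anechoic_results.bank)
        for l in range(2):
            np.testing.assert_allclose(
                q.signal.samples[:, l], anechoic_results.bank.coeffs[l, 0], atol=1e-15
            )

    def test_linearity(self, anechoic_results, rng):
        d = rng.standard_normal((256, 2))
        q1 = render(BinauralTarget(AudioSignal(d, FS)), anechoic_results.bank)
        q2 = render(BinauralTarget(AudioSignal(3.5 * d, FS)), anechoic_results.bank)
        np.testing.assert_allclose(q2.signal.samples, 3.5 * q1.signal.samples, atol=1e-12)

    def test_rate_mismatch_rejected(self, anechoic_results):
        target = BinauralTarget(AudioSignal(np.zeros((16, 2)), 44_100))
        with pytest.raises(ValueError):
            render(target, anechoic_results.bank)


class TestForward:
    def test_zero_feeds_zero_pressure(self, anechoic_va):
        q = LoudspeakerSignals(AudioSignal(np.zeros((64, 2)), FS))
        p = forward(q, anechoic_va)
        assert not np.any(p.signal.samples)

    def test_identity_single_path_plant(self, rng):
        irs = np.zeros((1, 1, 8))
        irs[0, 0, 0] = 1.0
        # two identical mics so the output container stays binaural
        plant = ImpulseResponseSet(np.concatenate([irs, irs]), FS)
        x = rng.standard_normal((128, 1))
        p = forward(LoudspeakerSignals(AudioSignal(x, FS)), plant)
        np.testing.assert_allclose(p.signal.samples[:128, 0], x[:, 0], atol=1e-15)

    def test_channel_count_mismatch_rejected(self, anechoic_va):
        q = LoudspeakerSignals(AudioSignal(np.zeros((16, 3)), FS))
        with pytest.raises(ValueError):
            forward(q, anechoic_va)

    def test_composite_kernel_associativity(self, anechoic_results, anechoic_va, rng):
        """forward(render(d)) equals convolution with composite kernels."""
        bank = anechoic_results.bank
        d = rng.standard_normal((512, 2))
        p = forward(render(BinauralTarget(AudioSignal(d, FS)), bank), anechoic_va)
        for m in range(2):
            direct = np.zeros(bank.n_taps + anechoic_va.length + d.shape[0] - 2)
            for c in range(2):
                composite = np.zeros(bank.n_taps + anechoic_va.length - 1)
                for l in range(2):
                    composite += fftconvolve(anechoic_va.irs[m, l], bank.coeffs[l, c])
                direct += fftconvolve(composite, d[:, c])
            np.testing.assert_allclose(p.signal.samples[:, m], direct, atol=1e-9)


class TestAlignment:
    def test_pure_delayed_copy_aligns_exactly(self, rng):
        d = rng.standard_normal((1000, 2))
        delay = 123
        p_samples = np.vstack([np.zeros((delay, 2)), d])
        p = ReproducedSignals(AudioSignal(p_samples, FS), total_delay=delay)
        aligned_p, aligned_d = time_align(p, BinauralTarget(AudioSignal(d, FS)), crop=800)
        np.testing.assert_array_equal(aligned_p, aligned_d)
        assert aligned_p.shape == (800, 2)

    def test_insufficient_length_rejected(self, rng):
        p = ReproducedSignals(AudioSignal(np.zeros((100, 2)), FS), total_delay=50)
        d = BinauralTarget(AudioSignal(np.zeros((100, 2)), FS))
        with pytest.raises(ValueError):
            time_align(p, d, crop=80)

    def test_end_to_end_alignment_peaks_at_zero_lag(
        self, anechoic_results, anechoic_plant, anechoic_va
    ):
        """Cross-correlation of aligned target/reproduction peaks at lag 0."""
        kernel = anechoic_results.config.lowpass_kernel(FS)
        speech = ta.speech_like_signal(0.4, FS, seed=5)
        target = make_target(0, speech, anechoic_plant, kernel)
        p = reproduce(target, anechoic_results.bank, anechoic_va)
        crop = 16_384
        aligned_p, aligned_d = time_align(p, target, crop)
        xc = fftconvolve(aligned_p[:, 0], aligned_d[::-1, 0])
        assert int(np.argmax(np.abs(xc))) == crop - 1

    def test_delay_bookkeeping_matches_end_to_end_peak(
        self, anechoic_results, anechoic_va
    ):
        bank = anechoic_results.bank
        e2e = np.zeros(bank.n_taps + anechoic_va.length - 1)
        for l in range(2):
            e2e += fftconvolve(anechoic_va.irs[0, l], bank.coeffs[l, 0])
        assert abs(int(np.argmax(np.abs(e2e))) - bank.total_delay) <= 1
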