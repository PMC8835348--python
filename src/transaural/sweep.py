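"""Exponential sine sweep (ESS) measurement and deconvolution.

The transfer paths between the loudspeakers and the device microphones are
identified by playing a logarithmic sweep s(t) = sin(K (e^{t/T'} - 1)) and
deconvolving the microphone recording.  The exponential sweep concentrates
harmonic-distortion products at negative lags of the deconvolved response, so
cropping at the time origin isolates the linear impulse response.

Deconvolution is performed by regularized spectral division, which is exact
for noise-free linear systems; :func:`inverse_sweep` exposes the equivalent
time-domain kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as _fft

from .signals import DEFAULT_SAMPLE_RATE, AudioSignal

__all__ = ["SweepSpec", "generate_ess", "inverse_sweep", "extract_ir"]

#: Relative spectral floor for regularized division (re max |S|^2).
_DIVISION_EPS = 1e-12


@dataclass(frozen=True)
class SweepSpec:
    """Exponential sweep parameters.

    The measurement band defaults to 1 Hz - 24 kHz (full band at 48 kHz);
    duration and silences are free parameters of the acquisition, with a 10 s
    sweep and 1 s of guard silence either side as a practical default.
    """

    f_start: float = 1.0
    f_end: float = 24_000.0
    duration: float = 10.0
    pre_silence: float = 1.0
    post_silence: float = 1.0
    amplitude: float = 1.0

    def validate(self, sample_rate: int) -> None:
        if not 0 < self.f_start < self.f_end:
            raise ValueError("need 0 < f_start < f_end")
        if self.f_end > sample_rate / 2:
            raise ValueError(
                f"f_end {self.f_end} Hz exceeds Nyquist at fs={sample_rate}"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")
        if self.pre_silence < 0 or self.post_silence < 0:
            raise ValueError("silences must be non-negative")

    def rate_constant(self) -> float:
        """T' in s(t) = sin(2 pi f_start T' (e^{t/T'} - 1))."""
        return self.duration / np.log(self.f_end / self.f_start)

    def n_samples(self, sample_rate: int) -> int:
        return int(
            round((self.pre_silence + self.duration + self.post_silence) * sample_rate)
        )


def generate_ess(spec: SweepSpec, sample_rate: int = DEFAULT_SAMPLE_RATE) -> AudioSignal:
    """Synthesize the exponential sweep, padded by the guard silences.

    Instantaneous frequency grows as f_start * e^{t/T'} from f_start at t=0 to
    f_end at t=duration.
    """
    spec.validate(sample_rate)
    t_prime = spec.rate_constant()
    n_sweep = int(round(spec.duration * sample_rate))
    t = np.arange(n_sweep) / sample_rate
    phase = 2.0 * np.pi * spec.f_start * t_prime * (np.exp(t / t_prime) - 1.0)
    sweep = spec.amplitude * np.sin(phase)
    pre = np.zeros(int(round(spec.pre_silence * sample_rate)))
    post = np.zeros(int(round(spec.post_silence * sample_rate)))
    return AudioSignal(np.concatenate([pre, sweep, post]), sample_rate)


def _deconvolution_spectrum(sweep: np.ndarray, n_fft: int) -> np.ndarray:
    """Regularized reciprocal spectrum K = conj(S) / (|S|^2 + eps)."""
    spectrum = _fft.rfft(sweep, n_fft)
    power = np.abs(spectrum) ** 2
    eps = _DIVISION_EPS * power.max()
    return np.conj(spectrum) / (power + eps)


def inverse_sweep(spec: SweepSpec, sample_rate: int = DEFAULT_SAMPLE_RATE) -> AudioSignal:
    """Time-domain deconvolution kernel for the sweep.

    The kernel is the (regularized) spectral inverse of the sweep rendered in
    the time domain; it is predominantly anti-causal (it has to undo the
    sweep's time spread), so the returned block holds lags -n..-1 and linear
    convolution with the forward sweep produces its peak near lag n-1.  Length
    matches the sweep (silences included).
    """
    sweep = generate_ess(spec, sample_rate).channel(0)
    n = sweep.shape[0]
    n_fft = _fft.next_fast_len(2 * n)
    kernel_full = _fft.irfft(_deconvolution_spectrum(sweep, n_fft), n_fft)
    return AudioSignal(kernel_full[-n:], sample_rate)


def extract_ir(
    recording: AudioSignal,
    spec: SweepSpec,
    ir_length: int,
    anchor: str = "origin",
    pre_peak_margin: float = 1e-3,
) -> np.ndarray:
    """Deconvolve a sweep recording into the system's linear impulse response.

    Parameters
    ----------
    recording
        Microphone capture while the sweep played through the system; may be
        longer than the sweep (acquisition latency is preserved).
    ir_length
        Number of samples of impulse response to keep.
    anchor
        ``"origin"`` (default) crops from lag 0, preserving the system's
        absolute latency -- required when several paths must share a time
        base.  ``"peak"`` crops from ``pre_peak_margin`` seconds before the
        strongest deconvolution peak, discarding acquisition delay.

    Harmonic-distortion components land at negative lags (the tail of the
    deconvolution buffer) and are excluded by either crop.
    """
    if recording.n_channels != 1:
        raise ValueError("extract_ir expects a single-channel recording")
    sweep = generate_ess(spec, recording.sample_rate).channel(0)
    captured = recording.channel(0)
    if captured.shape[0] < sweep.shape[0]:
        raise ValueError("recording is shorter than the measurement sweep")
    if not np.any(captured):
        warnings.warn("silent recording; returning an all-zero impulse response")
        return np.zeros(ir_length)

    n_fft = _fft.next_fast_len(captured.shape[0] + sweep.shape[0])
    response = _fft.irfft(
        _fft.rfft(captured, n_fft) * _deconvolution_spectrum(sweep, n_fft), n_fft
    )

    if anchor == "origin":
        start = 0
    elif anchor == "peak":
        margin = int(round(pre_peak_margin * recording.sample_rate))
        start = max(int(np.argmax(np.abs(response))) - margin, 0)
    else:
        raise ValueError("anchor must be 'origin' or 'peak'")
    out = response[start : start + ir_length]
    if out.shape[0] < ir_length:
        out = np.pad(out, (0, ir_length - out.shape[0]))
    return out


def measure_plant(
    plant,
    spec: SweepSpec | None = None,
    ir_length: int | None = None,
):
    """Re-measure an impulse-response set through the sweep pipeline.

    Simulates playing the sweep through every (mic, source) path of ``plant``
    and deconvolving the virtual recording -- the in-silico analogue of the
    in-clinic transfer-function measurement.  With a noise-free plant the
    result matches the plant itself to deconvolution accuracy.
    """
    from scipy.signal import fftconvolve

    from .signals import ImpulseResponseSet

    spec = spec or SweepSpec()
    ir_length = ir_length or plant.length
    sweep = generate_ess(spec, plant.sample_rate)
    measured = np.zeros((plant.n_mics, plant.n_sources, ir_length))
    for m in range(plant.n_mics):
        for l in range(plant.n_sources):
            rec = fftconvolve(sweep.channel(0), plant.irs[m, l])
            measured[m, l] = extract_ir(
                AudioSignal(rec, plant.sample_rate), spec, ir_length
            )
    return ImpulseResponseSet(
        measured, plant.sample_rate, plant.mic_labels, plant.source_labels
    )
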