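"""Rendering and forward simulation of the reproduction chain.

``make_target`` builds the two-channel target d[n] (what the microphones
would capture for a real source), ``render`` turns it into loudspeaker feeds
q[n] through the inverse filters, ``forward`` propagates those feeds through
the raw acoustic plant to the reproduced pressures p[n], and ``time_align``
removes the known constant design delay before error analysis.

The forward path always uses the raw, unwindowed plant: the mismatch between
the windowed design plant and the true room response is precisely what limits
performance in reverberant conditions, so it must not be hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .design import InverseFilterBank
from .signals import AudioSignal, ImpulseResponseSet

__all__ = [
    "BinauralTarget",
    "LoudspeakerSignals",
    "ReproducedSignals",
    "make_target",
    "render",
    "forward",
    "time_align",
]

DEFAULT_CROP = 76_800  # 1.6 s at 48 kHz


@dataclass
class BinauralTarget:
    """Two-channel target pressure signal d[n] with its provenance."""

    signal: AudioSignal
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.signal.n_channels != 2:
            raise ValueError("a binaural target has exactly 2 channels")


@dataclass
class LoudspeakerSignals:
    """L-channel loudspeaker feed q[n]."""

    signal: AudioSignal


@dataclass
class ReproducedSignals:
    """Two-channel reproduced pressure p[n] and the chain's constant delay."""

    signal: AudioSignal
    total_delay: int

    def __post_init__(self) -> None:
        if self.signal.n_channels != 2:
            raise ValueError("reproduced pressure has exactly 2 channels")
        if self.total_delay < 0:
            raise ValueError("total_delay must be >= 0")


def make_target(
    source_index: int,
    signal: AudioSignal,
    plant: ImpulseResponseSet,
    lowpass: np.ndarray | None = None,
) -> BinauralTarget:
    """Target microphone signals for ``signal`` played from one source.

    d_m = g_{m,source} * signal, then filtered with the same low-pass kernel
    used in the filter design so energy beyond the device Nyquist is
    negligible in the reference as well.
    """
    if not 0 <= source_index < plant.n_sources:
        raise IndexError(f"source index {source_index} out of range")
    if signal.n_channels != 1:
        raise ValueError("the source signal must be single-channel")
    x = signal.channel(0)
    channels = [fftconvolve(plant.irs[m, source_index], x) for m in range(plant.n_mics)]
    d = np.stack(channels, axis=-1)
    if lowpass is not None:
        d = fftconvolve(d, lowpass[:, None], axes=0)
    return BinauralTarget(
        AudioSignal(d, plant.sample_rate), plant.source_labels[source_index]
    )


def render(target: BinauralTarget, bank: InverseFilterBank) -> LoudspeakerSignals:
    """Loudspeaker feeds q_l = sum_m h_{l,m} * d_m (full linear convolution)."""
    if target.signal.sample_rate != bank.sample_rate:
        raise ValueError("sample-rate mismatch between target and filter bank")
    d = target.signal.samples  # (n, M)
    n_out = d.shape[0] + bank.n_taps - 1
    q = np.zeros((n_out, bank.n_sources))
    for l in range(bank.n_sources):
        for m in range(bank.n_inputs):
            q[:, l] += fftconvolve(bank.coeffs[l, m], d[:, m])
    return LoudspeakerSignals(AudioSignal(q, bank.sample_rate))


def forward(
    q: LoudspeakerSignals,
    plant: ImpulseResponseSet,
    total_delay: int = 0,
) -> ReproducedSignals:
    """Reproduced pressures p_m = sum_l g_{m,l} * q_l through the raw plant."""
    feeds = q.signal.samples
    if feeds.shape[1] != plant.n_sources:
        raise ValueError(
            f"{feeds.shape[1]} loudspeaker channels but the plant has "
            f"{plant.n_sources} sources"
        )
    n_out = feeds.shape[0] + plant.length - 1
    p = np.zeros((n_out, plant.n_mics))
    for m in range(plant.n_mics):
        for l in range(plant.n_sources):
            p[:, m] += fftconvolve(plant.irs[m, l], feeds[:, l])
    return ReproducedSignals(AudioSignal(p, plant.sample_rate), total_delay)


def reproduce(
    target: BinauralTarget,
    bank: InverseFilterBank,
    plant: ImpulseResponseSet,
) -> ReproducedSignals:
    """render + forward, compensating the chain's known constant gain.

    The bank's peak normalization leaves a known end-to-end amplitude
    (``bank.reproduction_gain``); dividing it out is the playback-level
    calibration a physical setup performs at the amplifier stage.
    """
    p = forward(render(target, bank), plant, bank.total_delay)
    calibrated = p.signal.samples / bank.reproduction_gain
    return ReproducedSignals(
        AudioSignal(calibrated, p.signal.sample_rate), bank.total_delay
    )


def time_align(
    p: ReproducedSignals,
    d: BinauralTarget,
    crop: int = DEFAULT_CROP,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance p by the known constant delay and crop both to ``crop`` samples.

    Alignment is deterministic -- the modeling and low-pass delays are known
    exactly -- rather than estimated by cross-correlation.
    """
    advanced = p.signal.samples[p.total_delay :]
    if advanced.shape[0] < crop or d.signal.n_samples < crop:
        raise ValueError(
            f"signals too short to crop to {crop} samples after delay removal"
        )
    return advanced[:crop], d.signal.samples[:crop]
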