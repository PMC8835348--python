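"""Synthetic acoustic plant: device-microphone impulse responses.

Stands in for a head-and-torso simulator wearing behind-the-ear devices in a
real room.  The head is a rigid sphere: each (source, microphone) path gets

* a propagation delay from the exact source-to-surface-point path length --
  straight line when the microphone is in view of the source, tangent line
  plus great-circle arc when it is shadowed (the Woodworth construction, so
  interaural time differences follow a(theta + sin theta)/c in the far field),
* 1/r spreading loss on the path length,
* a first-order low-pass "head shadow" whose cutoff falls as the incidence
  moves behind the head.

Rooms are modelled as a handful of first-order image sources (each passed
through the same head model) plus an optional exponentially decaying diffuse
tail pinned at a stated energy level relative to the direct path.  Everything
is deterministic given the seed.

Two presets mirror the study conditions: an anechoic chamber (sources at
1.5 m, no reflections) and a small clinical audiological booth (1.0 m, early
reflections within 20 ms, -50 dB diffuse tail).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .signals import DEFAULT_SAMPLE_RATE, AudioSignal, ImpulseResponseSet

__all__ = [
    "HeadModelSpec",
    "RoomSpec",
    "SourceLayout",
    "simulate_hadirs",
    "anechoic_preset",
    "booth_preset",
    "rotate_head",
    "speech_like_signal",
]

_FRAC_DELAY_TAPS = 32  # windowed-sinc fractional-delay kernel length
# Head-shadow low-pass cutoffs, set so the interaural level difference of a
# frontal +/-15 deg pair reaches a few dB by 3-4 kHz (typical rigid-sphere /
# manikin behaviour), rather than the sub-dB values a gentler filter gives.
_SHADOW_FC_MAX = 8_000.0  # Hz, cutoff at grazing incidence (90 deg)
_SHADOW_FC_MIN = 800.0  # Hz, cutoff directly behind the head (180 deg)


@dataclass(frozen=True)
class HeadModelSpec:
    """Rigid-sphere head with two behind-the-ear microphones.

    Azimuth convention: degrees, 0 in front, positive to the right.  The
    default microphones sit on the sphere surface at +/-100 degrees (slightly
    behind the ears, as behind-the-ear devices do).
    """

    radius: float = 0.0875  # m
    mic_azimuths: tuple[float, ...] = (-100.0, 100.0)  # left, right
    speed_of_sound: float = 343.0  # m/s

    def validate(self) -> None:
        if self.radius <= 0:
            raise ValueError("head radius must be positive")
        if len(self.mic_azimuths) != 2:
            raise ValueError("the core use case has exactly two microphones")


@dataclass(frozen=True)
class RoomSpec:
    """Early reflections (delay s, linear gain, azimuth deg) + diffuse tail.

    ``tail_level`` is energy in dB relative to the direct path (-inf for
    anechoic), decaying with time constant ``tail_decay`` seconds.
    ``absorption_cutoff`` models frequency-dependent surface absorption: each
    reflection passes a first-order low-pass at this cutoff (Hz), as the
    absorptive treatment of a clinical booth attenuates high frequencies far
    more than low ones.  ``None`` means perfectly reflective surfaces.
    """

    reflections: tuple[tuple[float, float, float], ...] = ()
    tail_level: float = -np.inf
    tail_decay: float = 0.15
    absorption_cutoff: float | None = None
    seed: int = 0

    def validate(self) -> None:
        for delay, gain, _az in self.reflections:
            if delay <= 0:
                raise ValueError("reflection delays must be positive")
            if abs(gain) >= 1:
                raise ValueError("reflection |gain| must be < 1")
        if self.tail_level > 0:
            raise ValueError("tail_level must be <= 0 dB")


@dataclass(frozen=True)
class SourceLayout:
    """Loudspeaker azimuths (deg, positive right) at a common distance (m)."""

    azimuths: tuple[float, ...]
    distance: float
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("source distance must be positive")
        for az in self.azimuths:
            if not -180.0 <= az < 180.0:
                raise ValueError("azimuths must lie in [-180, 180)")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"S{i}@{az:g}" for i, az in enumerate(self.azimuths))
            )

    @property
    def n_sources(self) -> int:
        return len(self.azimuths)


def _wrap_angle(deg: float) -> float:
    """Wrap to (-180, 180]."""
    return ((deg + 180.0) % 360.0) - 180.0


def _path_length(r: float, a: float, gamma_rad: float) -> float:
    """Exact source-to-surface-point distance on a rigid sphere.

    ``gamma_rad`` is the angle at the head centre between the source direction
    and the microphone position.  Beyond the tangent angle acos(a/r) the path
    wraps around the sphere (tangent segment + arc), which reproduces the
    Woodworth interaural delay in the far field.
    """
    gamma_t = np.arccos(a / r)
    if gamma_rad <= gamma_t:
        return np.sqrt(r * r + a * a - 2.0 * r * a * np.cos(gamma_rad))
    return np.sqrt(r * r - a * a) + a * (gamma_rad - gamma_t)


def _shadow_pole(gamma_deg: float, fs: int) -> float:
    """One-pole low-pass coefficient for incidence ``gamma_deg``; 0 = no shadow."""
    shade = (gamma_deg - 90.0) / 90.0
    if shade <= 0:
        return 0.0
    fc = _SHADOW_FC_MAX * (_SHADOW_FC_MIN / _SHADOW_FC_MAX) ** shade
    return float(np.exp(-2.0 * np.pi * fc / fs))


def _fractional_impulse(delay: float, length: int) -> np.ndarray:
    """Unit impulse at fractional ``delay`` samples via a windowed sinc."""
    out = np.zeros(length)
    half = _FRAC_DELAY_TAPS // 2
    indices = int(np.floor(delay)) + np.arange(-half + 1, half + 1)
    x = indices - delay  # in (-half-1, half); window centred on the true delay
    kernel = np.sinc(x) * (0.5 + 0.5 * np.cos(np.pi * np.clip(x / half, -1.0, 1.0)))
    valid = (indices >= 0) & (indices < length)
    out[indices[valid]] = kernel[valid]
    return out


def _single_arrival(
    head: HeadModelSpec,
    mic_az: float,
    source_az: float,
    distance: float,
    gain: float,
    extra_delay: float,
    fs: int,
    length: int,
) -> np.ndarray:
    """One arrival (direct or image source) through the sphere model."""
    gamma = abs(_wrap_angle(source_az - mic_az))
    path = _path_length(distance, head.radius, np.deg2rad(gamma))
    delay = (path / head.speed_of_sound + extra_delay) * fs
    if delay >= length:
        raise ValueError(
            f"impulse-response length {length} too short for arrival at "
            f"{delay:.1f} samples"
        )
    pulse = _fractional_impulse(delay, length) * (gain / path)
    pole = _shadow_pole(gamma, fs)
    if pole > 0.0:
        pulse = lfilter([1.0 - pole], [1.0, -pole], pulse)
    return pulse


def simulate_hadirs(
    head: HeadModelSpec,
    room: RoomSpec,
    layout: SourceLayout,
    fs: int = DEFAULT_SAMPLE_RATE,
    length: int = 2048,
) -> ImpulseResponseSet:
    """Simulate the device-microphone impulse responses for a layout.

    Deterministic given ``room.seed``: the diffuse tail draws one noise
    sequence per source (shared by both microphones, scaled per path), which
    keeps the plant exactly mirror-symmetric under azimuth negation.
    """
    head.validate()
    room.validate()
    n_mics = len(head.mic_azimuths)
    irs = np.zeros((n_mics, layout.n_sources, length))
    fs = int(fs)

    for l, src_az in enumerate(layout.azimuths):
        for m, mic_az in enumerate(head.mic_azimuths):
            direct = _single_arrival(
                head, mic_az, src_az, layout.distance, 1.0, 0.0, fs, length
            )
            ir = direct.copy()
            for delay, gain, refl_az in room.reflections:
                # a reflection delayed by `delay` is an image source that far
                # away: its 1/r loss comes from the full image distance
                image_distance = layout.distance + head.speed_of_sound * delay
                arrival = _single_arrival(
                    head, mic_az, refl_az, image_distance, gain, 0.0, fs, length
                )
                if room.absorption_cutoff is not None:
                    pole = float(np.exp(-2.0 * np.pi * room.absorption_cutoff / fs))
                    arrival = lfilter([1.0 - pole], [1.0, -pole], arrival)
                ir += arrival
            if np.isfinite(room.tail_level):
                onset = int(np.argmax(np.abs(direct) > 1e-9 * np.max(np.abs(direct))))
                # keying the noise on the path's own onset decorrelates the
                # tails between microphones (diffuse fields are interaurally
                # incoherent at high frequency) while remaining exactly
                # mirror-symmetric: mirrored geometries share onsets
                rng = np.random.default_rng([abs(int(room.seed)), l, onset])
                noise = rng.standard_normal(length)
                t = np.arange(length) - onset
                envelope = np.where(t >= 0, np.exp(-t / (room.tail_decay * fs)), 0.0)
                tail = noise * envelope
                direct_energy = float(np.sum(direct**2))
                tail_energy = float(np.sum(tail**2))
                if tail_energy > 0:
                    target = direct_energy * 10.0 ** (room.tail_level / 10.0)
                    ir += tail * np.sqrt(target / tail_energy)
            irs[m, l] = ir

    mic_labels = tuple(f"mic{m}@{az:g}" for m, az in enumerate(head.mic_azimuths))
    return ImpulseResponseSet(irs, fs, mic_labels, layout.labels)


def anechoic_preset() -> tuple[RoomSpec, SourceLayout]:
    """Anechoic chamber: six-source semicircle at 1.5 m, no reflections.

    The layout includes the compact virtual-acoustics pair at +/-15 deg, a
    hard-left source at -90 deg, and fills the semicircle symmetrically.
    """
    room = RoomSpec(reflections=(), tail_level=-np.inf)
    layout = SourceLayout(
        azimuths=(-90.0, -50.0, -15.0, 15.0, 50.0, 90.0),
        distance=1.5,
        labels=("L3", "L2", "L1", "R1", "R2", "R3"),
    )
    return room, layout


def booth_preset(seed: int = 0) -> tuple[RoomSpec, SourceLayout]:
    """Clinical booth: 1.0 m sources, early reflections within 20 ms,
    diffuse tail at -50 dB re the direct path with 0.15 s decay."""
    rng = np.random.default_rng(abs(int(seed)) + 17)
    n_refl = int(rng.integers(4, 9))
    reflections = tuple(
        (
            float(rng.uniform(0.003, 0.018)),  # s, extra delay re direct
            float(rng.uniform(0.10, 0.30) * rng.choice([-1.0, 1.0])),
            float(rng.uniform(-179.0, 179.0)),
        )
        for _ in range(n_refl)
    )
    room = RoomSpec(
        reflections=reflections,
        tail_level=-50.0,
        tail_decay=0.15,
        absorption_cutoff=1000.0,
        seed=seed,
    )
    layout = SourceLayout(
        azimuths=(-90.0, -50.0, -15.0, 15.0, 50.0, 90.0),
        distance=1.0,
        labels=("L3", "L2", "L1", "R1", "R2", "R3"),
    )
    return room, layout


#: Source indices of the virtual-acoustics loudspeaker pair in the presets.
VA_PAIR = (2, 3)


def rotate_head(layout: SourceLayout, angle: float) -> SourceLayout:
    """Head-relative layout after rotating the head by ``angle`` degrees.

    Positive angles are to the right; every source azimuth shifts by -angle.
    """
    if abs(angle) > 90:
        raise ValueError("|rotation| must be <= 90 degrees")
    new_az = tuple(_wrap_angle(az - angle) for az in layout.azimuths)
    return replace(layout, azimuths=new_az)


def speech_like_signal(
    duration: float,
    fs: int = DEFAULT_SAMPLE_RATE,
    seed: int = 0,
) -> AudioSignal:
    """Seeded speech-shaped test signal.

    Pink-spectrum (-3 dB/octave) noise with 4 Hz amplitude modulation and
    periodic pauses, peak-normalized to 0.5 so error levels in dB are
    comparable across runs.  Like female speech, the spectrum rolls off
    steeply below ~150 Hz (no energy under the fundamental) and above ~5 kHz.
    Deterministic given the seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    rng = np.random.default_rng(abs(int(seed)))
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 50.0))
    shaping *= freqs**2 / (freqs**2 + 150.0**2)  # below the fundamental
    high = freqs > 5000.0
    shaping[high] *= np.exp(-(freqs[high] - 5000.0) / 1500.0)
    pink = np.fft.irfft(spectrum * shaping, n)
    t = np.arange(n) / fs
    syllabic = 0.55 + 0.45 * np.sin(2.0 * np.pi * 4.0 * t)
    pauses = np.clip(1.5 * np.sin(2.0 * np.pi * 0.625 * t) + 1.0, 0.0, 1.0)
    shaped = pink * syllabic * pauses
    peak = np.max(np.abs(shaped))
    return AudioSignal(shaped * (0.5 / peak), fs)
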