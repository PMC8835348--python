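"""Shared audio containers, spectral conversion, WAV and report I/O.

Everything downstream (sweep deconvolution, plant simulation, inverse-filter
design, metrics) operates on three containers:

``AudioSignal``
    A float, channels-last time series at a known sample rate.  Amplitudes are
    dimensionless with nominal full scale +/-1; integer bit depth only exists
    at the WAV boundary.

``ImpulseResponseSet``
    The measured or simulated "plant": one impulse response per
    (microphone m, loudspeaker l) pair on a common time base, so interaural
    delays between paths are meaningful.

``PlantMatrix``
    The one-sided frequency-domain view G(f) of an impulse-response set: an
    M x L complex matrix per FFT bin.  Time-domain synthesis assumes Hermitian
    symmetry (real filters).
"""

from __future__ import annotations

import json
import wave
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile as _wavfile

DEFAULT_SAMPLE_RATE = 48_000

__all__ = [
    "AudioSignal",
    "ImpulseResponseSet",
    "PlantMatrix",
    "to_db",
    "read_wav",
    "write_wav",
    "plant_fft",
    "DEFAULT_SAMPLE_RATE",
]


@dataclass
class AudioSignal:
    """A (n_samples, n_channels) float time series at ``sample_rate`` Hz."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim == 1:
            samples = samples[:, None]
        if samples.ndim != 2:
            raise ValueError("samples must be 1-D or (n_samples, n_channels)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.samples = samples

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, index: int) -> np.ndarray:
        return self.samples[:, index]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_samples


@dataclass
class ImpulseResponseSet:
    """Impulse responses g_{ml} between L sources and M microphones.

    ``irs`` has shape (M, L, length); all paths share the sample rate and a
    common time origin, so relative (e.g. interaural) delays are preserved.
    """

    irs: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    mic_labels: tuple[str, ...] = ()
    source_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        irs = np.asarray(self.irs, dtype=np.float64)
        if irs.ndim != 3:
            raise ValueError("irs must have shape (M, L, length)")
        if not np.all(np.isfinite(irs)):
            raise ValueError("impulse responses must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.irs = irs
        if not self.mic_labels:
            self.mic_labels = tuple(f"mic{m}" for m in range(self.n_mics))
        if not self.source_labels:
            self.source_labels = tuple(f"src{l}" for l in range(self.n_sources))
        if len(self.mic_labels) != self.n_mics:
            raise ValueError("mic_labels length mismatch")
        if len(self.source_labels) != self.n_sources:
            raise ValueError("source_labels length mismatch")

    @property
    def n_mics(self) -> int:
        return self.irs.shape[0]

    @property
    def n_sources(self) -> int:
        return self.irs.shape[1]

    @property
    def length(self) -> int:
        return self.irs.shape[2]

    def path(self, mic: int, source: int) -> np.ndarray:
        return self.irs[mic, source]

    def select_sources(self, indices) -> "ImpulseResponseSet":
        """Sub-plant restricted to the given source columns (e.g. the VA pair)."""
        indices = list(indices)
        return ImpulseResponseSet(
            self.irs[:, indices, :],
            self.sample_rate,
            self.mic_labels,
            tuple(self.source_labels[i] for i in indices),
        )

    def scaled(self, factor: float) -> "ImpulseResponseSet":
        return ImpulseResponseSet(
            self.irs * factor, self.sample_rate, self.mic_labels, self.source_labels
        )

    def save(self, directory) -> None:
        """Write one WAV per path plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = {}
        for m in range(self.n_mics):
            for l in range(self.n_sources):
                name = f"ir_m{m}_l{l}.wav"
                write_wav(
                    AudioSignal(self.irs[m, l], self.sample_rate),
                    directory / name,
                    subtype="float32",
                )
                names[f"{m},{l}"] = name
        manifest = {
            "sample_rate": self.sample_rate,
            "n_mics": self.n_mics,
            "n_sources": self.n_sources,
            "length": self.length,
            "mic_labels": list(self.mic_labels),
            "source_labels": list(self.source_labels),
            "files": names,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "ImpulseResponseSet":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        irs = np.zeros((manifest["n_mics"], manifest["n_sources"], manifest["length"]))
        for key, name in manifest["files"].items():
            m, l = (int(v) for v in key.split(","))
            sig = read_wav(directory / name)
            irs[m, l] = sig.channel(0)
        return cls(
            irs,
            manifest["sample_rate"],
            tuple(manifest["mic_labels"]),
            tuple(manifest["source_labels"]),
        )


@dataclass
class PlantMatrix:
    """One-sided spectrum of an impulse-response set: G[k] is M x L per bin."""

    bins: np.ndarray  # (n_bins, M, L) complex
    frequencies: np.ndarray  # Hz, strictly increasing, 0..Nyquist
    fft_size: int
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.complex128)
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if self.bins.ndim != 3:
            raise ValueError("bins must have shape (n_bins, M, L)")
        if self.bins.shape[0] != self.frequencies.shape[0]:
            raise ValueError("bin count does not match frequency grid")
        if self.bins.shape[0] != self.fft_size // 2 + 1:
            raise ValueError("bin count does not match one-sided fft_size grid")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def n_mics(self) -> int:
        return self.bins.shape[1]

    @property
    def n_sources(self) -> int:
        return self.bins.shape[2]

    def to_impulse_responses(self) -> np.ndarray:
        """Hermitian synthesis back to (M, L, fft_size) time domain."""
        return np.fft.irfft(np.moveaxis(self.bins, 0, -1), n=self.fft_size, axis=-1)


def to_db(x):
    """Amplitude ratio -> decibels, 20*log10(x); 0 maps to -inf.

    Negative amplitudes have no dB value and raise ``ValueError``.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("to_db expects non-negative amplitude ratios")
    with np.errstate(divide="ignore"):
        out = 20.0 * np.log10(x)
    return float(out) if out.ndim == 0 else out


def from_db(db):
    """Inverse of :func:`to_db`."""
    return 10.0 ** (np.asarray(db, dtype=np.float64) / 20.0)


def _pack_int24(frames: np.ndarray) -> bytes:
    """Pack int32 values (already scaled to 24-bit range) into 3-byte LE frames."""
    as32 = frames.astype("<i4")
    raw = as32.view(np.uint8).reshape(-1, 4)
    return raw[:, :3].tobytes()


def write_wav(signal: AudioSignal, path, subtype: str = "pcm24") -> None:
    """Write an :class:`AudioSignal` as RIFF WAV.

    ``subtype`` is ``"pcm24"`` (24-bit integer, the acquisition format) or
    ``"float32"``.  Amplitudes outside +/-1 are clipped for pcm24.
    """
    path = Path(path)
    if subtype == "float32":
        _wavfile.write(path, signal.sample_rate, signal.samples.astype(np.float32))
    elif subtype == "pcm24":
        clipped = np.clip(signal.samples, -1.0, 1.0 - 2.0**-23)
        frames = np.round(clipped * 2**23).astype(np.int32)
        with wave.open(str(path), "wb") as handle:
            handle.setnchannels(signal.n_channels)
            handle.setsampwidth(3)
            handle.setframerate(signal.sample_rate)
            handle.writeframes(_pack_int24(frames.reshape(-1)))
    else:
        raise ValueError(f"unsupported WAV subtype: {subtype!r}")


def read_wav(path) -> AudioSignal:
    """Read a WAV file into float amplitudes in [-1, 1)."""
    path = Path(path)
    try:
        rate, data = _wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise ValueError(f"not a readable WAV file: {path}") from exc
    if data.dtype == np.int16:
        samples = data / 2.0**15
    elif data.dtype == np.int32:
        # 24-bit PCM is delivered left-justified in int32, so one scale covers both.
        samples = data / 2.0**31
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    return AudioSignal(samples, int(rate))


def plant_fft(irs: ImpulseResponseSet, fft_size: int) -> PlantMatrix:
    """Zero-pad every impulse response to ``fft_size`` and transform.

    Refuses to truncate: ``fft_size`` must be at least the IR length.
    """
    if fft_size < irs.length:
        raise ValueError(
            f"fft_size {fft_size} is shorter than the impulse responses "
            f"({irs.length} samples); truncation is not allowed"
        )
    spectra = np.fft.rfft(irs.irs, n=fft_size, axis=-1)  # (M, L, n_bins)
    bins = np.moveaxis(spectra, -1, 0)
    freqs = np.fft.rfftfreq(fft_size, d=1.0 / irs.sample_rate)
    return PlantMatrix(bins, freqs, fft_size, irs.sample_rate)
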