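"""Tikhonov-regularized crosstalk-cancellation filter design.

Given the plant G(w) (loudspeakers -> device microphones), the synthesis
filters realise the regularized pressure-matching solution

    q0(w) = G^H(w) (G(w) G^H(w) + beta I)^(-1) d(w),

with a modeling delay e^{-j w tau} folded into the target so the filters are
causal.  The full design chain, executed by :func:`design_filters`, is:

 1. normalize the impulse responses to full scale (one global factor),
 2. apply a modified Tukey window (raised-cosine fades around a flat section)
    to remove late reflections and noise that destabilise the inverse,
 3. transform to the frequency domain,
 4. invert each bin with Tikhonov regularization and the modeling delay,
 5. synthesise time-domain FIR filters,
 6. low-pass with a linear-phase FIR (default 99 taps, 8 kHz cutoff) to tame
    the roll-off near the device Nyquist,
 7. renormalize the bank to a peak amplitude of 1,
 8. circularly shift all filters by one common amount so energy decays before
    and after the main peak (causality), recording the exact total delay.

The regularization beta trades cancellation depth for robustness; the study
conditions use 0.0005 in the anechoic room and 0.001 in the booth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import fftconvolve, firwin

from .signals import ImpulseResponseSet, plant_fft

__all__ = [
    "TukeyWindowSpec",
    "DesignConfig",
    "InverseFilterBank",
    "normalize_set",
    "apply_window",
    "build_window",
    "tikhonov_bin_inverse",
    "design_filters",
    "suggest_window",
]


@dataclass(frozen=True)
class TukeyWindowSpec:
    """Modified Tukey window: zeros, raised-cosine fade in, flat top,
    raised-cosine fade out, zeros.  All fields in samples."""

    fade_in_start: int = 0
    fade_in_length: int = 32
    flat_length: int = 256
    fade_out_length: int = 128

    def __post_init__(self) -> None:
        for name in ("fade_in_start", "fade_in_length", "flat_length", "fade_out_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def end(self) -> int:
        return (
            self.fade_in_start
            + self.fade_in_length
            + self.flat_length
            + self.fade_out_length
        )


def build_window(spec: TukeyWindowSpec, length: int) -> np.ndarray:
    """Render the window to ``length`` samples (exactly 1 on the flat top)."""
    if spec.end > length:
        raise ValueError(
            f"window extends to sample {spec.end} but responses have only "
            f"{length} samples"
        )
    win = np.zeros(length)
    pos = spec.fade_in_start
    if spec.fade_in_length:
        k = np.arange(spec.fade_in_length)
        win[pos : pos + spec.fade_in_length] = 0.5 * (
            1.0 - np.cos(np.pi * (k + 1) / (spec.fade_in_length + 1))
        )
        pos += spec.fade_in_length
    win[pos : pos + spec.flat_length] = 1.0
    pos += spec.flat_length
    if spec.fade_out_length:
        k = np.arange(spec.fade_out_length)
        win[pos : pos + spec.fade_out_length] = 0.5 * (
            1.0 + np.cos(np.pi * (k + 1) / (spec.fade_out_length + 1))
        )
    return win


@dataclass(frozen=True)
class DesignConfig:
    """Inverse-filter design parameters.

    beta
        Frequency-independent Tikhonov regularization.
    fft_size
        Design grid length in samples; must cover the windowed responses.
    lowpass_taps / lowpass_cutoff
        Linear-phase FIR low-pass applied to the synthesized filters
        (odd tap count -> type-I symmetry).  ``lowpass_taps=0`` bypasses it.
    modeling_delay
        tau in samples; default fft_size // 2 if None.
    causal_shift
        Apply the final common circular shift (step 8).
    """

    beta: float = 0.0005
    fft_size: int = 8192
    lowpass_taps: int = 99
    lowpass_cutoff: float = 8000.0
    modeling_delay: int | None = None
    peak_norm_target: float = 1.0
    causal_shift: bool = True

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.lowpass_taps and self.lowpass_taps % 2 == 0:
            raise ValueError("lowpass_taps must be odd (type-I linear phase)")
        if self.modeling_delay is not None and self.modeling_delay < 0:
            raise ValueError("modeling_delay must be >= 0")
        if self.peak_norm_target <= 0:
            raise ValueError("peak_norm_target must be positive")

    def resolved_delay(self) -> int:
        return self.fft_size // 2 if self.modeling_delay is None else self.modeling_delay

    def lowpass_kernel(self, sample_rate: int) -> np.ndarray | None:
        if not self.lowpass_taps:
            return None
        if self.lowpass_cutoff > sample_rate / 2:
            raise ValueError("lowpass_cutoff above Nyquist")
        return firwin(self.lowpass_taps, self.lowpass_cutoff, fs=sample_rate)


@dataclass
class InverseFilterBank:
    """L x M FIR synthesis filters with exact delay bookkeeping.

    ``coeffs[l, m]`` is the filter from binaural input channel m to
    loudspeaker l.  ``total_delay`` (samples) is the constant delay the whole
    chain imposes on the target: modeling delay + low-pass group delay +
    causal shift.  Time alignment removes exactly this amount.
    """

    coeffs: np.ndarray  # (L, M, n_taps)
    sample_rate: int
    total_delay: int
    config: DesignConfig
    window: TukeyWindowSpec | None = None
    #: global factor applied at the peak-normalization step; dividing the
    #: coefficients by it recovers the unnormalized synthesis filters
    norm_scale: float = 1.0
    #: known end-to-end amplitude of the chain (plant * filters) for a unit
    #: target: the product of the input-normalization and peak-normalization
    #: factors.  Playback compensates it, like setting an amplifier gain.
    reproduction_gain: float = 1.0

    @property
    def n_sources(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.coeffs.shape[1]

    @property
    def n_taps(self) -> int:
        return self.coeffs.shape[2]

    def provenance(self) -> dict:
        prov = {
            "config": asdict(self.config),
            "window": asdict(self.window) if self.window else None,
            "total_delay": self.total_delay,
            "sample_rate": self.sample_rate,
            "shape": list(self.coeffs.shape),
            "norm_scale": self.norm_scale,
            "reproduction_gain": self.reproduction_gain,
        }
        prov["config"]["modeling_delay"] = self.config.resolved_delay()
        return prov


def normalize_set(irs: ImpulseResponseSet) -> ImpulseResponseSet:
    """Scale the whole set by one factor so its peak |sample| is 1.

    A single global factor exploits the full digital dynamic range while
    preserving the relative levels between paths.
    """
    peak = np.max(np.abs(irs.irs))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero impulse-response set")
    return irs.scaled(1.0 / peak)


def apply_window(irs: ImpulseResponseSet, spec: TukeyWindowSpec) -> ImpulseResponseSet:
    """Per-sample product with the modified Tukey window (same for all paths)."""
    win = build_window(spec, irs.length)
    return ImpulseResponseSet(
        irs.irs * win[None, None, :], irs.sample_rate, irs.mic_labels, irs.source_labels
    )


def tikhonov_bin_inverse(
    g_bin: np.ndarray, beta: float, frequency: float | None = None
) -> np.ndarray:
    """Per-bin regularized inverse H = G^H (G G^H + beta I)^(-1).

    Loudspeaker spectra for a target d are H @ d.  With beta = 0 the plant's
    Gram matrix must be invertible.
    """
    g_bin = np.asarray(g_bin, dtype=np.complex128)
    m = g_bin.shape[0]
    gram = g_bin @ g_bin.conj().T + beta * np.eye(m)
    if beta == 0:
        cond = np.linalg.cond(gram)
        if not np.isfinite(cond) or cond > 1e14:
            where = f" at {frequency:.1f} Hz" if frequency is not None else ""
            raise np.linalg.LinAlgError(
                f"G G^H is singular{where}; regularize (beta > 0) or window tighter"
            )
    return np.linalg.solve(gram, g_bin).conj().T


def _tikhonov_stack(g_bins: np.ndarray, beta: float) -> np.ndarray:
    """Vectorised tikhonov_bin_inverse over a (n_bins, M, L) stack."""
    m = g_bins.shape[1]
    gram = g_bins @ np.conj(np.swapaxes(g_bins, 1, 2)) + beta * np.eye(m)
    return np.conj(np.swapaxes(np.linalg.solve(gram, g_bins), 1, 2))


def design_filters(
    irs: ImpulseResponseSet,
    window: TukeyWindowSpec | None = None,
    config: DesignConfig | None = None,
) -> InverseFilterBank:
    """Run the full eight-stage design chain; see the module docstring."""
    config = config or DesignConfig()
    if irs.n_mics > irs.n_sources:
        raise ValueError(
            "the design requires no more microphones than loudspeakers "
            f"(got M={irs.n_mics}, L={irs.n_sources})"
        )

    # (1) full-scale normalization, (2) temporal windowing
    input_peak = float(np.max(np.abs(irs.irs)))
    prepared = normalize_set(irs)
    if window is not None:
        prepared = apply_window(prepared, window)
        # the window zeroes everything past its end; drop those samples so a
        # long raw acquisition does not force a larger design grid
        trimmed = prepared.irs[:, :, : window.end]
        prepared = ImpulseResponseSet(
            trimmed, prepared.sample_rate, prepared.mic_labels, prepared.source_labels
        )

    # (3) frequency domain on the design grid
    plant = plant_fft(prepared, config.fft_size)

    # (4) per-bin Tikhonov inverse with the modeling-delay phase
    tau = config.resolved_delay()
    try:
        h_bins = _tikhonov_stack(plant.bins, config.beta)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular plant Gram matrix during design; use beta > 0 or a "
            "tighter window"
        ) from exc
    phase = np.exp(-2j * np.pi * plant.frequencies * tau / irs.sample_rate)
    h_bins = h_bins * phase[:, None, None]

    # (5) back to the time domain: (L, M, fft_size)
    filters = np.fft.irfft(np.moveaxis(h_bins, 0, -1), n=config.fft_size, axis=-1)

    # (6) linear-phase FIR low-pass
    lowpass = config.lowpass_kernel(irs.sample_rate)
    lowpass_delay = 0
    if lowpass is not None:
        filters = fftconvolve(filters, lowpass[None, None, :], axes=-1)
        lowpass_delay = (config.lowpass_taps - 1) // 2

    if not np.all(np.isfinite(filters)):
        raise FloatingPointError(
            "inverse filters are not finite; increase beta or tighten the window"
        )

    # (7) one global scale to the target peak amplitude
    peak = np.max(np.abs(filters))
    if peak == 0:
        raise ValueError("designed filters are identically zero")
    norm_scale = config.peak_norm_target / peak
    filters = filters * norm_scale

    # (8) common circular shift so the bank's energy centroid sits at the
    # nominal delay, guaranteeing decay before and after the main peak
    total_delay = tau + lowpass_delay
    if config.causal_shift:
        energy = filters**2
        centroid = float(
            np.sum(energy * np.arange(filters.shape[-1])) / np.sum(energy)
        )
        shift = int(round(tau + lowpass_delay - centroid))
        filters = np.roll(filters, shift, axis=-1)
        total_delay += shift

    return InverseFilterBank(
        coeffs=filters,
        sample_rate=irs.sample_rate,
        total_delay=total_delay,
        config=config,
        window=window,
        norm_scale=norm_scale,
        reproduction_gain=norm_scale * input_peak,
    )


def suggest_window(irs: ImpulseResponseSet, room: str = "anechoic") -> TukeyWindowSpec:
    """Window preset derived from the measured onset.

    The fade-in ends just before the earliest direct-path onset across the
    set.  The anechoic flat section (256 samples) keeps only the direct sound;
    the booth flat section (1024 samples) additionally covers early
    reflections within 20 ms while the longer fade-out suppresses the diffuse
    tail before it can destabilise the inverse.
    """
    energy = np.max(np.abs(irs.irs), axis=(0, 1))
    threshold = 1e-3 * np.max(energy)
    onset = int(np.argmax(energy > threshold))
    if room == "anechoic":
        fade_in, flat, fade_out = 32, 256, 128
    elif room == "booth":
        fade_in, flat, fade_out = 32, 1024, 256
    else:
        raise ValueError("room must be 'anechoic' or 'booth'")
    start = max(onset - fade_in, 0)
    flat = min(flat, irs.length - start - fade_in - fade_out)
    if flat <= 0:
        raise ValueError("impulse responses too short for the requested window")
    return TukeyWindowSpec(start, fade_in, flat, fade_out)
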