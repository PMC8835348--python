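"""Physical reproduction metrics and the head-rotation harness.

Channel separation CS_1(w) = |p_1(w)/p_2(w)| (and its mirror for the other
input channel) is measured with unit-impulse targets, one input channel at a
time, propagated through the inverse filters and the raw plant.  Time-domain
accuracy is measured by per-sample absolute error AE_m[n] = |d_m[n] - p_m[n]|
and its mean (MAE), with Savitzky-Golay smoothing (window 1001, order 1) for
display.  All dB values are 20 log10 of an amplitude quantity.

The rotation harness re-simulates the plant at each head angle (+/-10 deg in
1 deg steps) and evaluates either the 0-degree filters (uncompensated) or
filters redesigned at that angle with identical parameters (compensated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as _fft
from scipy.signal import fftconvolve, savgol_filter

from .design import DesignConfig, InverseFilterBank, TukeyWindowSpec, design_filters
from .plant import (
    VA_PAIR,
    HeadModelSpec,
    RoomSpec,
    SourceLayout,
    rotate_head,
    simulate_hadirs,
)
from .signals import ImpulseResponseSet, to_db

__all__ = [
    "MetricsReport",
    "RotationReport",
    "channel_separation",
    "absolute_error",
    "mean_absolute_error",
    "smooth_ae",
    "response_analysis",
    "rotation_sweep",
    "DEFAULT_BAND",
    "SEPARATION_CAP_DB",
]

DEFAULT_BAND = (100.0, 7800.0)  # Hz, the effective passband
SEPARATION_CAP_DB = 120.0
SG_WINDOW = 1001
SG_ORDER = 1


@dataclass
class MetricsReport:
    """Frequency- and time-domain reproduction metrics for one condition."""

    frequencies: np.ndarray
    cs1_db: np.ndarray
    cs2_db: np.ndarray
    ae1: np.ndarray | None = None
    ae2: np.ndarray | None = None
    ae1_smooth: np.ndarray | None = None
    ae2_smooth: np.ndarray | None = None
    mae1: float | None = None
    mae2: float | None = None
    flatness_db: float | None = None
    phase_linearity_s: float | None = None
    band: tuple[float, float] = DEFAULT_BAND

    @property
    def mae1_db(self) -> float | None:
        return None if self.mae1 is None else to_db(self.mae1)

    @property
    def mae2_db(self) -> float | None:
        return None if self.mae2 is None else to_db(self.mae2)

    def band_mask(self) -> np.ndarray:
        lo, hi = self.band
        return (self.frequencies >= lo) & (self.frequencies <= hi)

    def separation_floor_db(self) -> float:
        """Minimum of both separation curves over the report band."""
        mask = self.band_mask()
        return float(min(self.cs1_db[mask].min(), self.cs2_db[mask].min()))

    def separation_median_db(self) -> float:
        """Band median of the per-bin worse of the two separation curves."""
        mask = self.band_mask()
        return float(np.median(np.minimum(self.cs1_db[mask], self.cs2_db[mask])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frequency_hz": self.frequencies, "cs1_db": self.cs1_db, "cs2_db": self.cs2_db}
        )

    def summary_dict(self) -> dict:
        return {
            "cs_min_db": self.separation_floor_db(),
            "cs_median_db": self.separation_median_db(),
            "mae1": self.mae1,
            "mae2": self.mae2,
            "mae1_db": self.mae1_db,
            "mae2_db": self.mae2_db,
            "flatness_db": self.flatness_db,
            "phase_linearity_s": self.phase_linearity_s,
            "band_hz": list(self.band),
        }


def _impulse_pressures(
    bank: InverseFilterBank, plant: ImpulseResponseSet, n_fft: int | None = None
):
    """Reproduced spectra for unit-impulse targets on each input channel.

    Returns (frequencies, P) where P[c, m] is the one-sided spectrum at
    microphone m when the impulse was sent to input channel c.
    """
    if plant.n_sources != bank.n_sources:
        raise ValueError("plant sources do not match the filter bank")
    n_time = bank.n_taps + plant.length - 1
    if n_fft is None:
        n_fft = _fft.next_fast_len(n_time)
    if n_fft < n_time:
        raise ValueError("n_fft too short for the end-to-end response")
    pressures = np.zeros((bank.n_inputs, plant.n_mics, n_time))
    for c in range(bank.n_inputs):
        for m in range(plant.n_mics):
            acc = np.zeros(n_time)
            for l in range(bank.n_sources):
                acc += fftconvolve(plant.irs[m, l], bank.coeffs[l, c])
            pressures[c, m] = acc
    spectra = _fft.rfft(pressures, n_fft, axis=-1)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / plant.sample_rate)
    return freqs, spectra


def separation_curve_db(bright: np.ndarray, dark: np.ndarray) -> np.ndarray:
    """20 log10 |bright/dark|, clipped to +/-SEPARATION_CAP_DB."""
    if not np.any(np.abs(bright)):
        raise ValueError("bright-channel pressure is zero; separation undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = 20.0 * np.log10(np.abs(bright) / np.abs(dark))
    ratio = np.nan_to_num(ratio, nan=SEPARATION_CAP_DB, posinf=SEPARATION_CAP_DB)
    return np.clip(ratio, -SEPARATION_CAP_DB, SEPARATION_CAP_DB)


def channel_separation(
    bank: InverseFilterBank,
    plant: ImpulseResponseSet,
    n_fft: int | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> MetricsReport:
    """CS curves from unit-impulse targets through filters and raw plant."""
    freqs, spectra = _impulse_pressures(bank, plant, n_fft)
    cs1 = separation_curve_db(spectra[0, 0], spectra[0, 1])
    cs2 = separation_curve_db(spectra[1, 1], spectra[1, 0])
    return MetricsReport(frequencies=freqs, cs1_db=cs1, cs2_db=cs2, band=band)


def absolute_error(d: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample |d_m[n] - p_m[n]| for the two aligned channels."""
    d = np.asarray(d)
    p = np.asarray(p)
    if d.shape != p.shape:
        raise ValueError("aligned signals must have identical shapes")
    err = np.abs(d - p)
    return err[:, 0], err[:, 1]


def mean_absolute_error(ae: np.ndarray) -> float:
    """Arithmetic mean of an absolute-error sequence (linear amplitude)."""
    ae = np.asarray(ae)
    if ae.size == 0:
        raise ValueError("empty error sequence")
    return float(np.mean(ae))


def smooth_ae(ae: np.ndarray) -> np.ndarray:
    """Savitzky-Golay smoothing, window 1001 / order 1, same-length output."""
    ae = np.asarray(ae, dtype=np.float64)
    if ae.shape[0] < SG_WINDOW:
        import warnings

        warnings.warn("sequence shorter than the smoothing window; returned as-is")
        return ae.copy()
    return savgol_filter(ae, SG_WINDOW, SG_ORDER)


def response_analysis(
    bank: InverseFilterBank,
    plant: ImpulseResponseSet,
    band: tuple[float, float] = DEFAULT_BAND,
    n_fft: int | None = None,
) -> tuple[float, float]:
    """Magnitude flatness and phase linearity of the bright channels.

    Returns ``(flatness_db, group_delay_deviation_s)``: the worst absolute
    deviation of the bright-channel magnitude (dB) from its band mean over
    both impulse conditions, and the worst absolute deviation of the group
    delay from its band median.  The band mean is the reference because the
    bank's peak normalization makes the absolute level arbitrary, and the
    bright channel is referenced to the design low-pass response first: the
    band limit is an intended part of the chain (it is applied to targets
    too), so flatness should expose inversion artifacts, not the low-pass
    transition edge.
    """
    lo, hi = band
    if hi <= lo:
        raise ValueError("empty analysis band")
    freqs, spectra = _impulse_pressures(bank, plant, n_fft)
    mask = (freqs >= lo) & (freqs <= hi)
    if not np.any(mask):
        raise ValueError("analysis band contains no FFT bins")
    lowpass = bank.config.lowpass_kernel(plant.sample_rate)
    reference = np.ones_like(freqs, dtype=np.complex128)
    if lowpass is not None:
        n_fft_used = 2 * (freqs.shape[0] - 1)
        reference = _fft.rfft(lowpass, n_fft_used)
    flatness = 0.0
    gd_deviation = 0.0
    for c in range(bank.n_inputs):
        bright = spectra[c, c] / reference
        mag_db = 20.0 * np.log10(np.abs(bright[mask]))
        flatness = max(flatness, float(np.max(np.abs(mag_db - mag_db.mean()))))
        phase = np.unwrap(np.angle(bright))[mask]
        # group delay tau_g = -dphi/dw from finite differences
        d_omega = 2.0 * np.pi * np.diff(freqs[mask])
        gd = -np.diff(phase) / d_omega
        gd_deviation = max(gd_deviation, float(np.max(np.abs(gd - np.median(gd)))))
    return flatness, gd_deviation


@dataclass
class RotationReport:
    """Per-angle summaries for uncompensated and compensated operation."""

    table: pd.DataFrame  # columns: angle_deg, mode, cs_min_db, cs_median_db, ...
    band: tuple[float, float] = DEFAULT_BAND

    def mode(self, mode: str) -> pd.DataFrame:
        return self.table[self.table["mode"] == mode].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rotation_sweep(
    head: HeadModelSpec,
    room: RoomSpec,
    layout: SourceLayout,
    window: TukeyWindowSpec | None = None,
    config: DesignConfig | None = None,
    angles=None,
    va_indices: tuple[int, int] = VA_PAIR,
    fs: int = 48_000,
    ir_length: int = 2048,
    band: tuple[float, float] = DEFAULT_BAND,
    modes: tuple[str, ...] = ("uncompensated", "compensated"),
    mae_source: int | None = None,
    speech_seed: int = 0,
    crop: int = 76_800,
) -> RotationReport:
    """Evaluate robustness to head rotation.

    For each angle the plant is re-simulated head-relative; the metrics use
    either the 0-degree filter bank (uncompensated) or a bank redesigned from
    the rotated plant with identical design parameters (compensated).

    If ``mae_source`` is given (an index into ``layout``), a speech-like
    target rendered from the *unrotated* plant for that source is reproduced
    through each rotated plant and the per-channel mean absolute errors are
    added to the summary table.
    """
    if angles is None:
        angles = range(-10, 11)
    angles = [int(a) for a in angles]
    if any(abs(a) > 10 for a in angles):
        raise ValueError("rotation angles are limited to [-10, 10] degrees")
    config = config or DesignConfig()

    from .design import suggest_window

    def _design(plant_set: ImpulseResponseSet) -> InverseFilterBank:
        win = window
        if win is None:
            win = suggest_window(
                plant_set, "anechoic" if not np.isfinite(room.tail_level) else "booth"
            )
        return design_filters(plant_set, win, config)

    base_full = simulate_hadirs(head, room, layout, fs, ir_length)
    base_plant = base_full.select_sources(va_indices)
    base_bank = _design(base_plant)

    target = None
    if mae_source is not None:
        from .plant import speech_like_signal
        from .reproduction import make_target

        kernel = config.lowpass_kernel(fs)
        speech = speech_like_signal(crop / fs, fs, speech_seed)
        target = make_target(mae_source, speech, base_full, kernel)

    rows = []
    for angle in angles:
        rotated_layout = rotate_head(layout, angle)
        rotated = simulate_hadirs(head, room, rotated_layout, fs, ir_length)
        rotated_va = rotated.select_sources(va_indices)
        for mode in modes:
            bank = base_bank if mode == "uncompensated" else _design(rotated_va)
            report = channel_separation(bank, rotated_va, band=band)
            row = {
                "angle_deg": angle,
                "mode": mode,
                "cs_min_db": report.separation_floor_db(),
                "cs_median_db": report.separation_median_db(),
            }
            if target is not None:
                from .reproduction import reproduce, time_align

                p = reproduce(target, bank, rotated_va)
                crop_n = min(crop, target.signal.n_samples,
                             p.signal.n_samples - bank.total_delay)
                aligned_p, aligned_d = time_align(p, target, crop_n)
                ae1, ae2 = absolute_error(aligned_d, aligned_p)
                row["mae1_db"] = to_db(mean_absolute_error(ae1))
                row["mae2_db"] = to_db(mean_absolute_error(ae2))
            rows.append(row)
    return RotationReport(pd.DataFrame(rows), band)
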