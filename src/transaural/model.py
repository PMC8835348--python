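"""Model/Results surface for pressure-matching filter design.

``PressureMatchingModel`` wraps a measured (or simulated) plant; ``fit()``
executes the design chain and returns ``InverseFilterResults``, which carries
the filter bank, its exact delay, diagnostics (channel separation, magnitude
flatness, phase linearity) and a ``summary()`` table.  Rendering, evaluation
against targets and plotting hang off the results object.

Example
-------
>>> from transaural import plant, model
>>> room, layout = plant.anechoic_preset()
>>> irs = plant.simulate_hadirs(plant.HeadModelSpec(), room, layout)
>>> res = model.PressureMatchingModel(irs.select_sources(plant.VA_PAIR)).fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, reproduction
from .design import (
    DesignConfig,
    InverseFilterBank,
    TukeyWindowSpec,
    design_filters,
    suggest_window,
)
from .evaluation import DEFAULT_BAND, MetricsReport
from .reproduction import BinauralTarget, ReproducedSignals
from .signals import AudioSignal, ImpulseResponseSet

__all__ = ["PressureMatchingModel", "InverseFilterResults"]


class PressureMatchingModel:
    """Tikhonov-regularized crosstalk-cancellation design for one plant.

    Parameters
    ----------
    plant
        Impulse responses between the control loudspeakers and the device
        microphones (M <= L).  This is the *design* plant; evaluation may use
        a different (e.g. raw or rotated) plant.
    window
        Temporal window applied before inversion; ``None`` selects a preset
        from the plant's onset (:func:`transaural.design.suggest_window`).
    config
        Design parameters (regularization, grids, low-pass, delays).
    """

    def __init__(
        self,
        plant: ImpulseResponseSet,
        window: TukeyWindowSpec | None = None,
        config: DesignConfig | None = None,
        room: str = "anechoic",
    ) -> None:
        if plant.n_mics > plant.n_sources:
            raise ValueError("need at least as many loudspeakers as microphones")
        self.plant = plant
        self.window = window if window is not None else suggest_window(plant, room)
        self.config = config or DesignConfig()

    @classmethod
    def from_simulation(
        cls,
        head,
        room_spec,
        layout,
        va_indices=None,
        config: DesignConfig | None = None,
        window: TukeyWindowSpec | None = None,
        fs: int = 48_000,
        ir_length: int = 2048,
        room: str = "anechoic",
    ) -> "PressureMatchingModel":
        """Build the design plant by simulating the study geometry."""
        from .plant import VA_PAIR, simulate_hadirs

        full = simulate_hadirs(head, room_spec, layout, fs, ir_length)
        sub = full.select_sources(va_indices if va_indices is not None else VA_PAIR)
        return cls(sub, window=window, config=config, room=room)

    def fit(self) -> "InverseFilterResults":
        bank = design_filters(self.plant, self.window, self.config)
        return InverseFilterResults(self, bank)


class InverseFilterResults:
    """Fitted inverse filters plus diagnostics.

    Attributes
    ----------
    bank : InverseFilterBank
        The L x M FIR filters with exact delay bookkeeping.
    """

    def __init__(self, model: PressureMatchingModel, bank: InverseFilterBank) -> None:
        self.model = model
        self.bank = bank
        self._cs_cache: dict = {}

    @property
    def total_delay(self) -> int:
        return self.bank.total_delay

    @property
    def config(self) -> DesignConfig:
        return self.bank.config

    # ---- diagnostics -----------------------------------------------------

    def channel_separation(
        self,
        eval_plant: ImpulseResponseSet | None = None,
        band=DEFAULT_BAND,
    ) -> MetricsReport:
        """CS curves through ``eval_plant`` (default: the raw design plant)."""
        plant = eval_plant if eval_plant is not None else self.model.plant
        key = (id(plant), band)
        if key not in self._cs_cache:
            self._cs_cache[key] = evaluation.channel_separation(
                self.bank, plant, band=band
            )
        return self._cs_cache[key]

    def response_analysis(
        self,
        eval_plant: ImpulseResponseSet | None = None,
        band=DEFAULT_BAND,
    ) -> tuple[float, float]:
        plant = eval_plant if eval_plant is not None else self.model.plant
        return evaluation.response_analysis(self.bank, plant, band)

    # ---- reproduction ----------------------------------------------------

    def render(self, target: BinauralTarget):
        return reproduction.render(target, self.bank)

    def reproduce(
        self, target: BinauralTarget, eval_plant: ImpulseResponseSet | None = None
    ) -> ReproducedSignals:
        plant = eval_plant if eval_plant is not None else self.model.plant
        return reproduction.reproduce(target, self.bank, plant)

    def evaluate(
        self,
        target: BinauralTarget,
        eval_plant: ImpulseResponseSet | None = None,
        crop: int = reproduction.DEFAULT_CROP,
        band=DEFAULT_BAND,
    ) -> MetricsReport:
        """Full time/frequency evaluation against a target signal."""
        plant = eval_plant if eval_plant is not None else self.model.plant
        p = self.reproduce(target, plant)
        aligned_p, aligned_d = reproduction.time_align(p, target, crop)
        ae1, ae2 = evaluation.absolute_error(aligned_d, aligned_p)
        report = self.channel_separation(plant, band)
        flat, gd = self.response_analysis(plant, band)
        return MetricsReport(
            frequencies=report.frequencies,
            cs1_db=report.cs1_db,
            cs2_db=report.cs2_db,
            ae1=ae1,
            ae2=ae2,
            ae1_smooth=evaluation.smooth_ae(ae1),
            ae2_smooth=evaluation.smooth_ae(ae2),
            mae1=evaluation.mean_absolute_error(ae1),
            mae2=evaluation.mean_absolute_error(ae2),
            flatness_db=flat,
            phase_linearity_s=gd,
            band=band,
        )

    # ---- presentation ----------------------------------------------------

    def summary(self, eval_plant: ImpulseResponseSet | None = None) -> str:
        """Plain-text summary of the design and its physical diagnostics."""
        cfg = self.config
        report = self.channel_separation(eval_plant)
        flat, gd = self.response_analysis(eval_plant)
        lo, hi = report.band
        rows = [
            ("Loudspeakers (L)", self.bank.n_sources),
            ("Microphones (M)", self.bank.n_inputs),
            ("Sample rate [Hz]", self.bank.sample_rate),
            ("Regularization beta", cfg.beta),
            ("Design FFT size", cfg.fft_size),
            ("Modeling delay [samples]", cfg.resolved_delay()),
            ("Low-pass", f"{cfg.lowpass_taps} taps @ {cfg.lowpass_cutoff:g} Hz"
             if cfg.lowpass_taps else "bypassed"),
            ("Total chain delay [samples]", self.total_delay),
            ("Filter length [taps]", self.bank.n_taps),
            (f"Min channel separation {lo:g}-{hi:g} Hz [dB]",
             f"{report.separation_floor_db():.1f}"),
            (f"Median channel separation [dB]",
             f"{report.separation_median_db():.1f}"),
            ("Magnitude flatness (max dev) [dB]", f"{flat:.3f}"),
            ("Group-delay deviation [ms]", f"{gd * 1e3:.4f}"),
        ]
        width = max(len(str(k)) for k, _ in rows)
        lines = ["Pressure-matching inverse filter design", "=" * (width + 22)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def summary_frame(self, eval_plant: ImpulseResponseSet | None = None) -> pd.DataFrame:
        report = self.channel_separation(eval_plant)
        flat, gd = self.response_analysis(eval_plant)
        return pd.DataFrame(
            [
                {
                    "beta": self.config.beta,
                    "fft_size": self.config.fft_size,
                    "total_delay": self.total_delay,
                    "cs_min_db": report.separation_floor_db(),
                    "cs_median_db": report.separation_median_db(),
                    "flatness_db": flat,
                    "group_delay_dev_s": gd,
                }
            ]
        )

    # ---- plotting --------------------------------------------------------

    def plot_separation(self, eval_plant=None, ax=None):
        """Channel-separation curves vs frequency (log axis)."""
        import matplotlib.pyplot as plt

        report = self.channel_separation(eval_plant)
        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(report.frequencies, report.cs1_db, label="CS1 (left impulse)")
        ax.semilogx(report.frequencies, report.cs2_db, "--", label="CS2 (right impulse)")
        ax.set_xlim(50, self.bank.sample_rate / 2)
        ax.set_xlabel("Frequency [Hz]")
        ax.set_ylabel("Channel separation [dB]")
        ax.axhline(20.0, color="k", lw=0.5, ls=":")
        ax.legend()
        return ax

    def plot_error(self, report: MetricsReport, ax=None):
        """Smoothed absolute-error curves in dB against time."""
        import matplotlib.pyplot as plt

        if report.ae1_smooth is None:
            raise ValueError("report has no time-domain errors; use evaluate()")
        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(report.ae1_smooth.shape[0]) / self.bank.sample_rate
        with np.errstate(divide="ignore"):
            ax.plot(t, 20 * np.log10(np.maximum(report.ae1_smooth, 1e-12)), label="AE1")
            ax.plot(t, 20 * np.log10(np.maximum(report.ae2_smooth, 1e-12)), label="AE2")
        ax.set_xlabel("Time [s]")
        ax.set_ylabel("Smoothed absolute error [dB]")
        ax.legend()
        return ax
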