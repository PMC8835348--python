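"""Inverse-filter design chain tests.

The per-bin regularized inverse is checked against a brute-force dense solve
(the independent oracle) and against hand-derived 2x2 closed forms; the full
chain is checked on an analytically tractable diagonal-delay plant.
"""

import numpy as np
import pytest

import transaural as ta
from transaural.design import (
    DesignConfig,
    TukeyWindowSpec,
    _tikhonov_stack,
    apply_window,
    build_window,
    design_filters,
    normalize_set,
    suggest_window,
    tikhonov_bin_inverse,
)
from transaural.signals import ImpulseResponseSet

FS = 48_000


class TestNormalize:
    def test_scales_global_peak_to_one(self, rng):
        irs = ImpulseResponseSet(rng.uniform(-0.4, 0.4, size=(2, 2, 32)), FS)
        irs.irs[0, 1, 3] = 0.5  # known global max
        out = normalize_set(irs)
        assert np.max(np.abs(out.irs)) == pytest.approx(1.0, abs=1e-15)
        np.testing.assert_allclose(out.irs, irs.irs / 0.5, atol=1e-12)

    def test_preserves_inter_path_ratios(self, rng):
        irs = ImpulseResponseSet(rng.standard_normal((2, 2, 32)), FS)
        out = normalize_set(irs)
        ratio = out.irs / irs.irs
        assert np.ptp(ratio) <= 1e-12  # one global scalar

    def test_idempotent(self, rng):
        irs = normalize_set(ImpulseResponseSet(rng.standard_normal((2, 2, 32)), FS))
        again = normalize_set(irs)
        np.testing.assert_allclose(again.irs, irs.irs, atol=1e-15)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_set(ImpulseResponseSet(np.zeros((1, 1, 8)), FS))


class TestWindow:
    def test_flat_section_passes_unchanged(self, rng):
        irs = ImpulseResponseSet(rng.standard_normal((1, 1, 256)), FS)
        spec = TukeyWindowSpec(fade_in_start=10, fade_in_length=16, flat_length=64,
                               fade_out_length=32)
        out = apply_window(irs, spec)
        flat = slice(26, 90)
        np.testing.assert_array_equal(out.irs[0, 0, flat], irs.irs[0, 0, flat])

    def test_zero_after_fade_out(self, rng):
        irs = ImpulseResponseSet(rng.standard_normal((1, 1, 256)), FS)
        spec = TukeyWindowSpec(0, 16, 64, 32)
        out = apply_window(irs, spec)
        assert not np.any(out.irs[0, 0, spec.end :])

    def test_degenerate_fades_give_rectangle(self):
        win = build_window(TukeyWindowSpec(5, 0, 40, 0), 64)
        assert win.sum() == 40.0
        assert set(np.unique(win)) == {0.0, 1.0}

    def test_window_longer_than_ir_rejected(self, rng):
        irs = ImpulseResponseSet(rng.standard_normal((1, 1, 64)), FS)
        with pytest.raises(ValueError):
            apply_window(irs, TukeyWindowSpec(0, 16, 64, 32))

    def test_window_values_bounded(self):
        win = build_window(TukeyWindowSpec(4, 8, 16, 8), 64)
        assert win.min() >= 0.0 and win.max() <= 1.0


class TestTikhonovInverse:
    def test_identity_unregularized(self):
        h = tikhonov_bin_inverse(np.eye(2, dtype=complex), 0.0)
        np.testing.assert_allclose(h, np.eye(2), atol=1e-14)

    def test_identity_with_beta_closed_form(self):
        beta = 0.25
        h = tikhonov_bin_inverse(np.eye(2, dtype=complex), beta)
        np.testing.assert_allclose(h, np.eye(2) / (1 + beta), atol=1e-12)

    def test_symmetric_crosstalk_closed_form(self):
        g = np.array([[1.0, 0.5], [0.5, 1.0]], dtype=complex)
        h = tikhonov_bin_inverse(g, 0.0)
        expected = np.array([[4 / 3, -2 / 3], [-2 / 3, 4 / 3]])
        np.testing.assert_allclose(h, expected, atol=1e-12)

    def test_matches_brute_force_dense_solve(self, rng):
        """Oracle: solve (G G^H + beta I) x = d columnwise, then G^H x."""
        bins = rng.standard_normal((50, 2, 2)) + 1j * rng.standard_normal((50, 2, 2))
        beta = 3e-4
        h = _tikhonov_stack(bins, beta)
        for k in range(50):
            g = bins[k]
            gram = g @ g.conj().T + beta * np.eye(2)
            expected = np.column_stack(
                [g.conj().T @ np.linalg.solve(gram, d) for d in np.eye(2)]
            )
            np.testing.assert_allclose(h[k], expected, atol=1e-10)

    def test_singular_without_regularization_raises(self):
        g = np.array([[1.0, 1.0], [1.0, 1.0]], dtype=complex)
        with pytest.raises(np.linalg.LinAlgError, match="440"):
            tikhonov_bin_inverse(g, 0.0, frequency=440.0)

    def test_effort_monotone_in_beta(self, rng):
        """Frobenius norm of H per bin is non-increasing along a beta grid."""
        bins = rng.standard_normal((20, 2, 2)) + 1j * rng.standard_normal((20, 2, 2))
        norms = []
        for beta in (0.0, 1e-4, 1e-3, 1e-2):
            h = _tikhonov_stack(bins, beta)
            norms.append(np.linalg.norm(h, axis=(1, 2)))
        norms = np.array(norms)
        assert np.all(np.diff(norms, axis=0) <= 1e-9)


def _diagonal_delay_plant(lags=(40, 55), length=128):
    irs = np.zeros((2, 2, length))
    for i, lag in enumerate(lags):
        irs[i, i, lag] = 1.0
    return ImpulseResponseSet(irs, FS)


class TestDesignChain:
    def test_diagonal_delay_plant_flat_reproduction(self):
        """beta=0 on a pure-delay decoupled plant: flat to 0.01 dB in band."""
        plant = _diagonal_delay_plant()
        cfg = DesignConfig(beta=0.0, fft_size=1024, lowpass_taps=0)
        bank = design_filters(plant, None, cfg)
        from transaural.evaluation import response_analysis

        flatness, gd_dev = response_analysis(bank, plant, band=(100.0, 7800.0))
        assert flatness <= 0.01
        assert gd_dev <= 1e-6

    def test_bank_peak_is_exactly_one(self, anechoic_results):
        assert np.max(np.abs(anechoic_results.bank.coeffs)) == pytest.approx(
            1.0, abs=1e-15
        )

    def test_lowpass_kernel_is_type_one_symmetric(self):
        kernel = DesignConfig().lowpass_kernel(FS)
        assert kernel.shape[0] == 99
        np.testing.assert_allclose(kernel, kernel[::-1], atol=1e-15)

    def test_scale_invariance(self, anechoic_va):
        """A global input gain leaves the normalized bank unchanged."""
        win = suggest_window(anechoic_va)
        cfg = DesignConfig()
        a = design_filters(anechoic_va, win, cfg)
        b = design_filters(anechoic_va.scaled(7.3), win, cfg)
        np.testing.assert_allclose(a.coeffs, b.coeffs, atol=1e-12)
        assert a.total_delay == b.total_delay

    def test_more_mics_than_sources_rejected(self, rng):
        irs = ImpulseResponseSet(rng.standard_normal((3, 2, 64)), FS)
        with pytest.raises(ValueError):
            design_filters(irs, None, DesignConfig(fft_size=128))

    def test_provenance_records_design(self, anechoic_results):
        prov = anechoic_results.bank.provenance()
        assert prov["config"]["beta"] == 0.0005
        assert prov["total_delay"] == anechoic_results.total_delay
        assert prov["config"]["modeling_delay"] == 4096

    def test_suggest_window_tracks_onset(self, anechoic_va):
        win = suggest_window(anechoic_va, "anechoic")
        onset = int(
            np.argmax(np.max(np.abs(anechoic_va.irs), axis=(0, 1))
                      > 1e-3 * np.max(np.abs(anechoic_va.irs)))
        )
        assert win.fade_in_start + win.fade_in_length <= onset
        assert win.end <= anechoic_va.length
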