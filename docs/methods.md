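# Methods

## Scope and model

`transaural` implements two-loudspeaker crosstalk cancellation (CTC) at the
microphones of behind-the-ear hearing-assistive devices, by Tikhonov-
regularized pressure matching. Per frequency bin the synthesis filters are

    H(ω) = Gᴴ(ω) (G(ω)Gᴴ(ω) + βI)⁻¹ · e^{−jωτ},

the minimum-norm regularized right-inverse of the M×L plant G. The package
always uses this form and enforces M ≤ L; there is no switch to the
overdetermined (left-inverse) form. β is frequency independent. With β = 0
and an invertible plant the chain is exact: the reproduced spectrum equals
the target spectrum times e^{−jωτ} at every design-grid bin (verified to
1e−6 relative, and in practice to ~1e−14, by the perfect-reconstruction
test).

## Design chain and its parameters

`design_filters` executes normalization → temporal windowing → FFT →
per-bin inversion → synthesis → low-pass → peak normalization → causal
shift. Parameters that matter:

- **β (regularization, dimensionless).** 0.0005 for the anechoic condition,
  0.001 for the booth. Relative to a plant normalized to unit peak
  amplitude, β bounds the per-bin filter gain by 1/(2√β); larger β deepens
  stability at the cost of cancellation and of low-frequency accuracy (the
  reproduction rolls off below ~60–100 Hz where the two plant columns
  become nearly collinear).
- **fft_size (design grid), default 8192 at 48 kHz (~171 ms).** Must be at
  least the windowed impulse-response length. The filters are the inverse
  DFT of H on this grid; energy at the buffer edges indicates time aliasing
  of a slowly decaying true inverse and is the practical sign that the
  window/regularization balance is wrong.
- **Modeling delay τ, default fft_size/2 samples.** Centers the
  (intrinsically two-sided) inverse in the buffer. Recorded exactly.
- **Low-pass: 99 taps, 8 kHz cutoff, windowed-sinc linear phase.** Protects
  against inversion of the plant's roll-off near the 8 kHz device Nyquist.
  Its group delay (49 samples) is part of the recorded total delay.
- **Modified Tukey window.** Raised-cosine fade-in ending just before the
  earliest direct-path onset, a flat section, and a raised-cosine fade-out.
  Presets: anechoic keeps 256 flat samples (direct sound only); the booth
  keeps 1024 flat samples (direct + early reflections within ~20 ms) and
  fades out over 256, excluding the diffuse tail. Windowing is the primary
  stabilizer in reverberant conditions; what it removes from the design
  plant returns as a bounded design/evaluation mismatch rather than an
  unbounded inversion error.
- **Peak normalization to 1** leaves a known end-to-end chain gain
  (`reproduction_gain`, the product of the input- and filter-normalization
  factors). Reproduction divides it out — the software analogue of setting
  the playback amplifier level. Channel separation, being a ratio, is
  unaffected.
- **Causal shift.** All filters are circularly shifted by one common integer
  so the bank's energy centroid sits at the nominal delay; the shift is
  folded into `total_delay`, which time alignment later removes. The rule is
  deterministic; any common shift is valid as long as it is tracked, which
  the delay-bookkeeping test checks against the end-to-end impulse peak.

## Evaluation conventions

- The forward (evaluation) path always uses the **raw, unwindowed** plant:
  the design/evaluation mismatch is the phenomenon of interest in
  reverberant rooms.
- Channel separation is computed from unit-impulse targets, one input
  channel at a time, as the bright/dark pressure ratio in dB on the
  one-sided FFT grid of the end-to-end response, clipped at ±120 dB where
  the dark channel underflows. CS₂ of a condition is exactly −CS₁ of the
  same condition in dB (reciprocity, asserted).
- Magnitude flatness is the maximum deviation of the bright-channel response
  from its band mean over 100–7800 Hz, **after referencing to the design
  low-pass response**: the band limit is an intended part of the chain (the
  same kernel is applied to targets), so flatness isolates artifacts the
  inversion itself imposes. Without that reference the low-pass transition
  edge near 8 kHz would dominate (~3 dB) and mask inversion artifacts.
  Phase linearity is reported as the maximum deviation of the finite-
  difference group delay from its band median.
- Time-domain error uses the known constant delay (no cross-correlation
  search), a 76,800-sample (1.6 s) crop, per-sample absolute error, its
  mean (reported linear and in dB re full scale; the speech fixture is
  pinned at peak 0.5 so dB values are comparable across runs), and
  Savitzky–Golay smoothing (window 1001, order 1) for display.
- "Most frequencies" is operationalized as the 10th percentile across band
  bins of the per-bin worse of the two separation curves.

## The synthetic plant

The simulator replaces a manikin wearing real devices in real rooms. It is
deliberately simple enough to be analytically checkable:

- **Head:** rigid sphere, radius 8.75 cm, microphones on the surface at
  ±100° azimuth. Propagation uses the exact source-to-surface path (straight
  line in view, tangent-plus-arc when shadowed), reproducing Woodworth
  interaural delays; fractional delays are realized by 32-tap windowed-sinc
  interpolation so delays are not quantized to samples. Head shadow is a
  first-order low-pass whose cutoff falls from 8 kHz at grazing incidence to
  800 Hz directly behind the head, giving the ±15° source pair an interaural
  level difference of a few dB by 3–4 kHz, as a real sphere does. This
  matters: near f ≈ 1/(2·ΔITD) ≈ 3.6 kHz both sources produce the same
  interaural phase modulo 2π, and only the level asymmetry keeps the plant
  matrix well conditioned there. (Consistently, the booth condition shows
  its weakest — but still bounded — separation around 3–4 kHz.)
- **Rooms:** the anechoic preset is the direct path only, six sources in a
  semicircle at 1.5 m including the virtual-acoustics pair at ±15° and a
  hard-left source at −90°. The booth preset (1.0 m) adds 4–8 seeded
  first-order reflections (|gain| ≤ 0.3, extra delays 3–18 ms) treated as
  true image sources at distance r + cδ with their own 1/r loss, each passed
  through a first-order absorption low-pass at 1 kHz (booth treatment
  absorbs high frequencies strongly), plus a seeded diffuse noise tail at
  −50 dB energy relative to the direct path with a 0.15 s decay constant.
  The tail noise is keyed on each path's onset delay, which decorrelates it
  between the ears while keeping the set exactly mirror-symmetric under
  azimuth negation (asserted to 1e−12).
- **Test signal:** seeded pink-spectrum noise (−3 dB/octave between 200 Hz
  and 4 kHz) with 4 Hz amplitude modulation and periodic pauses, rolling off
  below ~150 Hz and above ~5 kHz like female speech, peak 0.5.

What the fixture does *not* model: pinna and torso effects, elevation,
source directivity, measurement noise floors, air absorption, and late
reverberation beyond a first-order-plus-tail approximation. Passing tests
therefore demonstrate the correctness and conditioning behaviour of the
inversion chain under controlled, physically plausible plants — not
performance with any particular real device or room.

## Measurement chain

Plant identification uses an exponential sine sweep
s(t) = sin(2π f₁ T′ (e^{t/T′} − 1)), T′ = T/ln(f₂/f₁), default 1 Hz–24 kHz,
10 s, 1 s guard silences. Deconvolution is regularized spectral division
(floor 1e−12 of the peak power spectrum), which is amplitude-exact for
noise-free linear systems; harmonic distortion products land at negative
lags and are excluded by the crop. The default crop anchor is the time
origin, preserving absolute latency so that all paths of a set share a time
base (interaural delays survive); a peak anchor with a 1 ms pre-peak margin
is available for trimming acquisition latency. The known-system test
requires a seeded 256-tap FIR to be recovered below −80 dB MAE with −90 dB
measurement noise, which needs the full-band sweep (outside the sweep band
the division has no signal energy and amplifies noise).

## Numerical choices and degenerate inputs

- One-sided spectra with Hermitian synthesis throughout; sampling the
  end-to-end transfer function on the design grid is done via the even bins
  of a double-length FFT (the DTFT of a length-N sequence at the N-grid
  equals its N-point DFT).
- β = 0 with a singular per-bin Gram matrix raises a singularity error
  naming the frequency; non-finite filter coefficients raise an instability
  error suggesting more regularization or a tighter window.
- All-zero impulse-response sets are rejected at normalization; silent sweep
  recordings warn and return zero responses; sequences shorter than the
  smoothing window pass through with a warning.
- Problem sizes: 2048-sample anechoic / 8192-sample booth impulse responses,
  8192-point design grid, 1.6 s evaluation crops, and the full ±10°/1°
  rotation protocol; a complete simulated study runs in seconds.

## Known limitations

- The rigid-sphere ILD model is a first-order caricature; absolute
  separation figures depend on it, and only their qualitative structure
  (band edges, the 3–4 kHz booth weakness, rotation sensitivity) should be
  compared against measured systems.
- The booth's reflection pattern is randomized per seed, parameterized
  rather than calibrated to any particular room.
- dB MAE values depend on the target level convention (peak 0.5 here);
  comparisons are meaningful only within that convention.
- Real-time rendering, device playback, and perceptual validation are out
  of scope; convolution is offline.
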