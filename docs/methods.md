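# Methods

## Stimulus generator

The generator is the package's synthetic-data module and defines the study
conditions; its defaults are the published stimulus parameters.

**Frequency pool.** 129 pure-tone frequencies `179 · 2^(k/24)` Hz,
k = 0…128, i.e. equal 1/24-octave spacing from 179 Hz to just under
7246 Hz. Every component of every stimulus is a pool member.

**Chords and background.** Chords last 50 ms (25 ms in the compressed
design) and abut with no gap; each carries a random number of components —
uniform on the integers 5…15, mean 10 — drawn uniformly without replacement
from the pool, independently across chords. The uniform count law is the
minimal reading of "varying between 5 and 15 with average 10"; nothing
downstream depends on its exact shape beyond the mean. Each chord is the
equal-amplitude sum of its tones, shaped by 10 ms raised-cosine edge ramps;
the final waveform is peak-normalised and rendered at 44.1 kHz (written as
16-bit mono WAV — presentation is diotic, so one channel suffices).

**Figure.** A figure of coherence *c* and duration *d* adds *c* fixed
components to *d* consecutive chords, starting at a chord drawn uniformly
from 15…20 (750–1000 ms post onset). The figure is additive on an
independently drawn background; if a figure tone collides with a background
tone, the background tone is redrawn to a free pool slot, preserving both
the background count and the exact coherence (a pool frequency appears at
most once per chord). Ramped figures shift all figure components upward by
2 or 5 pool steps per chord; start indices are drawn low enough that the
ramp never leaves the pool (no wraparound). Isolated stimuli consist of the
figure window only; the figure chords keep their random background
components.

**Figure-absent controls.** Control trials add components that are redrawn
every chord (consecutive added sets are never identical), over a 2–7 chord
window at the same onset jitter. For the model's matched pairs the control
count equals the coherence and the control window equals the figure window,
and both members of a pair draw their per-chord background counts from a
shared stream — so figure and ground trials are indistinguishable in
per-chord component counts, chord for chord.

**Interleaved noise.** In the noise designs every chord is followed by a
broadband white-noise burst (50–500 ms) with 5 ms raised-cosine edges (not
specified upstream; prevents clicks). The burst gain is set so that the
realised RMS over the noise segments sits exactly 12 dB above the realised
RMS over the chord segments of the same stimulus — "level" is interpreted
as long-term segment RMS of the rendered audio, which makes the offset
directly measurable from the waveform.

**Determinism.** All sampling flows through a caller-supplied NumPy
generator; a config plus a seed reproduces chordgrams and waveforms bit for
bit. WAV output carries a JSON sidecar with the config echo, seed, figure
onset and per-chord component lists.

## Temporal-coherence model

The model scores a stimulus by how strongly any two distant frequency
channels fluctuate together, and scores a condition by the mean difference
of that score between figure and count-matched ground stimuli (the *model
response*, `delta`).

**Auditory spectrogram.** A bank of constant-Q Gaussian band-pass filters
on a 24-channels/octave log grid from 125 to 8000 Hz (144 channels).
Q = 16 (≈1/16-octave bandwidth) resolves individual pool components, which
the later spectral-scale stage requires; with much broader filters the
8 cyc/oct scale channel sees almost no structure. Envelopes are the
magnitude of the analytic band signal, low-passed at 150 Hz and resampled
to 400 frames/s (implemented as windowed slices of the signal's FFT shifted
to baseband — exact to the filter definition but far cheaper than filtering
144 full-rate bands). Frame count is `duration × 400 ± 1` for any input
length. An optional cube-root compression is off by default: the coherence
readout is level-standardised, which makes compression largely neutral.

**Spectrotemporal filtering.** One spectral scale (8 cyc/oct; 4 cyc/oct for
the steep-ramp design) and four modulation rates per experiment (2.5–20 Hz
for 50 ms chords, 5–40 Hz for 25 ms chords, plus 3.33 Hz for 300 ms noise
gaps). Scale and rate kernels share one construction: a complex Gaussian
Gabor with unit gain at its centre, an exact DC null, Q = 1 (-3 dB bandwidth
equal to the centre frequency) and 4-cycle truncation (±5σ). The scale
stage is kept *complex* and the temporal rate filter is applied to it, so
the separable scale→rate chain forms direction-selective spectrotemporal
filters (kernel and conjugate kernel give the two directions). This matters
for ramped figures: a pattern sweeping at *v* oct/s resonates at the rate
`scale × v` — for a 2-step ramp, 8 cyc/oct × (2/24 oct / 50 ms) ≈ 13 Hz,
which among the analysed rates is closest to 10 Hz — while static figures
respond at the chord presentation rate through their temporal envelope.
Rate outputs are decimated to ≥4 samples per cycle, which is lossless for
the statistic and keeps the pairwise stage cheap.

**Coherence stage.** For each rate and direction, windowed inner products
between all channel pairs are evaluated over windows of 4 cycles of the
rate, sliding by a quarter window; each pair's matrix entry is the maximum
over window positions, and the stimulus readout is the maximum off-diagonal
entry among pairs more than 2 channels apart (adjacent channels are
trivially coherent through filter overlap), averaged over the two direction
branches. Before rate filtering, the scale output is standardised by its
joint RMS so product magnitudes are comparable across stimuli.

Three normalisations of the windowed product are implemented:

- `window` (the public default of `coherence_matrix`): per-window
  Cauchy–Schwarz correlation; entries in [0, 1], unit diagonal, a pair
  proportional within any window scores 1.
- `global`: windowed product over whole-signal channel RMS; in [0, 1].
- `product` (the model default): raw windowed product magnitude divided by
  window length, on the standardised input; non-negative, not confined to
  [0, 1].

The model uses `product` deliberately. In sparse tone clouds, per-window
correlation is degenerate as a *maximum* statistic: with ~10⁴ admissible
pairs there is almost always some pair of weakly active channels whose few
pulses coincide, so the off-diagonal maximum saturates at 1 for figure and
ground alike. Raw products weight coherence by activity — a figure pair,
strongly and continuously co-active, produces a larger sustained product
than any chance single-chord coincidence — and this is what lets the
maximum track coherence, duration, presentation rate and ramp velocity at
once. Silent channels contribute 0 (never NaN) via a relative power floor
of 1e-8 in the correlation modes.

**Monte-Carlo protocol.** Per condition cell, `n_iter` fresh matched pairs
are generated and pushed through the pipeline; per rate the class means of
the readout and their difference are tabulated with dispersion across
iterations. The package default is `n_iter = 100` (the reference protocol
uses 500); the tests and the acceptance script use 100, and a cell at four
rates takes ~15–30 s on one CPU at that setting. Seeds derive from a single
integer per run; reruns are bit-identical. For the full-sequence designs
(50 ms and 25 ms basic detection) the entire 2 s / 1 s stimulus enters the
model; for the perturbation designs only the figure window does, since the
flanking background chords contribute little to the coherence matrix.
`best_rate` reports the rate with the largest mean delta, ties broken
toward the lower rate.

## Signal detection

Yes/no sensitivity is d′ = z(hit rate) − z(false-alarm rate) with the
log-linear correction (+0.5 per response cell) applied unconditionally —
ceiling hit rates around 93% make a documented correction necessary for
reproducibility, and the correction vanishes as counts grow. AXB
identification maps proportion correct through the differencing-model
approximation d′ = √2 · z(pc); the true AXB decision rule is unknown, so
this conventional choice is stated prominently rather than hidden.
Condition summaries report group mean d′ and between-subject SEM; a single
subject yields SEM = NaN (not applicable), and missing cells are reported
absent, never imputed.

## What the synthetic data do and do not show

The generator reproduces the stimulus *statistics* of the study designs
(component counts, onset jitter, count-matched controls, noise levels), so
model results here speak to the same stimulus ensemble the designs define.
It does not emulate listeners: no attention, training, memory or response
noise. Passing tests therefore show that the two-stage coherence analysis
extracts figure salience from these stimuli with the published qualitative
profile — not that it predicts individual human thresholds. Behavioural d′
values from human sessions (e.g. ceiling performance at high coherence)
require listeners and are outside what this package can recompute.

## Numerical choices and limitations

- Frame rate 400 Hz (≥10× the fastest rate analysed); envelope cut-off
  150 Hz; both exposed in `FrontendConfig`.
- Rate kernels are truncated Gaussians; DC response is nulled exactly, and
  centre-rate gain is exact by construction (verified to ±5% after
  truncation).
- Coherence matrices are forced exactly symmetric (pairwise products are
  computed by BLAS per triangle and can differ in the last ulp).
- Windows longer than the signal fall back to a single full-signal window
  with a warning (routine for slow rates on isolated 350 ms stimuli).
- The coherence maximum is an extreme-value statistic; its Monte-Carlo
  standard error is reported per cell, and argmax-rate readouts should use
  ≥100 iterations.
- The model covers one spectral scale per run, as the study designs do; the
  full 2-D rate–scale decomposition with lateral inhibition of the upstream
  cortical model is intentionally out of scope.
- Loudness calibration in dB SPL, headphone transfer functions and binaural
  rendering are out of scope; levels are defined on the normalised digital
  waveform.
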