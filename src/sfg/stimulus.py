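"""Stochastic figure-ground (SFG) stimulus synthesis.

The SFG stimulus is a rapid sequence of brief multi-tone chords whose
components are drawn at random from a fixed pool of log-spaced pure-tone
frequencies.  In *figure-present* trials a subset of components (the
"figure") repeats across a run of consecutive chords; everything else (the
"ground") is redrawn chord by chord.  Figure and ground overlap fully in
frequency, so the figure can only be found by integrating across frequency
*and* time.  Figure-absent control trials receive extra components that
change from chord to chord, matching the per-chord component counts of
figure trials without forming a coherent pattern.

The module produces both a symbolic description of a trial (:class:`ChordGram`,
pool indices per chord with background/figure/control labels — the ground
truth for analysis) and the rendered audio (:class:`Waveform`).
All randomness flows through a caller-supplied :class:`numpy.random.Generator`,
so a seed plus a config reproduces a stimulus bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "FrequencyPool",
    "StimulusConfig",
    "Chord",
    "ChordGram",
    "Waveform",
    "build_frequency_pool",
    "sample_background",
    "sample_chordgram",
    "sample_matched_pair",
    "embed_figure",
    "embed_control",
    "render_waveform",
    "segment_bounds",
    "make_axb_triplet",
]

#: Default pool bounds (Hz) and spacing (octaves): 129 frequencies between
#: 179 and 7246 Hz at a resolution of 1/24 octave.
DEFAULT_F_MIN = 179.0
DEFAULT_F_MAX = 7246.0
DEFAULT_STEP_OCTAVES = 1.0 / 24.0


@dataclass(frozen=True)
class FrequencyPool:
    """Ordered pool of candidate pure-tone frequencies, equally log-spaced."""

    frequencies: np.ndarray
    step_octaves: float
    f_min: float

    @property
    def size(self) -> int:
        return len(self.frequencies)

    def __len__(self) -> int:
        return len(self.frequencies)


def build_frequency_pool(
    f_min: float = DEFAULT_F_MIN,
    step_octaves: float = DEFAULT_STEP_OCTAVES,
    f_max: float = DEFAULT_F_MAX,
) -> FrequencyPool:
    """All frequencies ``f_min * 2**(k*step_octaves) <= f_max``, k = 0, 1, ...

    The defaults give the canonical 129-member pool from 179 Hz to 7246 Hz
    with adjacent components separated by 1/24 octave.
    """
    if f_min <= 0 or f_max <= 0 or f_min > f_max:
        raise ValueError(f"invalid pool bounds: f_min={f_min}, f_max={f_max}")
    if step_octaves <= 0:
        raise ValueError(f"step_octaves must be positive, got {step_octaves}")
    # tolerance so that an exact top frequency is kept despite rounding
    k_max = int(np.floor(np.log2(f_max / f_min) / step_octaves + 1e-9))
    freqs = f_min * 2.0 ** (np.arange(k_max + 1) * step_octaves)
    return FrequencyPool(frequencies=freqs, step_octaves=step_octaves, f_min=f_min)


@dataclass
class StimulusConfig:
    """Parameters of one SFG trial type.

    ``coherence`` counts the repeated (figure) components and
    ``figure_duration_chords`` the consecutive chords over which they repeat.
    ``ramp_step`` shifts the figure upward by that many pool steps per chord
    (0 = a fixed, repeating figure).  ``isolated`` trials contain the figure
    window only: no preceding or following background-only chords.
    ``noise_gap_ms`` > 0 inserts a broadband white-noise burst of that
    duration after every chord, ``noise_level_db`` above the chord level.
    """

    chord_duration_ms: float = 50.0
    n_chords: int = 40
    components_min: int = 5
    components_max: int = 15
    coherence: int = 0
    figure_duration_chords: int = 0
    onset_jitter_chords: tuple[int, int] = (15, 20)
    ramp_ms: float = 10.0
    ramp_step: int = 0
    isolated: bool = False
    noise_gap_ms: float = 0.0
    noise_level_db: float = 12.0
    sample_rate_hz: int = 44100
    pool: FrequencyPool = field(default_factory=build_frequency_pool)

    def __post_init__(self) -> None:
        if self.isolated:
            # isolated trials are exactly the figure window
            if self.figure_duration_chords <= 0:
                raise ValueError("isolated stimuli need figure_duration_chords > 0")
            self.n_chords = self.figure_duration_chords
        self.validate()

    def validate(self) -> None:
        if self.chord_duration_ms <= 0 or self.n_chords <= 0:
            raise ValueError("chord duration and chord count must be positive")
        if not (0 < self.components_min <= self.components_max <= self.pool.size):
            raise ValueError(
                f"invalid component count range "
                f"[{self.components_min}, {self.components_max}]"
            )
        if self.coherence < 0 or self.coherence > self.pool.size:
            raise ValueError(f"coherence {self.coherence} exceeds pool size")
        if self.figure_duration_chords < 0:
            raise ValueError("figure duration must be non-negative")
        if self.noise_gap_ms < 0 or self.ramp_ms < 0:
            raise ValueError("durations must be non-negative")
        lo, hi = self.onset_jitter_chords
        if lo > hi or lo < 0:
            raise ValueError(f"bad onset jitter range {self.onset_jitter_chords}")
        if not self.isolated and self.figure_duration_chords > 0:
            if self.figure_duration_chords + hi > self.n_chords:
                raise ValueError(
                    "figure (duration + latest onset) extends past the last chord"
                )


@dataclass
class Chord:
    """One chord as three labelled sets of pool indices."""

    background: np.ndarray
    figure: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    control: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def indices(self) -> np.ndarray:
        """All component indices of this chord (each frequency at most once)."""
        return np.concatenate([self.background, self.figure, self.control])

    def total_count(self) -> int:
        return len(self.background) + len(self.figure) + len(self.control)

    def copy(self) -> "Chord":
        return Chord(
            self.background.copy(), self.figure.copy(), self.control.copy()
        )


@dataclass
class ChordGram:
    """Symbolic stimulus: per-chord component sets plus figure metadata."""

    chords: list[Chord]
    pool: FrequencyPool
    chord_duration_ms: float
    figure_onset_chord: int | None = None
    figure_duration_chords: int = 0
    ramp_step: int = 0

    @property
    def n_chords(self) -> int:
        return len(self.chords)

    @property
    def figure_frequencies(self) -> np.ndarray:
        """Frequencies (Hz) of the figure components at figure onset."""
        if self.figure_onset_chord is None:
            return np.empty(0)
        first = self.chords[self.figure_onset_chord].figure
        return self.pool.frequencies[np.sort(first)]

    def background_counts(self) -> np.ndarray:
        return np.array([len(c.background) for c in self.chords])

    def total_counts(self) -> np.ndarray:
        return np.array([c.total_count() for c in self.chords])

    def copy(self) -> "ChordGram":
        return ChordGram(
            chords=[c.copy() for c in self.chords],
            pool=self.pool,
            chord_duration_ms=self.chord_duration_ms,
            figure_onset_chord=self.figure_onset_chord,
            figure_duration_chords=self.figure_duration_chords,
            ramp_step=self.ramp_step,
        )


@dataclass
class Waveform:
    """Peak-normalised mono audio."""

    samples: np.ndarray
    sample_rate_hz: int

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


# ---------------------------------------------------------------------------
# sampling


def sample_background(config: StimulusConfig, rng: np.random.Generator) -> ChordGram:
    """Draw the random tonal background: per chord, a uniform count of
    components (``components_min``..``components_max``) chosen uniformly
    without replacement from the pool, independently across chords."""
    chords = []
    for _ in range(config.n_chords):
        n = int(rng.integers(config.components_min, config.components_max + 1))
        idx = rng.choice(config.pool.size, size=n, replace=False)
        chords.append(Chord(background=np.sort(idx)))
    return ChordGram(
        chords=chords, pool=config.pool, chord_duration_ms=config.chord_duration_ms
    )


def _draw_figure_indices(
    config: StimulusConfig, rng: np.random.Generator
) -> np.ndarray:
    """Figure start indices, kept low enough that a ramped figure never
    leaves the pool: start + ramp_step*(duration-1) <= pool top."""
    span = config.ramp_step * max(config.figure_duration_chords - 1, 0)
    limit = config.pool.size - span
    if limit < config.coherence:
        raise ValueError(
            "coherence and ramp span leave too few admissible start indices"
        )
    return np.sort(rng.choice(limit, size=config.coherence, replace=False))


def _draw_onset(config: StimulusConfig, rng: np.random.Generator) -> int:
    if config.isolated:
        return 0
    lo, hi = config.onset_jitter_chords
    return int(rng.integers(lo, hi + 1))


def embed_figure(
    chordgram: ChordGram,
    figure_indices: Sequence[int],
    onset: int,
    duration: int,
    ramp_step: int = 0,
    rng: np.random.Generator | None = None,
) -> ChordGram:
    """Add a repeating (or upward-ramping) figure on top of the background.

    Chord ``onset + k`` receives ``figure_indices + k*ramp_step`` for
    ``k = 0..duration-1``.  The figure is additive: background components are
    kept, except that a background tone colliding with a figure tone is
    redrawn to a free pool slot so each frequency occurs at most once per
    chord while the background count and the exact coherence are preserved.
    """
    fig = np.asarray(figure_indices, dtype=np.intp)
    if len(np.unique(fig)) != len(fig):
        raise ValueError("figure indices must be distinct")
    if duration <= 0:
        raise ValueError("figure duration must be positive")
    if onset < 0 or onset + duration > chordgram.n_chords:
        raise ValueError("figure extends past the last chord")
    top = fig.max() + ramp_step * (duration - 1) if len(fig) else -1
    if len(fig) and (fig.min() < 0 or top >= chordgram.pool.size):
        raise ValueError(
            "ramped figure index exceeds the pool top; draw lower start indices"
        )
    if rng is None:
        rng = np.random.default_rng()

    out = chordgram.copy()
    for k in range(duration):
        chord = out.chords[onset + k]
        fk = fig + k * ramp_step
        collide = np.isin(chord.background, fk)
        if collide.any():
            used = np.union1d(chord.background, fk)
            free = np.setdiff1d(np.arange(chordgram.pool.size), used)
            repl = rng.choice(free, size=int(collide.sum()), replace=False)
            bg = chord.background.copy()
            bg[collide] = repl
            chord.background = np.sort(bg)
        chord.figure = fk.copy()
    out.figure_onset_chord = onset
    out.figure_duration_chords = duration
    out.ramp_step = ramp_step
    return out


def embed_control(
    chordgram: ChordGram,
    n_components: int,
    onset: int,
    duration: int,
    rng: np.random.Generator,
) -> ChordGram:
    """Add figure-absent control components: ``n_components`` extra tones on
    each of ``duration`` consecutive chords, redrawn per chord so consecutive
    added sets are never identical (no coherent pattern forms)."""
    if any(len(c.figure) for c in chordgram.chords):
        raise ValueError("control components belong in figure-absent stimuli")
    if n_components < 0:
        raise ValueError("n_components must be non-negative")
    if duration <= 0:
        raise ValueError("control duration must be positive")
    if onset < 0 or onset + duration > chordgram.n_chords:
        raise ValueError("control window extends past the last chord")
    if not (2 <= duration <= 7):
        warnings.warn(
            f"control duration {duration} outside the usual 2-7 chord range",
            stacklevel=2,
        )
    if n_components == 0:
        return chordgram.copy()

    out = chordgram.copy()
    prev: np.ndarray | None = None
    for k in range(duration):
        chord = out.chords[onset + k]
        free = np.setdiff1d(np.arange(chordgram.pool.size), chord.background)
        while True:
            added = np.sort(rng.choice(free, size=n_components, replace=False))
            if prev is None or not np.array_equal(added, prev):
                break
        chord.control = added
        prev = added
    return out


def sample_chordgram(
    config: StimulusConfig,
    rng: np.random.Generator,
    figure_present: bool = True,
) -> ChordGram:
    """Draw one complete trial.

    With ``coherence > 0`` and ``figure_present`` the background is generated
    first and the repeating figure added on top.  With ``figure_present``
    False, control components (count = coherence) are added instead over a
    2-7 chord window, as in the figure-absent half of a block.
    """
    config.validate()
    gram = sample_background(config, rng)
    if config.coherence == 0 or config.figure_duration_chords == 0:
        return gram
    onset = _draw_onset(config, rng)
    if figure_present:
        fig = _draw_figure_indices(config, rng)
        return embed_figure(
            gram, fig, onset, config.figure_duration_chords, config.ramp_step, rng
        )
    duration = int(rng.integers(2, 8)) if not config.isolated else config.n_chords
    duration = min(duration, config.n_chords - onset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return embed_control(gram, config.coherence, onset, duration, rng)


def sample_matched_pair(
    config: StimulusConfig, rng: np.random.Generator
) -> tuple[ChordGram, ChordGram]:
    """A figure trial and a count-matched ground trial.

    Both draw their per-chord background counts from the same stream, and the
    ground trial receives control components of the same number (= coherence)
    over the same window as the figure, so per-chord total component counts
    agree chord for chord.  Component identities are independent.
    """
    config.validate()
    onset = _draw_onset(config, rng)
    counts = rng.integers(
        config.components_min, config.components_max + 1, size=config.n_chords
    )
    seeds = rng.integers(0, 2**31, size=4)

    def draw_bg(seed: int) -> ChordGram:
        sub = np.random.default_rng(seed)
        chords = [
            Chord(background=np.sort(sub.choice(config.pool.size, int(n), False)))
            for n in counts
        ]
        return ChordGram(
            chords=chords,
            pool=config.pool,
            chord_duration_ms=config.chord_duration_ms,
        )

    fig_rng = np.random.default_rng(seeds[2])
    gnd_rng = np.random.default_rng(seeds[3])
    fig_indices = _draw_figure_indices(config, fig_rng)
    figure = embed_figure(
        draw_bg(int(seeds[0])),
        fig_indices,
        onset,
        config.figure_duration_chords,
        config.ramp_step,
        fig_rng,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ground = embed_control(
            draw_bg(int(seeds[1])),
            config.coherence,
            onset,
            config.figure_duration_chords,
            gnd_rng,
        )
    return figure, ground


def make_axb_triplet(
    config: StimulusConfig, rng: np.random.Generator
) -> tuple[ChordGram, ChordGram, ChordGram, str]:
    """A, X, B stimuli for the odd-one-out figure identification task.

    All three contain a figure and mutually different backgrounds; X shares
    its figure components with exactly one flanker.  Returns the grams plus
    which flanker ('A' or 'B') carries the odd figure.
    """
    if config.coherence != 6:
        raise ValueError("the AXB task uses a fixed coherence of 6")
    if config.figure_duration_chords not in (4, 8, 12):
        raise ValueError("AXB figure duration must be 4, 8 or 12 chords")
    shared = _draw_figure_indices(config, rng)
    while True:
        odd_fig = _draw_figure_indices(config, rng)
        if not np.array_equal(odd_fig, shared):
            break
    odd = "A" if rng.random() < 0.5 else "B"

    def build(fig_indices: np.ndarray) -> ChordGram:
        gram = sample_background(config, rng)
        onset = _draw_onset(config, rng)
        return embed_figure(
            gram, fig_indices, onset, config.figure_duration_chords,
            config.ramp_step, rng,
        )

    a = build(odd_fig if odd == "A" else shared)
    x = build(shared)
    b = build(odd_fig if odd == "B" else shared)
    return a, x, b, odd


# ---------------------------------------------------------------------------
# rendering


def _raised_cosine_envelope(n: int, ramp_samples: int) -> np.ndarray:
    env = np.ones(n)
    r = min(ramp_samples, n // 2)
    if r > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[n - r:] = ramp[::-1]
    return env


def segment_bounds(
    config: StimulusConfig,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Sample spans ``[start, end)`` of the chord and noise segments.

    Boundaries are placed on the exact cumulative time grid, so the rendered
    length in samples equals total duration times sample rate even when a
    single chord does not span an integer number of samples.
    """
    fs = config.sample_rate_hz
    period_ms = config.chord_duration_ms + config.noise_gap_ms
    chords, noises = [], []
    for k in range(config.n_chords):
        t0 = k * period_ms
        c0 = round(t0 * fs / 1000.0)
        c1 = round((t0 + config.chord_duration_ms) * fs / 1000.0)
        chords.append((c0, c1))
        if config.noise_gap_ms > 0:
            n1 = round((t0 + period_ms) * fs / 1000.0)
            noises.append((c1, n1))
    return chords, noises


def render_waveform(
    chordgram: ChordGram,
    config: StimulusConfig,
    rng: np.random.Generator | None = None,
) -> Waveform:
    """Render a chordgram to audio.

    Each chord is the equal-amplitude sum of its component pure tones, shaped
    by raised-cosine onset/offset ramps; chords abut with no gap.  When the
    config interleaves noise, each chord is followed by a broadband white
    noise burst whose within-segment RMS sits ``noise_level_db`` above the
    long-term RMS of the chord portions (5 ms raised-cosine edges keep the
    bursts click-free).  The final waveform is peak-normalised.
    """
    fs = config.sample_rate_hz
    chord_spans, noise_spans = segment_bounds(config)
    total = round(
        config.n_chords * (config.chord_duration_ms + config.noise_gap_ms)
        * fs / 1000.0
    )
    x = np.zeros(total)
    ramp = round(config.ramp_ms * fs / 1000.0)
    for chord, (c0, c1) in zip(chordgram.chords, chord_spans):
        idx = chord.indices()
        if len(idx) == 0:
            continue
        freqs = chordgram.pool.frequencies[idx]
        t = np.arange(c1 - c0) / fs
        tone_sum = np.sin(2.0 * np.pi * np.outer(freqs, t)).sum(axis=0)
        x[c0:c1] = tone_sum * _raised_cosine_envelope(c1 - c0, ramp)

    if noise_spans:
        chord_samples = np.concatenate([x[a:b] for a, b in chord_spans])
        chord_rms = np.sqrt(np.mean(chord_samples**2))
        if rng is None:
            rng = np.random.default_rng()
        noise_ramp = round(5e-3 * fs)
        bursts = [
            rng.standard_normal(b - a)
            * _raised_cosine_envelope(b - a, noise_ramp)
            for a, b in noise_spans
        ]
        cat = np.concatenate(bursts)
        raw_rms = np.sqrt(np.mean(cat**2))
        if chord_rms > 0 and raw_rms > 0:
            gain = chord_rms * 10.0 ** (config.noise_level_db / 20.0) / raw_rms
            for (a, b), burst in zip(noise_spans, bursts):
                x[a:b] = burst * gain

    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak
    return Waveform(samples=x, sample_rate_hz=fs)
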