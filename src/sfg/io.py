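"""Audio and annotation I/O: 16-bit mono WAV plus JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.io.wavfile

from .stimulus import ChordGram, StimulusConfig, Waveform

__all__ = ["save_wav", "load_wav", "save_annotation", "spectrogram_to_csv"]


def save_wav(path: str | Path, w: Waveform) -> None:
    """Write 16-bit PCM mono (diotic presentation needs one channel)."""
    pcm = np.clip(w.samples, -1.0, 1.0)
    scipy.io.wavfile.write(
        str(path), w.sample_rate_hz, (pcm * 32767.0).astype(np.int16)
    )


def load_wav(path: str | Path) -> Waveform:
    rate, data = scipy.io.wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.abs(np.iinfo(data.dtype).min)
    return Waveform(samples=np.asarray(data, dtype=float), sample_rate_hz=rate)


def save_annotation(
    path: str | Path,
    gram: ChordGram,
    config: StimulusConfig,
    seed: int | None = None,
) -> None:
    """JSON sidecar: config echo, seed, figure onset/frequencies, per-chord
    component lists — everything needed to audit a rendered stimulus."""
    onset = gram.figure_onset_chord
    doc = {
        "seed": seed,
        "config": {
            "chord_duration_ms": config.chord_duration_ms,
            "n_chords": config.n_chords,
            "components_min": config.components_min,
            "components_max": config.components_max,
            "coherence": config.coherence,
            "figure_duration_chords": config.figure_duration_chords,
            "onset_jitter_chords": list(config.onset_jitter_chords),
            "ramp_step": config.ramp_step,
            "isolated": config.isolated,
            "noise_gap_ms": config.noise_gap_ms,
            "noise_level_db": config.noise_level_db,
            "sample_rate_hz": config.sample_rate_hz,
        },
        "figure_onset_chord": onset,
        "figure_onset_ms": (
            None if onset is None else onset * gram.chord_duration_ms
        ),
        "figure_duration_chords": gram.figure_duration_chords,
        "figure_frequencies_hz": gram.figure_frequencies.tolist(),
        "chords": [
            {
                "background": c.background.tolist(),
                "figure": c.figure.tolist(),
                "control": c.control.tolist(),
            }
            for c in gram.chords
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def spectrogram_to_csv(path: str | Path, spec) -> None:
    """Persist an auditory spectrogram as frames x channels CSV with a
    header row of channel centre frequencies."""
    header = ",".join(f"{f:.2f}" for f in spec.channel_freqs)
    np.savetxt(str(path), spec.envelopes.T, delimiter=",", header=header, comments="")
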