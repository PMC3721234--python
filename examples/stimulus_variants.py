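"""Tour of the stimulus variants: ramped, isolated, noise-interleaved, AXB.

Builds one example of each perturbation the study designs use and prints
what changed relative to the basic sequence.
"""

import numpy as np

from sfg import StimulusConfig, make_axb_triplet, render_waveform, sample_chordgram, segment_bounds

rng = np.random.default_rng(0)

# ramped figure: components climb 2 pool steps (2/24 octave) per chord
cfg = StimulusConfig(coherence=4, figure_duration_chords=5, ramp_step=2)
gram = sample_chordgram(cfg, rng)
onset = gram.figure_onset_chord
print("ramped figure indices per chord:")
for k in range(5):
    print(f"  chord {onset + k}: {sorted(int(i) for i in gram.chords[onset + k].figure)}")

# isolated figure: the figure window only, no flanking background chords
iso = StimulusConfig(coherence=4, figure_duration_chords=5, isolated=True)
gram = sample_chordgram(iso, rng)
wav = render_waveform(gram, iso)
print(f"\nisolated stimulus: {gram.n_chords} chords, {wav.duration_s * 1000:.0f} ms")

# noise-interleaved: every chord followed by a louder broadband burst
noisy = StimulusConfig(coherence=6, figure_duration_chords=6, noise_gap_ms=50.0)
gram = sample_chordgram(noisy, rng)
wav = render_waveform(gram, noisy, rng=rng)
chords, noises = segment_bounds(noisy)
rms = lambda spans: np.sqrt(np.mean(np.concatenate(
    [wav.samples[a:b] for a, b in spans]) ** 2))
print(f"noise-interleaved: {wav.duration_s:.1f} s total, noise level "
      f"{20 * np.log10(rms(noises) / rms(chords)):+.1f} dB re chords")

# AXB triplet: X shares its figure with exactly one flanker
axb = StimulusConfig(coherence=6, figure_duration_chords=8)
a, x, b, odd = make_axb_triplet(axb, rng)
print(f"\nAXB triplet: odd figure in position {odd}; "
      f"X shares its figure with {'B' if odd == 'A' else 'A'}")
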