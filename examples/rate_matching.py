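"""Which modulation rate best separates figure from ground?

Runs the temporal-coherence model on basic 50-ms-chord stimuli (coherence 8,
duration 7) at four modulation rates.  The figure tones repeat once per
chord, i.e. at 20 Hz, so the 20 Hz rate filters should carry the largest
figure-minus-ground difference ("model response", delta).  With n_iter=25
this takes a few seconds; increase it for smoother estimates.
"""

from sfg import ModelConfig, StimulusConfig, best_rate, model_response

cfg = StimulusConfig(coherence=8, figure_duration_chords=7)
model = ModelConfig(rates_hz=(2.5, 5.0, 10.0, 20.0))
table = model_response([cfg], model, seed=0, n_iter=25)

print(table[["rate_hz", "mean_max_figure", "mean_max_ground",
             "delta", "sem_delta"]].round(3).to_string(index=False))
print(f"\nbest rate: {best_rate(table)} Hz "
      "(matches the 20 Hz chord presentation rate)")

# delta > 0 means figure stimuli produce larger maximal cross-channel
# coherence than their count-matched figure-absent controls; the rate at
# which delta peaks tracks how often the repeating tones are presented.
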