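"""Stimulus generator: pool construction, chord sampling, figure/control
embedding, rendering and the AXB triplet builder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chisquare

import sfg
from sfg import (
    StimulusConfig,
    build_frequency_pool,
    embed_control,
    embed_figure,
    make_axb_triplet,
    render_waveform,
    sample_background,
    sample_chordgram,
    sample_matched_pair,
    segment_bounds,
)


class TestFrequencyPool:
    def test_canonical_pool(self):
        pool = build_frequency_pool()
        assert pool.size == 129
        assert pool.frequencies[0] == pytest.approx(179.0)
        assert pool.frequencies[-1] <= 7246.0
        # closed form: the 25th entry is one octave above the first
        assert pool.frequencies[24] == pytest.approx(179.0 * 2.0, rel=1e-12)
        ratios = pool.frequencies[1:] / pool.frequencies[:-1]
        assert np.allclose(ratios, 2.0 ** (1.0 / 24.0), rtol=1e-9)

    def test_degenerate_range(self):
        pool = build_frequency_pool(179.0, 1.0 / 24.0, 179.0)
        assert pool.size == 1 and pool.frequencies[0] == 179.0

    @pytest.mark.parametrize(
        "f_min,step,f_max", [(-1, 1 / 24, 7246), (179, 0, 7246), (500, 1 / 24, 100)]
    )
    def test_invalid_parameters(self, f_min, step, f_max):
        with pytest.raises(ValueError):
            build_frequency_pool(f_min, step, f_max)

    @given(
        f_min=st.floats(20, 2000),
        octaves=st.floats(0.5, 6),
        step=st.floats(0.01, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_pool_properties(self, f_min, octaves, step):
        pool = build_frequency_pool(f_min, step, f_min * 2.0**octaves)
        f = pool.frequencies
        assert f[0] == pytest.approx(f_min)
        assert np.all(np.diff(f) > 0)
        assert f[-1] <= f_min * 2.0**octaves * (1 + 1e-9)
        if pool.size > 1:
            assert np.allclose(f[1:] / f[:-1], 2.0**step, rtol=1e-9)


class TestSampling:
    def test_figure_trial_structure(self):
        cfg = StimulusConfig(coherence=6, figure_duration_chords=7)
        gram = sample_chordgram(cfg, np.random.default_rng(0))
        assert gram.n_chords == 40
        fig_chords = [i for i, c in enumerate(gram.chords) if len(c.figure)]
        assert fig_chords == list(
            range(gram.figure_onset_chord, gram.figure_onset_chord + 7)
        )
        sets = [tuple(np.sort(gram.chords[i].figure)) for i in fig_chords]
        assert len(set(sets)) == 1 and len(sets[0]) == 6
        counts = gram.background_counts()
        assert counts.min() >= 5 and counts.max() <= 15
        # figure components never duplicate a background component
        for i in fig_chords:
            c = gram.chords[i]
            assert not np.intersect1d(c.background, c.figure).size

    def test_no_figure_when_coherence_zero(self):
        cfg = StimulusConfig(coherence=0, figure_duration_chords=0)
        gram = sample_chordgram(cfg, np.random.default_rng(1))
        assert all(len(c.figure) == 0 for c in gram.chords)
        assert gram.figure_onset_chord is None

    def test_mean_background_count(self):
        # expectation of the uniform integer law on 5..15 is 10
        cfg = StimulusConfig()
        rng = np.random.default_rng(2)
        counts = np.concatenate(
            [sample_background(cfg, rng).background_counts() for _ in range(250)]
        )
        assert len(counts) == 10_000
        assert abs(counts.mean() - 10.0) < 0.1

    def test_onset_jitter_uniform(self):
        cfg = StimulusConfig(coherence=4, figure_duration_chords=5)
        rng = np.random.default_rng(3)
        onsets = [sample_chordgram(cfg, rng).figure_onset_chord for _ in range(5000)]
        values, freq = np.unique(onsets, return_counts=True)
        assert values.min() >= 15 and values.max() <= 20
        assert chisquare(freq).pvalue > 0.001

    def test_determinism(self):
        cfg = StimulusConfig(coherence=6, figure_duration_chords=7)
        g1 = sample_chordgram(cfg, np.random.default_rng(7))
        g2 = sample_chordgram(cfg, np.random.default_rng(7))
        for a, b in zip(g1.chords, g2.chords):
            assert np.array_equal(a.background, b.background)
            assert np.array_equal(a.figure, b.figure)
        w1 = render_waveform(g1, cfg)
        w2 = render_waveform(g2, cfg)
        assert np.array_equal(w1.samples, w2.samples)

    def test_figure_overflow_rejected(self):
        with pytest.raises(ValueError):
            StimulusConfig(coherence=4, figure_duration_chords=30)


class TestEmbedFigure:
    def test_repeating_and_ramped(self):
        cfg = StimulusConfig()
        bg = sample_background(cfg, np.random.default_rng(0))
        out = embed_figure(bg, [10], onset=5, duration=3, ramp_step=2,
                           rng=np.random.default_rng(1))
        assert [list(out.chords[5 + k].figure) for k in range(3)] == [[10], [12], [14]]
        out0 = embed_figure(bg, [3, 40, 90], onset=8, duration=6, ramp_step=0,
                            rng=np.random.default_rng(1))
        sets = {tuple(out0.chords[8 + k].figure) for k in range(6)}
        assert sets == {(3, 40, 90)}

    def test_ramp_stays_inside_pool(self):
        # worst case: 8 components ramped by 5 steps over 9 chords
        cfg = StimulusConfig(
            coherence=8, figure_duration_chords=9, ramp_step=5, isolated=True
        )
        for seed in range(300):
            gram = sample_chordgram(cfg, np.random.default_rng(seed))
            for c in gram.chords:
                if len(c.figure):
                    assert c.figure.max() <= 128 and c.figure.min() >= 0

    def test_errors(self):
        cfg = StimulusConfig()
        bg = sample_background(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            embed_figure(bg, [5, 5], onset=0, duration=3)
        with pytest.raises(ValueError):
            embed_figure(bg, [127], onset=0, duration=3, ramp_step=2)
        with pytest.raises(ValueError):
            embed_figure(bg, [5], onset=38, duration=5)


class TestEmbedControl:
    def test_consecutive_sets_differ(self):
        cfg = StimulusConfig()
        bg = sample_background(cfg, np.random.default_rng(4))
        out = embed_control(bg, 6, onset=10, duration=4, rng=np.random.default_rng(5))
        added = [out.chords[10 + k].control for k in range(4)]
        assert all(len(a) == 6 for a in added)
        for a, b in zip(added, added[1:]):
            assert not np.array_equal(a, b)

    def test_zero_components_no_change(self):
        cfg = StimulusConfig()
        bg = sample_background(cfg, np.random.default_rng(4))
        out = embed_control(bg, 0, onset=10, duration=4, rng=np.random.default_rng(5))
        assert all(len(c.control) == 0 for c in out.chords)

    def test_duration_warning_and_figure_guard(self):
        cfg = StimulusConfig()
        bg = sample_background(cfg, np.random.default_rng(4))
        with pytest.warns(UserWarning):
            embed_control(bg, 4, onset=10, duration=9, rng=np.random.default_rng(5))
        fig = embed_figure(bg, [5], onset=10, duration=3, rng=np.random.default_rng(5))
        with pytest.raises(ValueError):
            embed_control(fig, 4, onset=10, duration=3, rng=np.random.default_rng(5))

    def test_matched_pair_counts_equal(self):
        # figure and control trials must not differ in per-chord energy budget
        cfg = StimulusConfig(coherence=6, figure_duration_chords=7)
        rng = np.random.default_rng(6)
        for _ in range(200):
            fig, gnd = sample_matched_pair(cfg, rng)
            assert np.array_equal(fig.total_counts(), gnd.total_counts())


class TestRender:
    def test_exact_durations(self):
        for cfg, n in [
            (StimulusConfig(), 88_200),  # 40 x 50 ms
            (StimulusConfig(chord_duration_ms=25.0), 44_100),  # 40 x 25 ms
            (StimulusConfig(coherence=4, figure_duration_chords=7, isolated=True),
             15_435),  # 350 ms figure window
            (StimulusConfig(noise_gap_ms=50.0), 176_400),  # interleaved noise
        ]:
            gram = sample_chordgram(cfg, np.random.default_rng(0))
            w = render_waveform(gram, cfg, rng=np.random.default_rng(1))
            assert len(w.samples) == n
            assert np.abs(w.samples).max() <= 1.0

    def test_empty_chordgram_is_silence(self):
        cfg = StimulusConfig()
        gram = sample_background(
            StimulusConfig(components_min=1, components_max=1),
            np.random.default_rng(0),
        )
        for c in gram.chords:
            c.background = np.empty(0, dtype=np.intp)
        w = render_waveform(gram, cfg)
        assert len(w.samples) == 88_200 and not np.any(w.samples)

    def test_single_tone_spectral_peak(self):
        # FFT oracle: the rendered chord's spectrum peaks at the component bin
        cfg = StimulusConfig(n_chords=1, components_min=1, components_max=1)
        gram = sample_background(cfg, np.random.default_rng(0))
        gram.chords[0].background = np.array([60])
        w = render_waveform(gram, cfg)
        spec = np.abs(np.fft.rfft(w.samples))
        f_bin = np.argmax(spec) * cfg.sample_rate_hz / len(w.samples)
        f_true = gram.pool.frequencies[60]
        assert abs(f_bin - f_true) < cfg.sample_rate_hz / len(w.samples) * 1.5

    def test_noise_level_offset(self):
        cfg = StimulusConfig(coherence=6, figure_duration_chords=6, noise_gap_ms=50.0)
        gram = sample_chordgram(cfg, np.random.default_rng(1))
        w = render_waveform(gram, cfg, rng=np.random.default_rng(2))
        chords, noises = segment_bounds(cfg)
        rms = lambda spans: np.sqrt(
            np.mean(np.concatenate([w.samples[a:b] for a, b in spans]) ** 2)
        )
        db = 20 * np.log10(rms(noises) / rms(chords))
        assert db == pytest.approx(12.0, abs=0.1)


class TestAXB:
    def test_triplet_structure(self):
        cfg = StimulusConfig(coherence=6, figure_duration_chords=8)
        a, x, b, odd = make_axb_triplet(cfg, np.random.default_rng(0))
        figs = {k: tuple(np.sort(g.chords[g.figure_onset_chord].figure))
                for k, g in (("A", a), ("X", x), ("B", b))}
        assert odd in ("A", "B")
        other = "B" if odd == "A" else "A"
        assert figs["X"] == figs[other] and figs["X"] != figs[odd]
        # matching figures identical chord for chord
        match = a if other == "A" else b
        for k in range(8):
            assert np.array_equal(
                np.sort(match.chords[match.figure_onset_chord + k].figure)
                - 0,  # identical index sets
                np.sort(x.chords[x.figure_onset_chord + k].figure),
            )
        # backgrounds differ between all three
        assert not np.array_equal(
            a.chords[0].background, b.chords[0].background
        ) or not np.array_equal(a.chords[1].background, b.chords[1].background)

    def test_odd_position_balanced(self):
        cfg = StimulusConfig(coherence=6, figure_duration_chords=4)
        rng = np.random.default_rng(1)
        odd = [make_axb_triplet(cfg, rng)[3] for _ in range(600)]
        frac_a = np.mean([o == "A" for o in odd])
        assert 0.43 < frac_a < 0.57  # binomial check at n=600

    def test_paradigm_constraints(self):
        with pytest.raises(ValueError):
            make_axb_triplet(
                StimulusConfig(coherence=4, figure_duration_chords=8),
                np.random.default_rng(0),
            )
        with pytest.raises(ValueError):
            make_axb_triplet(
                StimulusConfig(coherence=6, figure_duration_chords=5),
                np.random.default_rng(0),
            )


def test_pool_closure_and_annotation(tmp_path):
    """Every rendered component index addresses a pool member; the JSON
    sidecar round-trips the chordgram."""
    cfg = StimulusConfig(coherence=4, figure_duration_chords=5)
    gram = sample_chordgram(cfg, np.random.default_rng(0))
    for c in gram.chords:
        idx = c.indices()
        assert idx.min() >= 0 and idx.max() < gram.pool.size
        assert len(np.unique(idx)) == len(idx)
    sfg.save_annotation(tmp_path / "ann.json", gram, cfg, seed=0)
    import json

    doc = json.loads((tmp_path / "ann.json").read_text())
    assert doc["figure_onset_chord"] == gram.figure_onset_chord
    assert len(doc["chords"]) == 40
    assert doc["figure_onset_ms"] == gram.figure_onset_chord * 50.0
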