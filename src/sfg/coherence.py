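"""Temporal-coherence analysis: cross-channel correlation matrices and the
figure-minus-ground model response.

For each modulation rate, a windowed correlation is computed between every
pair of rate-filtered channels; the maximum over window positions fills a
channels-by-channels coherence matrix.  Channels carrying a temporally
coherent figure light up as high off-diagonal entries; a random ground does
not.  The scalar summary of a stimulus is the maximum off-diagonal entry
outside a near-diagonal exclusion band, and the *model response* (delta) of
a condition is the mean of that maximum over figure stimuli minus its mean
over count-matched ground stimuli, estimated by Monte-Carlo iteration over
freshly drawn stimuli.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cortical import (
    ModelConfig,
    RateFilterSpec,
    RateResponse,
    directional_scale_transform,
    rate_filter_array,
)
from .frontend import FrontendConfig, compute_spectrogram
from .stimulus import StimulusConfig, render_waveform, sample_matched_pair

__all__ = [
    "CoherenceMatrix",
    "coherence_matrix",
    "max_cross_correlation",
    "stimulus_max_correlation",
    "model_response",
    "best_rate",
]

#: Relative power floor below which a channel counts as silent in a window.
SILENT_POWER_FLOOR = 1e-8


@dataclass
class CoherenceMatrix:
    """Pairwise channel coherence at one rate.

    ``values`` is symmetric with unit diagonal, entries in [0, 1];
    ``time_of_max`` records the window start frame at which each pair
    attained its maximum.
    """

    values: np.ndarray
    rate_hz: float
    time_of_max: np.ndarray


def _window_starts(n_frames: int, window: int, hop: int) -> np.ndarray:
    starts = np.arange(0, n_frames - window + 1, hop)
    if starts[-1] != n_frames - window:
        starts = np.append(starts, n_frames - window)
    return starts


def coherence_matrix(
    r: RateResponse,
    window_cycles: float = 2.0,
    hop_frames: int | None = None,
    normalization: str = "window",
    eps: float = SILENT_POWER_FLOOR,
) -> CoherenceMatrix:
    """Windowed pairwise correlation of complex rate-filter outputs.

    The window spans ``window_cycles`` periods of the rate; windows slide by
    half a window (configurable via ``hop_frames``) and each pair's entry is
    the maximum normalised magnitude of the windowed inner product over all
    window positions.  Two normalisations are available:

    - ``"window"``: each window's inner product is divided by the product of
      the channel RMS *within that window* (per-window Cauchy-Schwarz, so a
      pair that is proportional inside any single window scores 1).
    - ``"global"``: the windowed inner product is divided by the product of
      the channel RMS over the *whole signal*, so a pair must be coherent for
      a substantial fraction of its total activity to score highly.
    - ``"product"``: raw windowed product magnitudes divided by the window
      length (mean product per frame), with no per-pair rescaling.  Strong,
      sustained coactivation then dominates brief chance coincidences, which
      is what separates a repeating figure from a random ground in sparse
      tone clouds; the model pipeline standardises the input level upstream
      and uses this variant.  Entries are non-negative but not confined to
      [0, 1], and the diagonal holds mean windowed channel powers.

    Near-silent channels (window power below ``eps`` times the strongest
    channel) contribute 0, not NaN.  Windows longer than the signal fall back
    to a single full-signal window with a warning.
    """
    R = r.values
    if R.shape[0] < 2:
        raise ValueError("coherence needs at least two channels")
    n_frames = R.shape[1]
    window = int(round(window_cycles * r.frame_rate_hz / r.rate_hz))
    if window < 1:
        raise ValueError("window must span at least one frame")
    if window > n_frames:
        warnings.warn(
            "window longer than signal; using a single full-signal window",
            stacklevel=2,
        )
        window = n_frames
    hop = hop_frames if hop_frames is not None else max(1, window // 2)
    starts = _window_starts(n_frames, window, hop)

    C = R.shape[0]
    best = np.zeros((C, C))
    t_max = np.zeros((C, C), dtype=np.intp)

    if normalization == "global":
        g_power = np.einsum("ct,ct->c", R, R.conj()).real
        g_floor = eps * max(g_power.max(), np.finfo(float).tiny)
        g_norm = np.sqrt(np.outer(np.maximum(g_power, g_floor), np.maximum(g_power, g_floor)))
    elif normalization not in ("window", "product"):
        raise ValueError(f"unknown normalization {normalization!r}")

    for s0 in starts:
        G = R[:, s0:s0 + window]
        S = G @ G.conj().T
        power = np.diag(S).real
        if normalization == "window":
            floor = eps * max(power.max(), np.finfo(float).tiny)
            active = power > floor
            denom = np.sqrt(np.outer(np.maximum(power, floor), np.maximum(power, floor)))
            M = np.abs(S) / denom
            M[~active, :] = 0.0
            M[:, ~active] = 0.0
        elif normalization == "product":
            M = np.abs(S) / window
        else:
            M = np.abs(S) / g_norm
            active = g_power > g_floor
            M[~active, :] = 0.0
            M[:, ~active] = 0.0
        M = np.maximum(M, M.T)  # exact symmetry despite rounding
        upd = M > best
        t_max[upd] = s0
        np.maximum(best, M, out=best)

    if normalization != "product":
        np.clip(best, 0.0, 1.0, out=best)
        np.fill_diagonal(best, 1.0)
    return CoherenceMatrix(values=best, rate_hz=r.rate_hz, time_of_max=t_max)


def max_cross_correlation(m: CoherenceMatrix, exclusion_span: int = 2) -> float:
    """Maximum off-diagonal coherence over pairs with ``|i - j| > span``.

    The excluded near-diagonal band removes pairs that are trivially
    coherent because neighbouring filters overlap on the same components.
    """
    if exclusion_span < 0:
        raise ValueError("exclusion span must be non-negative")
    v = m.values
    if v.shape[0] < 2 or v.shape[0] != v.shape[1]:
        raise ValueError("need a square coherence matrix of size >= 2")
    i, j = np.triu_indices_from(v, k=exclusion_span + 1)
    if len(i) == 0:
        raise ValueError("exclusion span leaves no admissible pairs")
    return float(v[i, j].max())


# ---------------------------------------------------------------------------
# Monte-Carlo model response


def _auto_decimation(frame_rate_hz: float, rate_hz: float) -> int:
    return max(1, int(frame_rate_hz // (4.0 * rate_hz)))


def stimulus_max_correlation(
    gram,
    config: StimulusConfig,
    model: ModelConfig,
    frontend: FrontendConfig = FrontendConfig(),
    rng: np.random.Generator | None = None,
) -> dict[float, float]:
    """Run one chordgram through the full pipeline; per-rate maxima.

    Spectrogram -> complex spectral-scale filtering (one branch per sweep
    direction) -> level standardisation (joint RMS of the branches, so
    product magnitudes are comparable across stimuli) -> per-rate Gabor
    filtering -> coherence matrix -> off-diagonal maximum, averaged over the
    two direction branches.  Rate responses are decimated to at least four
    samples per cycle, which loses nothing at the analysed rates.
    """
    wav = render_waveform(gram, config, rng=rng)
    spec = compute_spectrogram(wav, frontend)
    if model.scale_cyc_per_oct is not None:
        branches = list(directional_scale_transform(spec, model.scale_cyc_per_oct))
    else:
        branches = [spec.envelopes.astype(float)]
    rms = np.sqrt(np.mean([np.mean(np.abs(b) ** 2) for b in branches]))
    branches = [b / (rms + np.finfo(float).tiny) for b in branches]

    out: dict[float, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short stimuli: full-signal windows
        for rate in model.rates_hz:
            dec = _auto_decimation(spec.frame_rate_hz, rate)
            vals = []
            for b in branches:
                rr = rate_filter_array(
                    b, spec.frame_rate_hz, RateFilterSpec(rate, model.rate_q),
                    decimate=dec,
                )
                window = int(round(
                    model.window_cycles * rr.frame_rate_hz / rate
                ))
                cm = coherence_matrix(
                    rr,
                    model.window_cycles,
                    hop_frames=max(1, window // 4),
                    normalization=model.normalization,
                )
                vals.append(max_cross_correlation(cm, model.exclusion_span))
            out[rate] = float(np.mean(vals))
    return out


def model_response(
    grid: list[StimulusConfig],
    model: ModelConfig,
    seed: int,
    frontend: FrontendConfig = FrontendConfig(),
    n_iter: int | None = None,
    ground_vs_ground: bool = False,
    experiment: str = "",
) -> pd.DataFrame:
    """Monte-Carlo figure-minus-ground response over a stimulus grid.

    For every config cell and every rate, ``n_iter`` fresh figure stimuli and
    ``n_iter`` count-matched ground stimuli are generated, pushed through
    spectrogram, spectral-scale and rate filtering, and summarised by the
    off-diagonal coherence maximum.  The returned table has one row per
    (cell, rate) with the mean maxima of the two classes, their difference
    (the model response), and dispersion across iterations.

    ``ground_vs_ground=True`` replaces the figure stimulus with a second
    independent ground stimulus — a null calibration whose delta should sit
    within sampling error of zero.
    """
    n_iter = n_iter if n_iter is not None else model.n_iter
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rows = []
    for cell_idx, cfg in enumerate(grid):
        rng = np.random.default_rng([int(seed), cell_idx])
        max_f = {r: np.empty(n_iter) for r in model.rates_hz}
        max_g = {r: np.empty(n_iter) for r in model.rates_hz}
        for it in range(n_iter):
            try:
                fig, gnd = sample_matched_pair(cfg, rng)
                if ground_vs_ground:
                    _, fig = sample_matched_pair(cfg, rng)
                mf = stimulus_max_correlation(fig, cfg, model, frontend, rng)
                mg = stimulus_max_correlation(gnd, cfg, model, frontend, rng)
            except Exception as err:  # attach condition metadata
                raise RuntimeError(
                    f"model failed at coherence={cfg.coherence} "
                    f"duration={cfg.figure_duration_chords} iter={it}: {err}"
                ) from err
            for r in model.rates_hz:
                max_f[r][it] = mf[r]
                max_g[r][it] = mg[r]
        for r in model.rates_hz:
            f, g = max_f[r], max_g[r]
            sem = np.sqrt(
                (f.var(ddof=1) + g.var(ddof=1)) / n_iter
            ) if n_iter > 1 else np.nan
            rows.append(
                {
                    "experiment": experiment,
                    "coherence": cfg.coherence,
                    "duration": cfg.figure_duration_chords,
                    "chord_ms": cfg.chord_duration_ms,
                    "noise_gap_ms": cfg.noise_gap_ms,
                    "rate_hz": r,
                    "mean_max_figure": f.mean(),
                    "mean_max_ground": g.mean(),
                    "delta": f.mean() - g.mean(),
                    "sem_delta": sem,
                    "std_max_figure": f.std(ddof=1) if n_iter > 1 else np.nan,
                    "std_max_ground": g.std(ddof=1) if n_iter > 1 else np.nan,
                    "n_iter": n_iter,
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)


def best_rate(responses: pd.DataFrame) -> float:
    """The rate with the largest mean delta across the condition set; ties
    break toward the lower rate."""
    if len(responses) == 0:
        raise ValueError("empty response table")
    means = responses.groupby("rate_hz")["delta"].mean().sort_index()
    return float(means.idxmax())
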