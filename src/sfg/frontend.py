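"""Auditory spectrogram front end.

Converts a waveform into a matrix of band-limited channel envelopes on a
log-frequency axis — the input representation for the temporal-coherence
model.  The stage stands in for peripheral (cochlear) spectral analysis:
a constant-Q bank of Gaussian band-pass filters, envelope extraction via
the analytic signal, low-pass smoothing, and resampling to a modest frame
rate that still preserves all modulation content the later rate filters
(<= 40 Hz) care about.

The band-pass/Hilbert/low-pass chain is evaluated in the frequency domain:
for each channel the spectrum is windowed around the channel's centre
frequency and shifted to baseband, so the analytic envelope emerges directly
at a low sample rate without ever materialising 144 full-rate band signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .stimulus import Waveform

__all__ = ["FrontendConfig", "AuditorySpectrogram", "compute_spectrogram"]


@dataclass(frozen=True)
class FrontendConfig:
    """Front-end parameters.

    ``filter_q`` is centre frequency over -3 dB bandwidth of the Gaussian
    channel filters.  The default (Q = 16, roughly a 1/16-octave bandwidth)
    resolves individual components of the 1/24-octave stimulus pool, so the
    spectrogram exposes the fine spectral structure that the spectral-scale
    stage (8 cyc/oct) analyses downstream.  ``frame_rate_hz`` must stay well
    above the fastest modulation rate analysed downstream (40 Hz).
    """

    channels_per_octave: int = 24
    f_lo: float = 125.0
    f_hi: float = 8000.0
    envelope_cutoff_hz: float = 150.0
    frame_rate_hz: float = 400.0
    filter_q: float = 16.0
    compression: bool = False  # optional cube-root envelope compression

    def __post_init__(self) -> None:
        if self.f_lo >= self.f_hi:
            raise ValueError("f_lo must be below f_hi")
        if self.frame_rate_hz < 2 * 40.0 * 5:
            raise ValueError("frame rate too low to sample 40 Hz modulations")

    @property
    def n_channels(self) -> int:
        return int(round(self.channels_per_octave * np.log2(self.f_hi / self.f_lo)))

    @property
    def channel_freqs(self) -> np.ndarray:
        k = np.arange(self.n_channels)
        return self.f_lo * 2.0 ** (k / self.channels_per_octave)


@dataclass
class AuditorySpectrogram:
    """Channel envelopes (channels x frames, non-negative)."""

    envelopes: np.ndarray
    channel_freqs: np.ndarray
    frame_rate_hz: float

    @property
    def n_channels(self) -> int:
        return self.envelopes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.envelopes.shape[1]


def compute_spectrogram(
    w: Waveform, cfg: FrontendConfig = FrontendConfig()
) -> AuditorySpectrogram:
    """Band-pass each channel, extract the envelope, smooth and downsample.

    For channel centre :math:`f_c` the analytic band signal is obtained by
    applying a Gaussian transfer function around :math:`f_c` to the one-sided
    spectrum; demodulating it to baseband makes its magnitude available at a
    reduced sample rate (the slice is widened to cover at least +-4 sigma of
    the filter).  Envelopes are then Fourier-resampled onto the common frame
    grid and low-pass filtered at ``envelope_cutoff_hz``.
    """
    x = np.asarray(w.samples, dtype=float)
    fs = w.sample_rate_hz
    if x.size == 0:
        raise ValueError("empty waveform")
    if fs < 2 * cfg.f_hi:
        raise ValueError(f"sample rate {fs} too low for f_hi={cfg.f_hi}")

    n = len(x)
    n_frames = max(1, round(n * cfg.frame_rate_hz / fs))
    X = np.fft.fft(x)
    freqs_all = np.fft.fftfreq(n, 1.0 / fs)

    centers = cfg.channel_freqs
    sigma = centers / cfg.filter_q / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    env = np.empty((len(centers), n_frames))
    half_frames = (n_frames + 1) // 2
    for k, (fc, sig) in enumerate(zip(centers, sigma)):
        half_bw_hz = max(cfg.frame_rate_hz / 2.0, 4.0 * sig)
        h = min(int(np.ceil(half_bw_hz * n / fs)), n // 2 - 1)
        m = 2 * h + 1
        c = int(round(fc * n / fs))
        offs = np.fft.fftfreq(m, 1.0 / m).astype(int)
        bins = c + offs
        fbin = freqs_all[bins % n]
        weight = np.exp(-0.5 * ((fbin - fc) / sig) ** 2)
        weight[(bins <= 0) | (bins >= n // 2)] = 0.0  # analytic: positive freqs only
        z = np.fft.ifft(X[bins % n] * weight)
        e = np.abs(z)
        # exact Fourier resampling of the envelope onto the frame grid
        E = np.fft.fft(e)
        Ef = np.zeros(n_frames, dtype=complex)
        hi = min(half_frames, (m + 1) // 2)
        Ef[:hi] = E[:hi]
        lo = min(n_frames // 2, m // 2)
        if lo > 0:
            Ef[n_frames - lo:] = E[m - lo:]
        env[k] = np.fft.ifft(Ef).real * (n_frames / m)

    # low-pass smoothing of the envelopes along time
    nyq = cfg.frame_rate_hz / 2.0
    if cfg.envelope_cutoff_hz < nyq and n_frames > 16:
        taps = scipy.signal.firwin(
            min(31, 2 * (n_frames // 2) - 1), cfg.envelope_cutoff_hz / nyq
        )
        env = scipy.signal.fftconvolve(env, taps[None, :], mode="same", axes=1)
    env = np.clip(env, 0.0, None)
    if cfg.compression:
        env = np.cbrt(env)
    return AuditorySpectrogram(
        envelopes=env, channel_freqs=centers, frame_rate_hz=cfg.frame_rate_hz
    )
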