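"""Time-insensitive coda assembly and spectrogram rendering.

Per-click segments are cut around the click peak, DC-centered,
peak-normalized to [-1, 1], and concatenated in click order so that
inter-click timing is removed.  Session waveforms separate codas with a
buffer of exact-zero silence (default 25 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import ClickAnnotation, Recording, logger


@dataclass
class ClickSegment:
    coda_id: str
    click_index: int
    samples: np.ndarray
    start_offset_ms: float
    duration_ms: float
    sample_rate_hz: float


@dataclass
class TimeInsensitiveCoda:
    coda_id: str
    samples: np.ndarray
    segment_duration_ms: float
    n_clicks: int
    sample_rate_hz: float

    @property
    def duration_ms(self) -> float:
        return self.n_clicks * self.segment_duration_ms


def resolve_peak_time(recording: Recording, click: ClickAnnotation,
                      search_ms: float = 15.0) -> float:
    """Time of the maximum |amplitude| sample for a click.

    Uses the annotated ``peak_time_s`` when present; otherwise searches a
    window after the annotated click time, since annotated times do not
    reliably coincide with the highest click peak.
    """
    if click.peak_time_s is not None:
        return click.peak_time_s
    i0 = recording.time_to_index(click.click_time_s)
    i1 = min(len(recording.samples), i0 + int(round(search_ms / 1000 * recording.sample_rate_hz)))
    if i0 >= len(recording.samples) or i1 <= i0:
        raise ValueError(f"click at {click.click_time_s}s lies outside the recording")
    window = recording.samples[i0:i1]
    return (i0 + int(np.argmax(np.abs(window)))) / recording.sample_rate_hz


def center_and_normalize(samples: np.ndarray) -> np.ndarray:
    """Subtract the mean, then scale the result so max |amplitude| = 1.

    All-constant input yields all zeros (normalization skipped with a
    warning) rather than a division by zero.
    """
    centered = samples - samples.mean() if len(samples) else samples
    peak = np.max(np.abs(centered)) if len(centered) else 0.0
    if peak == 0:
        if len(samples):
            logger.warning("all-constant segment: normalization skipped")
        return np.zeros_like(samples, dtype=float)
    return centered / peak


def extract_click_segment(recording: Recording, click: ClickAnnotation,
                          start_offset_ms: float = -2.0, duration_ms: float = 15.0,
                          peak_search_ms: float = 15.0) -> ClickSegment:
    """Cut a peak-relative window, DC-center it, and peak-normalize it.

    The segment starts ``start_offset_ms`` relative to the click peak
    (negative = before) and has exactly ``round(duration_ms * fs / 1000)``
    samples; parts outside the recording are zero-padded and logged.
    """
    fs = recording.sample_rate_hz
    peak_t = resolve_peak_time(recording, click, search_ms=peak_search_ms)
    n = int(round(duration_ms * fs / 1000.0))
    start = int(round((peak_t + start_offset_ms / 1000.0) * fs))
    seg = np.zeros(n)
    lo, hi = max(start, 0), min(start + n, len(recording.samples))
    if lo >= len(recording.samples) or hi <= 0:
        raise ValueError(f"click peak at {peak_t}s falls outside the recording")
    if lo > start or hi < start + n:
        logger.warning("segment for coda %s click %d zero-padded at the recording edge",
                       click.coda_id, click.click_index)
    seg[lo - start:hi - start] = recording.samples[lo:hi]
    return ClickSegment(coda_id=click.coda_id, click_index=click.click_index,
                        samples=center_and_normalize(seg),
                        start_offset_ms=start_offset_ms, duration_ms=duration_ms,
                        sample_rate_hz=fs)


def assemble_time_insensitive_coda(segments) -> TimeInsensitiveCoda:
    """Concatenate a coda's click segments in click order (no hidden sorting)."""
    if not segments:
        raise ValueError("no segments to assemble")
    first = segments[0]
    for s in segments[1:]:
        if s.coda_id != first.coda_id:
            raise ValueError("segments belong to different codas")
        if s.sample_rate_hz != first.sample_rate_hz:
            raise ValueError("segments have mixed sample rates")
        if s.duration_ms != first.duration_ms:
            raise ValueError("segments have mixed durations")
    samples = np.concatenate([s.samples for s in segments])
    return TimeInsensitiveCoda(coda_id=first.coda_id, samples=samples,
                               segment_duration_ms=first.duration_ms,
                               n_clicks=len(segments),
                               sample_rate_hz=first.sample_rate_hz)


def assemble_session_waveform(codas, buffer_ms: float = 25.0) -> np.ndarray:
    """Concatenate codas into one waveform with exact-zero silence between."""
    if not codas:
        raise ValueError("no codas to assemble")
    fs = codas[0].sample_rate_hz
    if any(c.sample_rate_hz != fs for c in codas):
        raise ValueError("codas have mixed sample rates")
    gap = np.zeros(int(round(buffer_ms * fs / 1000.0)))
    parts = []
    for i, coda in enumerate(codas):
        if i:
            parts.append(gap)
        parts.append(coda.samples)
    return np.concatenate(parts)


def render_spectrogram(samples, sample_rate_hz: float, window_ms: float = 5.0,
                       fmax_hz: float = 15_000.0, db: bool = True,
                       out_png=None):
    """Short-time spectrum magnitude grid limited to [0, fmax_hz].

    Gaussian window of ``window_ms``, hop = window / 10.  Returns
    ``(freqs_hz, times_s, grid)`` with ``grid`` of shape (freqs, times).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty signal")
    nperseg = int(round(window_ms / 1000.0 * sample_rate_hz))
    if nperseg > samples.size:
        raise ValueError("window longer than the signal")
    hop = max(1, nperseg // 10)
    window = signal.windows.gaussian(nperseg, std=nperseg / 6.0)
    freqs, times, sxx = signal.spectrogram(
        samples, fs=sample_rate_hz, window=window, nperseg=nperseg,
        noverlap=nperseg - hop, mode="magnitude")
    keep = freqs <= fmax_hz
    freqs, sxx = freqs[keep], sxx[keep]
    grid = 20 * np.log10(sxx + 1e-12) if db else sxx
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        ax.pcolormesh(times, freqs, grid, shading="auto", cmap="magma")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return freqs, times, grid
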