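"""Per-click Welch spectra, constrained peak detection and a/i labelling.

The spectrum of each click's first pulse is estimated over a 3.5 ms window
(2.0 ms before the click peak, 1.5 ms after — roughly half the inter-pulse
interval).  Peaks are searched between 1 kHz and 10 kHz with a minimum
separation of 1.5 kHz and a minimum height of 25% of the band maximum; up
to the two highest survivors are kept and reported in ascending frequency
as the first and second spectral peaks.  Clicks with two or more peaks are
i-type, otherwise a-type.  This module is fully deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .assembly import resolve_peak_time
from .io import ClickAnnotation, Recording


@dataclass
class ClickSpectrum:
    coda_id: str
    click_index: int
    freqs_hz: np.ndarray
    psd: np.ndarray
    peaks: list[tuple[float, float]]  # (freq_hz, height), ascending frequency
    click_label: str = ""
    low_confidence: bool = False


@dataclass
class CodaPeakClassification:
    coda_id: str
    click_labels: list[str]
    majority_label: str  # "a", "i" or "tie"
    n_mismatched: int
    pct_mismatched: float


def welch_click_spectrum(recording: Recording, click: ClickAnnotation,
                         pre_ms: float = 2.0, post_ms: float = 1.5,
                         nfft: int | None = 4_096,
                         peak_search_ms: float = 15.0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of the (pre_ms + post_ms) window around the click peak.

    A single Hann-windowed segment is used (the window is too short for
    averaging); ``nfft`` zero-pads the FFT for finer frequency sampling.
    """
    fs = recording.sample_rate_hz
    if fs / 2 <= 10_000:
        raise ValueError("sample rate too low for the 10 kHz analysis band")
    peak_t = resolve_peak_time(recording, click, search_ms=peak_search_ms)
    n = int(round((pre_ms + post_ms) / 1000.0 * fs))
    start = int(round((peak_t - pre_ms / 1000.0) * fs))
    if start < 0 or start + n > len(recording.samples):
        raise ValueError(f"{pre_ms + post_ms} ms window around click at {peak_t}s "
                         "falls outside the recording")
    seg = recording.samples[start:start + n]
    nfft = max(n, nfft) if nfft else n
    freqs, psd = signal.welch(seg, fs=fs, window="hann", nperseg=n, nfft=nfft)
    return freqs, psd


def find_constrained_peaks(freqs, psd, band: tuple[float, float] = (1_000.0, 10_000.0),
                           min_sep_hz: float = 1_500.0, rel_height: float = 0.25,
                           max_peaks: int = 2) -> list[tuple[float, float]]:
    """Constrained peak selection in a PSD band.

    Local maxima inside ``band`` whose height is at least ``rel_height`` of
    the band maximum are accepted greedily by descending height subject to a
    ``min_sep_hz`` separation from every already-accepted peak; the
    ``max_peaks`` highest survivors are returned in ascending frequency.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= hi)
    if not np.any(in_band):
        raise ValueError(f"band {band} outside the frequency axis")
    floor = rel_height * psd[in_band].max()
    idx, _ = signal.find_peaks(psd, height=floor)
    idx = idx[in_band[idx]]
    # greedy by height with pairwise Hz separation
    order = idx[np.argsort(psd[idx], kind="stable")[::-1]]
    accepted: list[int] = []
    for i in order:
        if all(abs(freqs[i] - freqs[j]) >= min_sep_hz for j in accepted):
            accepted.append(i)
    chosen = accepted[:max_peaks]
    return sorted(((float(freqs[i]), float(psd[i])) for i in chosen))


def classify_click(peaks) -> str:
    """i-type iff two or more constrained peaks were found, else a-type."""
    return "i" if len(peaks) >= 2 else "a"


def click_spectrum(recording: Recording, click: ClickAnnotation,
                   pre_ms: float = 2.0, post_ms: float = 1.5,
                   band=(1_000.0, 10_000.0), min_sep_hz: float = 1_500.0,
                   rel_height: float = 0.25, max_peaks: int = 2,
                   nfft: int | None = 4_096,
                   peak_search_ms: float = 15.0) -> ClickSpectrum:
    """Full per-click analysis: Welch PSD, constrained peaks, a/i label."""
    freqs, psd = welch_click_spectrum(recording, click, pre_ms=pre_ms, post_ms=post_ms,
                                      nfft=nfft, peak_search_ms=peak_search_ms)
    peaks = find_constrained_peaks(freqs, psd, band=band, min_sep_hz=min_sep_hz,
                                   rel_height=rel_height, max_peaks=max_peaks)
    return ClickSpectrum(coda_id=click.coda_id, click_index=click.click_index,
                         freqs_hz=freqs, psd=psd, peaks=peaks,
                         click_label=classify_click(peaks),
                         low_confidence=len(peaks) == 0)


def classify_coda_majority(click_labels, coda_id: str = "") -> CodaPeakClassification:
    """Majority vote over click labels; a click is mismatched if it disagrees.

    Even splits are labelled ``tie`` with ``n_mismatched = n/2`` (the source
    material leaves such codas unclassified, rendered as '?').
    """
    labels = list(click_labels)
    if not labels:
        raise ValueError("empty label list")
    counts = Counter(labels)
    (top, top_n), = counts.most_common(1)[:1]
    runner_n = max((n for l, n in counts.items() if l != top), default=0)
    if runner_n == top_n:
        majority, mismatched = "tie", len(labels) // 2
    else:
        majority, mismatched = top, len(labels) - top_n
    return CodaPeakClassification(coda_id=coda_id, click_labels=labels,
                                  majority_label=majority, n_mismatched=mismatched,
                                  pct_mismatched=100.0 * mismatched / len(labels))


def mismatch_summary(classifications) -> pd.DataFrame:
    """Histogram of codas by mismatched-click count (bins 0, 1, 2+)."""
    if not classifications:
        raise ValueError("no classifications to summarize")
    bins = Counter(min(c.n_mismatched, 2) for c in classifications)
    n = len(classifications)
    rows = [{"n_mismatched": {0: "0", 1: "1", 2: "2+"}[b],
             "count": bins.get(b, 0),
             "pct": 100.0 * bins.get(b, 0) / n} for b in (0, 1, 2)]
    return pd.DataFrame(rows)


def classify_codas(recording: Recording, codas, **kwargs
                   ) -> tuple[list[ClickSpectrum], list[CodaPeakClassification]]:
    """Run the per-click analysis over many codas."""
    spectra: list[ClickSpectrum] = []
    classifications: list[CodaPeakClassification] = []
    for coda in codas:
        labels = []
        for click in coda.clicks:
            spec = click_spectrum(recording, click, **kwargs)
            spectra.append(spec)
            labels.append(spec.click_label)
        classifications.append(classify_coda_majority(labels, coda_id=coda.coda_id))
    return spectra, classifications


def spectra_frame(spectra) -> pd.DataFrame:
    rows = []
    for s in spectra:
        rows.append({
            "coda_id": s.coda_id, "click_index": s.click_index,
            "peak1_hz": s.peaks[0][0] if len(s.peaks) > 0 else "",
            "peak2_hz": s.peaks[1][0] if len(s.peaks) > 1 else "",
            "label": s.click_label,
        })
    return pd.DataFrame(rows)


def classification_frame(classifications) -> pd.DataFrame:
    return pd.DataFrame([{
        "coda_id": c.coda_id, "majority_label": c.majority_label,
        "n_mismatched": c.n_mismatched, "pct_mismatched": c.pct_mismatched,
    } for c in classifications])
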