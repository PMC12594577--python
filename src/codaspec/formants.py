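"""LPC formant tracking with smoothest-path candidate selection.

For each time-insensitive coda the signal is decimated to twice each of a
ladder of ceiling frequencies, pre-emphasized, and windowed into short
frames.  Autocorrelation LPC gives per-frame formant candidates (frequency,
bandwidth) from the roots of the prediction polynomial.  A dynamic program
then picks one ceiling per frame so that the global cost

    sum over transitions of |delta log f| across tracked formants
    + smoothness_weight * sum over frames of normalized bandwidths

is minimal, yielding the smoothest formant trajectory.  Codas are labelled
i-type when every frame carries both F1 and F2, a-type when no frame has an
F2, and unclassified otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal
from scipy.linalg import solve_toeplitz

from .assembly import assemble_time_insensitive_coda, extract_click_segment
from .io import Coda, Recording, logger

#: Tracked formants must fall in this band to count toward the a/i rule,
#: mirroring the click-spectrum peak band.
FORMANT_BAND_HZ = (1_000.0, 10_000.0)

#: Cost charged per frame for a missing candidate / missing formant match.
_EMPTY_FRAME_COST = 5.0
_MISSING_FORMANT_COST = 0.5


@dataclass
class FormantFrame:
    frame_time_ms: float
    f1_hz: float | None = None
    b1_hz: float | None = None
    f2_hz: float | None = None
    b2_hz: float | None = None

    def __post_init__(self) -> None:
        if self.f1_hz is not None and self.f2_hz is not None and self.f1_hz >= self.f2_hz:
            raise ValueError("f1 must be below f2")


@dataclass
class FormantTrack:
    coda_id: str
    pset_id: str
    frames: list[FormantFrame]
    vowel_label: str = "unclassified"


@dataclass(frozen=True)
class HyperparameterSet:
    """One cell of the extraction/tracking grid."""

    start_offset_ms: float
    segment_duration_ms: float
    ceilings_hz: tuple[float, ...] = (7000.0, 8168.0, 9531.0, 11121.0, 12977.0)
    lpc_order: int = 10
    window_ms: float = 5.0
    step_ms: float = 1.0
    smoothness_weight: float = 1.0

    @property
    def pset_id(self) -> str:
        return f"o{self.start_offset_ms:g}_d{self.segment_duration_ms:g}"


@dataclass
class WhaleVowelReport:
    whale_id: str
    psets_n: int
    pct_agree: float
    n_a: int
    mean_f1_a: float | None
    n_i: int
    mean_f1_i: float | None
    mean_f2_i: float | None


def default_grid(config=None) -> list[HyperparameterSet]:
    """The 2 x 7 extraction grid (start offset x segment duration)."""
    offsets = config.grid_start_offsets_ms if config else (-2.0, -1.5)
    durations = config.grid_durations_ms if config else (3.0, 3.5, 4.0, 4.5, 5.0, 14.5, 15.0)
    kwargs = {}
    if config is not None:
        kwargs = dict(ceilings_hz=tuple(config.lpc_ceilings_hz), lpc_order=config.lpc_order,
                      window_ms=config.lpc_window_ms, step_ms=config.lpc_step_ms,
                      smoothness_weight=config.smoothness_weight)
    return [HyperparameterSet(start_offset_ms=o, segment_duration_ms=d, **kwargs)
            for o in offsets for d in durations]


# ---------------------------------------------------------------------------
# LPC candidate extraction
# ---------------------------------------------------------------------------

def _lpc_coefficients(frame: np.ndarray, order: int) -> np.ndarray | None:
    """Autocorrelation-method LPC; returns prediction coefficients a[1..p]."""
    n = len(frame)
    r = np.correlate(frame, frame, mode="full")[n - 1:n + order]
    if r[0] <= 0:
        return None
    r = r * (1.0 + 1e-9 * np.arange(order + 1))  # tiny ridge for numerical safety
    try:
        return solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        return None


def _roots_to_candidates(a: np.ndarray, fs: float, ceiling_hz: float,
                         bandwidth_cap_hz: float,
                         min_sep_hz: float = 1_500.0) -> list[tuple[float, float]]:
    roots = np.roots(np.concatenate([[1.0], -a]))
    roots = roots[np.imag(roots) > 0]
    out = []
    for z in roots:
        freq = float(np.angle(z) * fs / (2 * np.pi))
        if not 0 < freq < ceiling_hz:
            continue
        mag = abs(z)
        if mag >= 1:
            continue
        bw = float(-np.log(mag) * fs / np.pi)
        if bw <= bandwidth_cap_hz:
            out.append((freq, bw))
    # one resonance can split into close pole pairs: keep the sharpest of any
    # cluster closer than min_sep_hz (mirrors the spectral-peak separation)
    accepted: list[tuple[float, float]] = []
    for freq, bw in sorted(out, key=lambda fb: fb[1]):
        if all(abs(freq - f0) >= min_sep_hz for f0, _ in accepted):
            accepted.append((freq, bw))
    return sorted(accepted)


def _resample_to(samples: np.ndarray, fs: float, target_fs: float) -> tuple[np.ndarray, float]:
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    out = signal.resample_poly(samples, frac.numerator, frac.denominator)
    return out, fs * frac.numerator / frac.denominator


def lpc_candidate_frames(samples, sample_rate_hz: float, ceiling_hz: float,
                         order: int = 10, window_ms: float = 5.0, step_ms: float = 1.0,
                         preemphasis_hz: float = 50.0,
                         bandwidth_cap_hz: float = 1_000.0,
                         ) -> list[list[tuple[float, float]]]:
    """Per-frame formant candidates below one ceiling.

    The signal is resampled to 2x the ceiling, pre-emphasized, Gaussian
    windowed and analysed by autocorrelation LPC; complex roots of the
    prediction polynomial give (frequency, bandwidth) pairs and only those
    under the ceiling with bandwidth below the cap survive.  Frames are laid
    out on a fixed *time* grid so frame counts agree across ceilings.
    """
    samples = np.asarray(samples, dtype=float)
    if ceiling_hz > sample_rate_hz / 2:
        raise ValueError("ceiling above Nyquist")
    x, fs2 = _resample_to(samples, sample_rate_hz, 2 * ceiling_hz)
    alpha = math.exp(-2 * math.pi * preemphasis_hz / fs2)
    x = np.append(x[0], x[1:] - alpha * x[:-1])

    duration_ms = len(samples) / sample_rate_hz * 1000.0
    nwin = int(round(window_ms / 1000.0 * fs2))
    if nwin < 2 * order:
        raise ValueError("window too short for the requested LPC order")
    win = signal.windows.gaussian(nwin, std=nwin / 6.0)
    frames: list[list[tuple[float, float]]] = []
    for start_ms in frame_times(duration_ms, window_ms, step_ms):
        i0 = int(round(start_ms / 1000.0 * fs2))
        frame = x[i0:i0 + nwin]
        if len(frame) < nwin:
            frame = np.pad(frame, (0, nwin - len(frame)))
        frame = frame * win
        a = _lpc_coefficients(frame, order)
        if a is None:
            logger.warning("unstable LPC frame at %.1f ms (ceiling %g Hz)", start_ms, ceiling_hz)
            frames.append([])
            continue
        frames.append(_roots_to_candidates(a, fs2, ceiling_hz, bandwidth_cap_hz))
    return frames


def frame_times(duration_ms: float, window_ms: float, step_ms: float) -> list[float]:
    """Frame start times (ms); at least one frame even for short signals."""
    times, t = [], 0.0
    while t + window_ms <= duration_ms + 1e-9:
        times.append(round(t, 6))
        t += step_ms
    return times or [0.0]


# ---------------------------------------------------------------------------
# Smoothest-path selection
# ---------------------------------------------------------------------------

def _frame_formants(cands: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Lowest (up to) two candidates in ascending frequency: F1 (and F2)."""
    return cands[:2]


def _local_cost(cands, smoothness_weight: float) -> float:
    fmts = _frame_formants(cands)
    if not fmts:
        return _EMPTY_FRAME_COST
    return smoothness_weight * sum(bw / f for f, bw in fmts) / len(fmts)


def _transition_cost(prev, cur) -> float:
    a, b = _frame_formants(prev), _frame_formants(cur)
    if not a or not b:
        return 0.0
    cost = sum(abs(math.log(fb / fa)) for (fa, _), (fb, _) in zip(a, b))
    cost += _MISSING_FORMANT_COST * abs(len(a) - len(b))
    return cost


def path_cost(candidates_per_ceiling, assignment, smoothness_weight: float) -> float:
    """Total cost of one ceiling assignment (used by the DP and by tests)."""
    frames = [candidates_per_ceiling[c][t] for t, c in enumerate(assignment)]
    cost = sum(_local_cost(f, smoothness_weight) for f in frames)
    cost += sum(_transition_cost(frames[t - 1], frames[t]) for t in range(1, len(frames)))
    return cost


def formant_path(samples, sample_rate_hz: float, ceilings=None,
                 smoothness_weight: float = 1.0, order: int = 10,
                 window_ms: float = 5.0, step_ms: float = 1.0,
                 preemphasis_hz: float = 50.0, bandwidth_cap_hz: float = 1_000.0,
                 coda_id: str = "", pset_id: str = "") -> FormantTrack:
    """Pick the smoothest per-frame ceiling assignment by dynamic programming."""
    ceilings = tuple(ceilings or (7000.0, 8168.0, 9531.0, 11121.0, 12977.0))
    per_ceiling = [
        lpc_candidate_frames(samples, sample_rate_hz, c, order=order,
                             window_ms=window_ms, step_ms=step_ms,
                             preemphasis_hz=preemphasis_hz,
                             bandwidth_cap_hz=bandwidth_cap_hz)
        for c in ceilings
    ]
    n_frames = len(per_ceiling[0])
    n_c = len(ceilings)
    if all(not per_ceiling[c][t] for c in range(n_c) for t in range(n_frames)):
        raise ValueError("no formant candidates in any frame")

    local = np.array([[_local_cost(per_ceiling[c][t], smoothness_weight)
                       for c in range(n_c)] for t in range(n_frames)])
    best = local[0].copy()
    back = np.zeros((n_frames, n_c), dtype=int)
    for t in range(1, n_frames):
        trans = np.array([[_transition_cost(per_ceiling[i][t - 1], per_ceiling[j][t])
                           for i in range(n_c)] for j in range(n_c)])
        tot = best[None, :] + trans  # [j, i]
        back[t] = np.argmin(tot, axis=1)
        best = tot[np.arange(n_c), back[t]] + local[t]
    path = [int(np.argmin(best))]
    for t in range(n_frames - 1, 0, -1):
        path.append(int(back[t][path[-1]]))
    path.reverse()

    duration_ms = len(np.asarray(samples)) / sample_rate_hz * 1000.0
    times = frame_times(duration_ms, window_ms, step_ms)
    frames = []
    for t, c in enumerate(path):
        fmts = _frame_formants(per_ceiling[c][t])
        frame = FormantFrame(frame_time_ms=times[t])
        if len(fmts) >= 1:
            frame.f1_hz, frame.b1_hz = fmts[0]
        if len(fmts) >= 2:
            frame.f2_hz, frame.b2_hz = fmts[1]
        frames.append(frame)
    track = FormantTrack(coda_id=coda_id, pset_id=pset_id, frames=frames)
    track.vowel_label = classify_coda_from_formants(track)
    return track


def classify_coda_from_formants(track: FormantTrack) -> str:
    """i iff every frame has in-band F1 and F2; a iff no frame has an F2."""
    lo, hi = FORMANT_BAND_HZ

    def in_band(f):
        return f is not None and lo < f < hi

    has_f2 = [in_band(fr.f2_hz) and in_band(fr.f1_hz) for fr in track.frames]
    any_f2 = [in_band(fr.f2_hz) for fr in track.frames]
    if not track.frames:
        raise ValueError("empty track")
    if all(has_f2):
        return "i"
    if not any(any_f2):
        return "a"
    return "unclassified"


# ---------------------------------------------------------------------------
# Hyperparameter grid and per-whale reporting
# ---------------------------------------------------------------------------

def track_coda(recording: Recording, coda: Coda, pset: HyperparameterSet,
               peak_search_ms: float = 15.0, preemphasis_hz: float = 50.0,
               bandwidth_cap_hz: float = 1_000.0) -> FormantTrack:
    """Assemble one time-insensitive coda under ``pset`` and track it."""
    segments = [extract_click_segment(recording, c, start_offset_ms=pset.start_offset_ms,
                                      duration_ms=pset.segment_duration_ms,
                                      peak_search_ms=peak_search_ms)
                for c in coda.clicks]
    tic = assemble_time_insensitive_coda(segments)
    return formant_path(tic.samples, tic.sample_rate_hz, ceilings=pset.ceilings_hz,
                        smoothness_weight=pset.smoothness_weight, order=pset.lpc_order,
                        window_ms=pset.window_ms, step_ms=pset.step_ms,
                        preemphasis_hz=preemphasis_hz, bandwidth_cap_hz=bandwidth_cap_hz,
                        coda_id=coda.coda_id, pset_id=pset.pset_id)


def track_means(track: FormantTrack) -> tuple[float | None, float | None]:
    """Coda-level mean F1/F2 over frames where each is present."""
    f1 = [fr.f1_hz for fr in track.frames if fr.f1_hz is not None]
    f2 = [fr.f2_hz for fr in track.frames if fr.f2_hz is not None]
    return (float(np.mean(f1)) if f1 else None, float(np.mean(f2)) if f2 else None)


def run_hyperparameter_grid(codas, recording: Recording, grid=None,
                            **track_kwargs) -> pd.DataFrame:
    """Track and classify every hand-labelled coda under every pset.

    Returns a long-format table with one row per (pset, coda): predicted
    label, hand label, agreement flag and coda-mean F1/F2.  Whales without
    any hand-labelled coda are excluded with a warning.
    """
    grid = grid or default_grid()
    scored = [c for c in codas if c.hand_vowel in ("a", "i")]
    skipped_whales = {c.whale_id for c in codas} - {c.whale_id for c in scored}
    for w in sorted(skipped_whales):
        logger.warning("whale %s has no hand-labeled codas; excluded from the grid", w)
    rows = []
    for pset in grid:
        for coda in scored:
            track = track_coda(recording, coda, pset, **track_kwargs)
            f1, f2 = track_means(track)
            rows.append({
                "whale_id": coda.whale_id, "pset_id": pset.pset_id,
                "coda_id": coda.coda_id, "hand_vowel": coda.hand_vowel,
                "predicted": track.vowel_label,
                "agree": track.vowel_label == coda.hand_vowel,
                "mean_f1_hz": f1, "mean_f2_hz": f2,
            })
    return pd.DataFrame(rows)


def grid_agreement(grid_results: pd.DataFrame) -> pd.DataFrame:
    """Percent agreement with hand labels per (whale, pset)."""
    g = grid_results.groupby(["whale_id", "pset_id"])["agree"].mean().reset_index()
    g["pct_agree"] = 100.0 * g.pop("agree")
    return g


def best_pset_report(grid_results: pd.DataFrame) -> list[WhaleVowelReport]:
    """Per-whale report over the best-performing (possibly tied) psets.

    All psets tied at the maximum agreement contribute to the formant means:
    frame means are averaged per coda (inside the grid run), then over codas,
    then over tied psets.
    """
    reports = []
    agreement = grid_agreement(grid_results)
    for whale, g in agreement.groupby("whale_id"):
        best = g["pct_agree"].max()
        tied = g.loc[g["pct_agree"] == best, "pset_id"].tolist()
        sub = grid_results[(grid_results["whale_id"] == whale)
                           & grid_results["pset_id"].isin(tied)]
        a = sub[sub["hand_vowel"] == "a"]
        i = sub[sub["hand_vowel"] == "i"]
        reports.append(WhaleVowelReport(
            whale_id=whale, psets_n=len(tied), pct_agree=float(best),
            n_a=a["coda_id"].nunique(), n_i=i["coda_id"].nunique(),
            mean_f1_a=float(a["mean_f1_hz"].dropna().mean()) if len(a) else None,
            mean_f1_i=float(i["mean_f1_hz"].dropna().mean()) if len(i) else None,
            mean_f2_i=float(i["mean_f2_hz"].dropna().mean()) if len(i) else None,
        ))
    return reports


def report_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([{
        "whale_id": r.whale_id, "psetsN": r.psets_n, "pct_agree": r.pct_agree,
        "n_a": r.n_a, "mean_f1_a": r.mean_f1_a,
        "n_i": r.n_i, "mean_f1_i": r.mean_f1_i, "mean_f2_i": r.mean_f2_i,
    } for r in reports])


def frames_table(tracks) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for fr in tr.frames:
            rows.append({"coda_id": tr.coda_id, "pset_id": tr.pset_id,
                         "frame_ms": fr.frame_time_ms,
                         "f1": fr.f1_hz, "b1": fr.b1_hz, "f2": fr.f2_hz, "b2": fr.b2_hz})
    return pd.DataFrame(rows)
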