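"""Domain types and file I/O shared by every pipeline stage.

Audio is read from standard WAV files (PCM16/24/32 or float32) via
:mod:`scipy.io.wavfile`; annotation and movement tables are CSV with a
header row.  All times are seconds from the start of the recording and
intervals are half-open ``[start, start + dur)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger("codaspec")

#: Analysis band must stay below Nyquist with headroom.
MIN_SAMPLE_RATE_HZ = 20_000.0

#: Grammar for traditional coda-type labels: "5R1", "9i", "6D", "1+1+3", ...
CODA_TYPE_RE = re.compile(r"^(\d+[RDi]?\d?|\d+(\+\d+)+)$")

VOWEL_LABELS = ("a", "i", "unknown", "absent")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ClickAnnotation:
    """One annotated click inside a coda.

    ``click_time_s`` is the annotated onset; ``peak_time_s`` is the time of
    the maximum-magnitude sample and may be absent (derived from audio later
    because annotated times are not guaranteed to coincide with the peak).
    """

    coda_id: str
    whale_id: str
    click_index: int
    click_time_s: float
    peak_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.click_index < 0:
            raise ValueError(f"click_index must be >= 0, got {self.click_index}")
        if self.peak_time_s is not None and self.peak_time_s < self.click_time_s:
            raise ValueError(
                f"peak_time_s ({self.peak_time_s}) precedes click_time_s "
                f"({self.click_time_s}) for coda {self.coda_id}"
            )


@dataclass
class Coda:
    """An ordered group of clicks with whale identity and optional labels."""

    coda_id: str
    whale_id: str
    clicks: list[ClickAnnotation]
    coda_type: str | None = None
    hand_vowel: str = "absent"
    focal: bool = True

    def __post_init__(self) -> None:
        if not self.clicks:
            raise ValueError(f"coda {self.coda_id} has no clicks")
        idx = [c.click_index for c in self.clicks]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"click_index not strictly increasing in coda {self.coda_id}")
        times = [c.click_time_s for c in self.clicks]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"click times not strictly increasing in coda {self.coda_id}")
        if self.hand_vowel not in VOWEL_LABELS:
            raise ValueError(f"hand_vowel must be one of {VOWEL_LABELS}, got {self.hand_vowel!r}")
        if self.coda_type is not None and not CODA_TYPE_RE.match(self.coda_type):
            raise ValueError(f"coda_type {self.coda_type!r} does not match the type grammar")

    @property
    def n_clicks(self) -> int:
        return len(self.clicks)

    @property
    def icis_s(self) -> list[float]:
        """Inter-click intervals in seconds (length ``n_clicks - 1``)."""
        t = [c.click_time_s for c in self.clicks]
        return [b - a for a, b in zip(t, t[1:])]

    @property
    def onset_s(self) -> float:
        return self.clicks[0].click_time_s


@dataclass
class MovementSeries:
    """Tag movement channels sampled on a (possibly irregular) time grid."""

    time_s: np.ndarray
    depth_m: np.ndarray
    head_deg: np.ndarray
    pitch_deg: np.ndarray
    roll_deg: np.ndarray

    CHANNELS = ("depth", "head", "pitch", "roll")

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.time_s.size == 0:
            raise ValueError("movement series is empty")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("movement time_s must be strictly increasing")
        for name in ("depth_m", "head_deg", "pitch_deg", "roll_deg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.time_s.shape:
                raise ValueError(f"{name} length does not match time_s")
            setattr(self, name, arr)
        if np.any(self.depth_m < 0):
            raise ValueError("depth_m must be >= 0")

    def channel(self, name: str) -> np.ndarray:
        return {
            "depth": self.depth_m,
            "head": self.head_deg,
            "pitch": self.pitch_deg,
            "roll": self.roll_deg,
        }[name]

    def at(self, times_s, channel: str = "depth") -> np.ndarray:
        """Linear interpolation, clamped to the first/last sample outside range."""
        return np.interp(np.asarray(times_s, dtype=float), self.time_s, self.channel(channel))


@dataclass
class Recording:
    """Mono audio with its sample rate; amplitudes are floats."""

    samples: np.ndarray
    sample_rate_hz: float
    channel_used: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_hz <= MIN_SAMPLE_RATE_HZ:
            raise ValueError(
                f"sample rate {self.sample_rate_hz} Hz too low: the 10 kHz analysis "
                f"band requires > {MIN_SAMPLE_RATE_HZ:g} Hz"
            )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def time_to_index(self, t_s: float) -> int:
        return int(round(t_s * self.sample_rate_hz))


@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline, defaulting to the published parameters."""

    # click-spectrum peak detection
    band_low_hz: float = 1_000.0
    band_high_hz: float = 10_000.0
    peak_min_sep_hz: float = 1_500.0
    peak_rel_height: float = 0.25
    max_peaks: int = 2

    # Welch segment around the click peak (first pulse only)
    welch_pre_ms: float = 2.0
    welch_post_ms: float = 1.5
    welch_nfft: int = 4_096

    # time-insensitive coda assembly
    start_offset_ms: float = -2.0
    segment_duration_ms: float = 15.0
    buffer_ms: float = 25.0
    peak_search_ms: float = 15.0

    # spectrogram rendering
    spectrogram_window_ms: float = 5.0
    spectrogram_fmax_hz: float = 15_000.0

    # LPC formant tracking
    lpc_ceilings_hz: tuple[float, ...] = (7000.0, 8168.0, 9531.0, 11121.0, 12977.0)
    lpc_order: int = 10
    lpc_window_ms: float = 5.0
    lpc_step_ms: float = 1.0
    preemphasis_hz: float = 50.0
    bandwidth_cap_hz: float = 1_000.0
    smoothness_weight: float = 1.0

    # hyperparameter grid (offsets x durations = 14 extraction cells)
    grid_start_offsets_ms: tuple[float, ...] = (-2.0, -1.5)
    grid_durations_ms: tuple[float, ...] = (3.0, 3.5, 4.0, 4.5, 5.0, 14.5, 15.0)

    # trajectory statistics
    gmm_k_min: int = 1
    gmm_k_max: int = 5
    gmm_restarts: int = 5
    diphthong_threshold_hz: float = 300.0

    # context analysis
    exclusion_min_codas: int = 50
    dialogue_overlap_s: float = 1.0
    bout_gap_s: float = 10.0

    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(f.default, tuple):
                raw[f.name] = tuple(raw[f.name])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31, np.dtype(np.uint8): 2**7}


def read_recording(path, channel: int = 0) -> Recording:
    """Read one channel of a WAV file as floating-point amplitudes.

    Integer PCM is scaled to [-1, 1).  Sample rates at or below 20 kHz are
    rejected because the analysis band extends to 10 kHz.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.ndim == 1:
        if channel != 0:
            raise IndexError(f"mono file has no channel {channel}")
        mono = data
    else:
        if not 0 <= channel < data.shape[1]:
            raise IndexError(f"channel {channel} out of range for {data.shape[1]}-channel file")
        mono = data[:, channel]
    if mono.dtype in _PCM_SCALE:
        samples = mono.astype(float)
        if mono.dtype == np.dtype(np.uint8):  # uint8 WAV is offset-binary
            samples = samples - 128.0
        samples /= _PCM_SCALE[mono.dtype]
    else:
        samples = mono.astype(float)
    return Recording(samples=samples, sample_rate_hz=float(rate), channel_used=channel)


def write_recording(path, recording: Recording) -> None:
    """Write a recording as float32 WAV (lossless within float32 rounding)."""
    wavfile.write(str(path), int(recording.sample_rate_hz), recording.samples.astype(np.float32))


ANNOTATION_COLUMNS = ["coda_id", "whale_id", "click_index", "click_time_s", "peak_time_s",
                      "coda_type", "hand_vowel", "focal"]


def read_annotations(path) -> list[Coda]:
    """Read a click-annotation CSV and group rows into :class:`Coda` objects.

    Required columns: ``coda_id``, ``whale_id``, ``click_time_s``.  Optional:
    ``click_index`` (derived from time order when absent), ``peak_time_s``,
    ``coda_type``, ``hand_vowel``, ``focal``.
    """
    df = pd.read_csv(path, dtype={"coda_id": str, "whale_id": str})
    required = {"coda_id", "whale_id", "click_time_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    codas: list[Coda] = []
    for coda_id, g in df.groupby("coda_id", sort=False):
        g = g.sort_values("click_time_s", kind="stable")
        if "click_index" in g.columns and g["click_index"].notna().all():
            if g["click_index"].duplicated().any():
                raise ValueError(f"duplicate (coda_id, click_index) in coda {coda_id}")
            g = g.sort_values("click_index", kind="stable")
        times = g["click_time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"non-monotone click times in coda {coda_id}")
        clicks = []
        for i, (_, row) in enumerate(g.iterrows()):
            peak = row.get("peak_time_s")
            peak = None if peak is None or pd.isna(peak) else float(peak)
            idx = int(row["click_index"]) if "click_index" in g.columns and not pd.isna(row.get("click_index")) else i
            clicks.append(ClickAnnotation(
                coda_id=str(coda_id), whale_id=str(row["whale_id"]),
                click_index=idx, click_time_s=float(row["click_time_s"]),
                peak_time_s=peak,
            ))
        first = g.iloc[0]
        coda_type = first.get("coda_type")
        coda_type = None if coda_type is None or pd.isna(coda_type) else str(coda_type)
        hand_vowel = first.get("hand_vowel")
        hand_vowel = "absent" if hand_vowel is None or pd.isna(hand_vowel) else str(hand_vowel)
        focal = first.get("focal")
        focal = True if focal is None or pd.isna(focal) else bool(focal)
        codas.append(Coda(coda_id=str(coda_id), whale_id=str(first["whale_id"]),
                          clicks=clicks, coda_type=coda_type,
                          hand_vowel=hand_vowel, focal=focal))
    return codas


def write_annotations(path, codas: Sequence[Coda]) -> None:
    rows = []
    for coda in codas:
        for c in coda.clicks:
            rows.append({
                "coda_id": coda.coda_id, "whale_id": coda.whale_id,
                "click_index": c.click_index, "click_time_s": c.click_time_s,
                "peak_time_s": "" if c.peak_time_s is None else c.peak_time_s,
                "coda_type": coda.coda_type or "", "hand_vowel": coda.hand_vowel,
                "focal": coda.focal,
            })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


MOVEMENT_COLUMNS = ["time_s", "depth_m", "head_deg", "pitch_deg", "roll_deg"]


def read_movement(path) -> MovementSeries:
    df = pd.read_csv(path)
    missing = set(MOVEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"movement file missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("movement file is empty")
    return MovementSeries(
        time_s=df["time_s"].to_numpy(), depth_m=df["depth_m"].to_numpy(),
        head_deg=df["head_deg"].to_numpy(), pitch_deg=df["pitch_deg"].to_numpy(),
        roll_deg=df["roll_deg"].to_numpy(),
    )


def write_movement(path, movement: MovementSeries) -> None:
    pd.DataFrame({
        "time_s": movement.time_s, "depth_m": movement.depth_m,
        "head_deg": movement.head_deg, "pitch_deg": movement.pitch_deg,
        "roll_deg": movement.roll_deg,
    }).to_csv(path, index=False)
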