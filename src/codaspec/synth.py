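"""Source-filter simulator for coda click trains.

Each click is a short train of pulses (default two, ~3.1 ms apart, the first
strongest).  Every pulse is a unit impulse driven through a cascade of
two-pole resonators, so the output spectrum carries maxima at the requested
formant centers.  Codas place clicks at cumulative inter-click intervals and
per-click formant centers follow a level / rising / falling / rise-fall /
fall-rise trajectory law that is linear in click index.

The dataset generator emits WAV audio plus annotation, movement and truth
CSVs, and optionally couples the depth trace to the per-click formant
centers with a configurable Pearson coefficient so movement-correlation
analyses can be validated in both the null and the coupled regime.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .io import (
    ClickAnnotation,
    Coda,
    MovementSeries,
    Recording,
    logger,
    write_annotations,
    write_movement,
    write_recording,
)

TRAJECTORIES = ("level", "rising", "falling", "rise_fall", "fall_rise")

#: Published mean formant centers used as generator defaults.
A_CENTER_HZ = 5_780.0
I_CENTERS_HZ = (3_757.0, 6_579.0)

#: Mean first-to-second pulse spacing within a click.
DEFAULT_IPI_S = 0.0031

#: Traditional-type ICI templates (seconds).
CODA_TEMPLATES = {
    "1+1+3": [0.30, 0.30, 0.15, 0.15],
    "5R1": [0.18, 0.18, 0.18, 0.18],
    "5R2": [0.28, 0.28, 0.28, 0.28],
}


@dataclass
class VowelSpec:
    """Ground-truth spectral specification for one coda."""

    label: str  # "a" or "i"
    formant_centers_hz: tuple[float, ...]
    bandwidths_hz: tuple[float, ...]
    trajectory: str = "level"
    trajectory_span_hz: float = 0.0
    first_click_offset_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.label == "a" and len(self.formant_centers_hz) != 1:
            raise ValueError("a-vowel must have exactly one formant center")
        if self.label == "i":
            if len(self.formant_centers_hz) != 2:
                raise ValueError("i-vowel must have exactly two formant centers")
            if abs(self.formant_centers_hz[1] - self.formant_centers_hz[0]) < 1_500:
                raise ValueError("i-vowel centers must be >= 1500 Hz apart")
        if not all(1_000 < c < 10_000 for c in self.formant_centers_hz):
            raise ValueError("formant centers must lie in (1000, 10000) Hz")
        if self.trajectory not in TRAJECTORIES:
            raise ValueError(f"unknown trajectory {self.trajectory!r}")

    @classmethod
    def default(cls, label: str, trajectory: str = "level",
                span_hz: float = 0.0, bandwidth_hz: float = 400.0,
                first_click_offset_hz: float = 0.0) -> "VowelSpec":
        centers = (A_CENTER_HZ,) if label == "a" else I_CENTERS_HZ
        return cls(label=label, formant_centers_hz=centers,
                   bandwidths_hz=(bandwidth_hz,) * len(centers),
                   trajectory=trajectory, trajectory_span_hz=span_hz,
                   first_click_offset_hz=first_click_offset_hz)


@dataclass
class CodaTemplate:
    """Timing skeleton of a coda: ICIs plus intra-click pulse structure."""

    coda_type: str
    icis_s: tuple[float, ...]
    ipi_s: float = DEFAULT_IPI_S
    pulses_per_click: int = 2
    pulse_decay: float = 0.5

    def __post_init__(self) -> None:
        if self.icis_s and self.ipi_s >= min(self.icis_s):
            raise ValueError("intra-click IPI must be shorter than every ICI")
        if self.pulses_per_click < 1:
            raise ValueError("need at least one pulse per click")

    @property
    def n_clicks(self) -> int:
        return len(self.icis_s) + 1

    @classmethod
    def from_type(cls, coda_type: str, **kwargs) -> "CodaTemplate":
        return cls(coda_type=coda_type, icis_s=tuple(CODA_TEMPLATES[coda_type]), **kwargs)


@dataclass
class SyntheticTruth:
    """Per-coda ground truth emitted alongside the audio."""

    coda_id: str
    whale_id: str
    vowel_label: str
    trajectory: str
    click_times_s: list[float]
    peak_times_s: list[float]
    formant_centers_hz: list[list[float]]  # [click][formant]


@dataclass
class DatasetConfig:
    """Configuration of :func:`synthesize_dataset`."""

    whales: dict[str, int] = field(default_factory=lambda: {"ALPHA": 10, "BRAVO": 10})
    vowel_proportions: dict[str, float] = field(default_factory=lambda: {"a": 0.6, "i": 0.4})
    trajectory_proportions: dict[str, float] = field(
        default_factory=lambda: {"level": 1.0})
    coda_types: tuple[str, ...] = ("1+1+3", "5R1", "5R2")
    sample_rate_hz: float = 96_000.0
    snr_db: float = 30.0
    bandwidth_hz: float = 400.0
    trajectory_span_hz: float = 1_400.0
    gap_s: float = 0.5
    depth_coupling: float = 0.0       # target Pearson r between depth and F1 center
    depth_mean_m: float = 150.0
    depth_sd_m: float = 60.0


# ---------------------------------------------------------------------------
# Click and coda synthesis
# ---------------------------------------------------------------------------

def resonator_coefficients(center_hz: float, bandwidth_hz: float,
                           sample_rate_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Two-pole resonator (b, a) for one formant."""
    if bandwidth_hz <= 0:
        raise ValueError("bandwidth must be positive")
    r = np.exp(-np.pi * bandwidth_hz / sample_rate_hz)
    theta = 2 * np.pi * center_hz / sample_rate_hz
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    b = np.array([1.0 - r])  # keeps gain roughly bounded; output is normalized later
    return b, a


def synthesize_click(formants, duration_s: float, sample_rate_hz: float) -> np.ndarray:
    """Unit impulse through a cascade of two-pole resonators.

    ``formants`` is a sequence of ``(center_hz, bandwidth_hz, gain)`` tuples.
    """
    nyquist = sample_rate_hz / 2
    n = int(round(duration_s * sample_rate_hz))
    for center, bandwidth, _gain in formants:
        if center >= nyquist:
            raise ValueError(f"formant center {center} Hz at or above Nyquist {nyquist} Hz")
        if duration_s < 2.0 / bandwidth:
            raise ValueError("duration too short to resolve the requested bandwidth")
    x = np.zeros(n)
    x[0] = 1.0
    for center, bandwidth, gain in formants:
        b, a = resonator_coefficients(center, bandwidth, sample_rate_hz)
        x = signal.lfilter(gain * b, a, x)
    return x


def trajectory_centers(vowel: VowelSpec, n_clicks: int) -> np.ndarray:
    """Per-click true formant centers, shape (n_clicks, n_formants).

    Level: constant.  Rising/falling: linear in click index with total
    excursion ``trajectory_span_hz`` (so a 1400 Hz span over 5 clicks steps
    350 Hz per click).  Rise-fall / fall-rise: piecewise linear with the turn
    at the middle click.  ``first_click_offset_hz`` is added to click 0 only.
    """
    base = np.asarray(vowel.formant_centers_hz, dtype=float)
    k = np.arange(n_clicks, dtype=float)
    span = vowel.trajectory_span_hz
    if n_clicks == 1 or vowel.trajectory == "level" or span == 0:
        offsets = np.zeros(n_clicks)
    elif vowel.trajectory in ("rising", "falling"):
        offsets = -span / 2 + span * k / (n_clicks - 1)
        if vowel.trajectory == "falling":
            offsets = -offsets
    else:  # rise_fall / fall_rise: turn at the middle click
        mid = (n_clicks - 1) / 2.0
        offsets = np.interp(k, [0.0, mid, n_clicks - 1.0],
                            [-span / 2, span / 2, -span / 2])
        if vowel.trajectory == "fall_rise":
            offsets = -offsets
    centers = base[None, :] + offsets[:, None]
    centers[0] += vowel.first_click_offset_hz
    return centers


def synthesize_coda(template: CodaTemplate, vowel: VowelSpec,
                    sample_rate_hz: float, noise_db: float = 30.0,
                    seed: int | np.random.Generator = 0,
                    coda_id: str = "c0", whale_id: str = "W",
                    click_duration_s: float = 0.012,
                    ) -> tuple[np.ndarray, list[ClickAnnotation], SyntheticTruth]:
    """Render one coda and return (samples, annotations, truth).

    Clicks sit at cumulative ICI times; each click is ``pulses_per_click``
    resonator impulse responses spaced ``ipi_s`` apart with geometric decay.
    White Gaussian noise is added at ``noise_db`` dB SNR relative to signal
    power.  Annotated click times are pulse onsets and peak times are the
    measured argmax of |amplitude| over the first pulse.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = sample_rate_hz
    n_clicks = template.n_clicks
    click_times = np.concatenate([[0.0], np.cumsum(template.icis_s)])
    total_s = click_times[-1] + (template.pulses_per_click - 1) * template.ipi_s \
        + click_duration_s + 0.005
    out = np.zeros(int(round(total_s * fs)))
    centers = trajectory_centers(vowel, n_clicks)

    peak_times = []
    for k in range(n_clicks):
        formants = [(c, bw, 1.0) for c, bw in zip(centers[k], vowel.bandwidths_hz)]
        click = synthesize_click(formants, click_duration_s, fs)
        start = int(round(click_times[k] * fs))
        for p in range(template.pulses_per_click):
            off = start + int(round(p * template.ipi_s * fs))
            seg = click * (template.pulse_decay ** p)
            out[off:off + len(seg)] += seg[:max(0, len(out) - off)]
        # measured peak of the first pulse (before the second pulse lands)
        first_len = int(round(template.ipi_s * fs))
        window = out[start:start + first_len]
        peak_times.append((start + int(np.argmax(np.abs(window)))) / fs)

    sig_power = np.mean(out**2)
    if sig_power > 0 and np.isfinite(noise_db):
        noise_power = sig_power / (10 ** (noise_db / 10))
        out = out + rng.normal(0.0, np.sqrt(noise_power), size=len(out))
        if noise_db < 0:
            logger.warning("coda %s rendered at %.1f dB SNR; truth peaks may be "
                           "unrecoverable", coda_id, noise_db)

    annotations = [
        ClickAnnotation(coda_id=coda_id, whale_id=whale_id, click_index=k,
                        click_time_s=float(click_times[k]), peak_time_s=float(peak_times[k]))
        for k in range(n_clicks)
    ]
    truth = SyntheticTruth(coda_id=coda_id, whale_id=whale_id, vowel_label=vowel.label,
                           trajectory=vowel.trajectory,
                           click_times_s=[float(t) for t in click_times],
                           peak_times_s=[float(t) for t in peak_times],
                           formant_centers_hz=centers.tolist())
    return out, annotations, truth


# ---------------------------------------------------------------------------
# Dataset-level planning and rendering
# ---------------------------------------------------------------------------

def _draw_categorical(rng: np.random.Generator, proportions: dict[str, float]) -> str:
    labels = sorted(proportions)
    p = np.array([proportions[l] for l in labels], dtype=float)
    return labels[rng.choice(len(labels), p=p / p.sum())]


@dataclass
class DatasetPlan:
    """Audio-free description of a dataset: codas, truth and movement."""

    codas: list[tuple[CodaTemplate, VowelSpec, str, str, float]]  # (+coda_id, whale, onset)
    truths: list[SyntheticTruth]
    movement: MovementSeries


def plan_dataset(config: DatasetConfig, seed: int) -> DatasetPlan:
    """Lay out codas, ground-truth formant centers and the movement trace.

    Pure function of (config, seed).  The depth value at each click is
    ``mean + sd * (rho * z + sqrt(1 - rho^2) * eps)`` where ``z`` is the
    z-scored first-formant center of the click and ``rho`` is
    ``config.depth_coupling``, so the population Pearson correlation between
    depth and formant center equals the coupling coefficient.
    """
    if not config.whales or all(n == 0 for n in config.whales.values()):
        raise ValueError("zero codas requested")
    rng = np.random.default_rng(seed)
    plan_rows = []
    truths = []
    t = 0.05  # lead-in so analysis windows never precede the recording start
    serial = 0
    for whale in sorted(config.whales):
        for _ in range(config.whales[whale]):
            label = _draw_categorical(rng, config.vowel_proportions)
            trajectory = _draw_categorical(rng, config.trajectory_proportions)
            span = config.trajectory_span_hz if trajectory != "level" else 0.0
            vowel = VowelSpec.default(label, trajectory=trajectory, span_hz=span,
                                      bandwidth_hz=config.bandwidth_hz)
            coda_type = config.coda_types[rng.choice(len(config.coda_types))]
            template = CodaTemplate.from_type(coda_type)
            coda_id = f"c{serial:05d}"
            serial += 1
            plan_rows.append((template, vowel, coda_id, whale, t))
            centers = trajectory_centers(vowel, template.n_clicks)
            click_times = t + np.concatenate([[0.0], np.cumsum(template.icis_s)])
            truths.append(SyntheticTruth(
                coda_id=coda_id, whale_id=whale, vowel_label=label,
                trajectory=trajectory, click_times_s=click_times.tolist(),
                peak_times_s=click_times.tolist(),  # refined when audio is rendered
                formant_centers_hz=centers.tolist()))
            t = click_times[-1] + config.gap_s

    # depth trace coupled to per-click F1 centers at the requested Pearson r
    all_times = np.concatenate([tr.click_times_s for tr in truths])
    all_f1 = np.concatenate([[c[0] for c in tr.formant_centers_hz] for tr in truths])
    sd = all_f1.std()
    z = (all_f1 - all_f1.mean()) / sd if sd > 0 else np.zeros_like(all_f1)
    rho = float(config.depth_coupling)
    eps = rng.standard_normal(len(z))
    depth = config.depth_mean_m + config.depth_sd_m * (rho * z + np.sqrt(1 - rho**2) * eps)
    depth = np.clip(depth, 0.0, None)

    order = np.argsort(all_times, kind="stable")
    times = all_times[order]
    # guard strict monotonicity (click times never coincide by construction)
    movement = MovementSeries(
        time_s=times, depth_m=depth[order],
        head_deg=rng.normal(0, 20, len(times)),
        pitch_deg=rng.normal(0, 15, len(times)),
        roll_deg=rng.normal(0, 10, len(times)),
    )
    return DatasetPlan(codas=plan_rows, truths=truths, movement=movement)


def render_plan(plan: DatasetPlan, config: DatasetConfig, seed: int,
                ) -> tuple[Recording, list[Coda], list[SyntheticTruth]]:
    """Render a plan to audio plus annotations, refining truth peak times."""
    rng = np.random.default_rng(seed + 1)
    fs = config.sample_rate_hz
    last = plan.codas[-1]
    total_s = last[4] + sum(last[0].icis_s) + 0.1
    samples = np.zeros(int(round(total_s * fs)) + int(0.05 * fs))
    codas = []
    for (template, vowel, coda_id, whale, onset), truth in zip(plan.codas, plan.truths):
        wave, anns, local_truth = synthesize_coda(
            template, vowel, fs, noise_db=config.snr_db, seed=rng,
            coda_id=coda_id, whale_id=whale)
        start = int(round(onset * fs))
        end = min(start + len(wave), len(samples))
        samples[start:end] += wave[:end - start]
        for a in anns:
            a.click_time_s += onset
            a.peak_time_s += onset
        truth.peak_times_s = [t + onset for t in local_truth.peak_times_s]
        codas.append(Coda(coda_id=coda_id, whale_id=whale, clicks=anns,
                          coda_type=template.coda_type, hand_vowel=vowel.label))
    recording = Recording(samples=samples, sample_rate_hz=fs)
    return recording, codas, plan.truths


def truth_frame(truths) -> pd.DataFrame:
    rows = []
    for tr in truths:
        for k, (t, pt, centers) in enumerate(zip(tr.click_times_s, tr.peak_times_s,
                                                 tr.formant_centers_hz)):
            rows.append({
                "coda_id": tr.coda_id, "whale_id": tr.whale_id, "click_index": k,
                "vowel_label": tr.vowel_label, "trajectory": tr.trajectory,
                "click_time_s": t, "peak_time_s": pt,
                "f1_true_hz": centers[0],
                "f2_true_hz": centers[1] if len(centers) > 1 else "",
            })
    return pd.DataFrame(rows)


def synthesize_dataset(config: DatasetConfig, seed: int, outdir) -> dict[str, Path]:
    """Generate WAV + annotations/movement/truth CSVs; pure in (config, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plan = plan_dataset(config, seed)
    recording, codas, truths = render_plan(plan, config, seed)
    paths = {
        "audio": outdir / "audio.wav",
        "annotations": outdir / "annotations.csv",
        "movement": outdir / "movement.csv",
        "truth": outdir / "truth.csv",
    }
    write_recording(paths["audio"], recording)
    write_annotations(paths["annotations"], codas)
    write_movement(paths["movement"], plan.movement)
    truth_frame(truths).to_csv(paths["truth"], index=False)
    return paths
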