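"""Exclusion filtering, movement correlation, the closed-closed tube
resonance model, and dialogue transcription."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Coda, MovementSeries, logger

SPEED_OF_SOUND_M_S = 343.0


@dataclass
class ExclusionRules:
    """Drop codas from unidentified whales and from whales with few codas
    overall and no i-type hand labels."""

    drop_unknown: bool = True
    unknown_ids: tuple[str, ...] = ("unknown", "", "nan")
    min_codas: int = 50
    require_i: bool = True
    extra_exclude_whales: tuple[str, ...] = ()


@dataclass
class CorrelationReport:
    channel: str
    r: float | None
    n: int
    reason: str = ""


@dataclass
class DialogueRow:
    focal_id: str | None
    focal_type: str | None
    focal_vowel: str | None
    nonfocal_id: str | None
    nonfocal_type: str | None
    nonfocal_vowel: str | None
    overlap: bool
    flagged: bool = False


# ---------------------------------------------------------------------------
# Exclusion filter
# ---------------------------------------------------------------------------

def filter_codas(codas, rules: ExclusionRules | None = None
                 ) -> tuple[list[Coda], list[tuple[Coda, str]]]:
    """Split codas into (kept, excluded-with-reason).

    Reasons: ``unknown_whale`` for unidentified whales;
    ``low_count_no_i:<whale>`` for whales below ``min_codas`` codas that
    have no i-type hand label; ``excluded_whale:<whale>`` for explicitly
    configured exclusions.  Every excluded coda carries exactly one reason.
    """
    rules = rules or ExclusionRules()
    counts = Counter(c.whale_id for c in codas)
    has_i = {w: any(c.hand_vowel == "i" for c in codas if c.whale_id == w)
             for w in counts}
    kept, excluded = [], []
    for c in codas:
        if c.whale_id in rules.extra_exclude_whales:
            excluded.append((c, f"excluded_whale:{c.whale_id}"))
        elif rules.drop_unknown and c.whale_id.lower() in rules.unknown_ids:
            excluded.append((c, "unknown_whale"))
        elif (rules.min_codas and counts[c.whale_id] < rules.min_codas
              and (not rules.require_i or not has_i[c.whale_id])):
            excluded.append((c, f"low_count_no_i:{c.whale_id}"))
        else:
            kept.append(c)
    return kept, excluded


def exclusion_summary(excluded) -> pd.DataFrame:
    counts = Counter(reason for _, reason in excluded)
    return pd.DataFrame(sorted(counts.items()), columns=["reason", "count"])


# ---------------------------------------------------------------------------
# Movement correlation
# ---------------------------------------------------------------------------

def movement_correlation(click_times_s, peak_hz, movement: MovementSeries
                         ) -> list[CorrelationReport]:
    """Pearson r between per-click spectral peaks and each movement channel.

    Movement channels are linearly interpolated to the click times.  The
    spectral peak series is the first constrained peak per click (ascending
    frequency).  Constant series yield an undefined r, reported with a
    reason rather than NaN surprises.
    """
    t = np.asarray(click_times_s, dtype=float)
    p = np.asarray(peak_hz, dtype=float)
    ok = np.isfinite(p)
    t, p = t[ok], p[ok]
    if len(t) < 3:
        raise ValueError("need at least 3 clicks with peaks for correlation")
    reports = []
    for channel in MovementSeries.CHANNELS:
        m = movement.at(t, channel)
        if np.ptp(p) == 0 or np.ptp(m) == 0:
            reports.append(CorrelationReport(channel=channel, r=None, n=len(t),
                                             reason="constant series"))
            continue
        r, _ = stats.pearsonr(p, m)
        reports.append(CorrelationReport(channel=channel, r=float(r), n=len(t)))
    return reports


def correlation_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([{"channel": r.channel, "r": r.r, "n": r.n,
                          "reason": r.reason} for r in reports])


# ---------------------------------------------------------------------------
# Tube resonance model (closed-closed tube)
# ---------------------------------------------------------------------------

def tube_resonance_frequency(length_m: float, n: int = 1,
                             c: float = SPEED_OF_SOUND_M_S) -> float:
    """n-th resonance of a tube closed at both ends: f = n * c / (2 L)."""
    if length_m <= 0:
        raise ValueError("tube length must be positive")
    return n * c / (2.0 * length_m)


def tube_length_for_frequency(freq_hz: float, n: int = 1,
                              c: float = SPEED_OF_SOUND_M_S) -> float:
    """Tube length whose n-th closed-closed resonance is ``freq_hz``."""
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    return n * c / (2.0 * freq_hz)


# ---------------------------------------------------------------------------
# Bouts and dialogue transcription
# ---------------------------------------------------------------------------

def bout_ids(onsets_s, gap_s: float = 10.0) -> list[int]:
    """Assign bout indices: a gap strictly greater than ``gap_s`` starts a
    new bout (codas exactly ``gap_s`` apart share a bout)."""
    onsets = sorted(onsets_s)
    ids, current = [], 0
    for i, t in enumerate(onsets):
        if i and t - onsets[i - 1] > gap_s:
            current += 1
        ids.append(current)
    return ids


def transcribe_dialogue(focal_codas, nonfocal_codas, vowel_labels: dict[str, str],
                        overlap_s: float = 1.0) -> list[DialogueRow]:
    """Merge focal and non-focal codas chronologically into transcript rows.

    Codas whose onsets differ by less than ``overlap_s`` share a row.
    Pairing is greedy by nearest onset; a non-focal coda that could pair
    with several focal codas is attached to the nearest and the row is
    flagged.  ``vowel_labels`` maps coda_id -> label (a / i / ?).
    """
    focal = sorted(focal_codas, key=lambda c: c.onset_s)
    nonfocal = sorted(nonfocal_codas, key=lambda c: c.onset_s)

    candidate_pairs = []
    for i, f in enumerate(focal):
        for j, nf in enumerate(nonfocal):
            d = abs(f.onset_s - nf.onset_s)
            if d < overlap_s:
                candidate_pairs.append((d, i, j))
    candidate_pairs.sort()
    used_f, used_nf = set(), set()
    contested_f, contested_nf = Counter(), Counter()
    for _, i, j in candidate_pairs:
        contested_f[i] += 1
        contested_nf[j] += 1
    pairs = {}
    for d, i, j in candidate_pairs:
        if i in used_f or j in used_nf:
            continue
        used_f.add(i)
        used_nf.add(j)
        pairs[i] = (j, contested_f[i] > 1 or contested_nf[j] > 1)

    events = []  # (onset, row)
    for i, f in enumerate(focal):
        if i in pairs:
            j, flagged = pairs[i]
            nf = nonfocal[j]
            if flagged:
                logger.warning("overlapping triple near %.2fs resolved by nearest onset",
                               f.onset_s)
            events.append((min(f.onset_s, nf.onset_s), DialogueRow(
                focal_id=f.coda_id, focal_type=f.coda_type,
                focal_vowel=vowel_labels.get(f.coda_id),
                nonfocal_id=nf.coda_id, nonfocal_type=nf.coda_type,
                nonfocal_vowel=vowel_labels.get(nf.coda_id),
                overlap=True, flagged=flagged)))
        else:
            events.append((f.onset_s, DialogueRow(
                focal_id=f.coda_id, focal_type=f.coda_type,
                focal_vowel=vowel_labels.get(f.coda_id),
                nonfocal_id=None, nonfocal_type=None, nonfocal_vowel=None,
                overlap=False)))
    for j, nf in enumerate(nonfocal):
        if j not in used_nf:
            events.append((nf.onset_s, DialogueRow(
                focal_id=None, focal_type=None, focal_vowel=None,
                nonfocal_id=nf.coda_id, nonfocal_type=nf.coda_type,
                nonfocal_vowel=vowel_labels.get(nf.coda_id),
                overlap=False)))
    events.sort(key=lambda e: e[0])
    return [row for _, row in events]


def dialogue_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([{
        "focal_id": r.focal_id or "", "nonfocal_id": r.nonfocal_id or "",
        "focal_type": r.focal_type or "", "nonfocal_type": r.nonfocal_type or "",
        "focal_vowel": r.focal_vowel or "", "nonfocal_vowel": r.nonfocal_vowel or "",
        "overlap": r.overlap, "flagged": r.flagged,
    } for r in rows])
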