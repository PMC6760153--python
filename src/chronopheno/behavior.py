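"""Scoring of the cognitive-affective behavioral battery.

Consumes already-digitized traces (arm-entry sequences, boolean
movement/immobility traces, zone-occupancy traces) and applies the study's
scoring rules: Y-maze triad alternation, 2-s freezing/immobility runs,
forced-swim immobility latency with a 2-min scored window, zone occupancy and
boundary crossings, and sociability/novelty preference percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EntrySequence",
    "MovementTrace",
    "ZoneTrace",
    "BehaviorError",
    "spontaneous_alternation",
    "freezing_metrics",
    "immobility_latency",
    "zone_metrics",
    "social_preference",
]


class BehaviorError(ValueError):
    pass


@dataclass
class EntrySequence:
    """Ordered maze-arm entries for one subject.

    Consecutive duplicate entries are collapsed at construction (re-entering
    the arm you are in is not a new entry under the triad rule).
    """

    subject_id: str
    entries: list[str]
    immobile_seconds: float = 0.0
    arms: tuple[str, ...] = ("A", "B", "C")

    def __post_init__(self) -> None:
        bad = set(self.entries) - set(self.arms)
        if bad:
            raise BehaviorError(f"unknown arm labels {sorted(bad)}")
        deduped = []
        for a in self.entries:
            if not deduped or deduped[-1] != a:
                deduped.append(a)
        self.entries = deduped


@dataclass
class MovementTrace:
    """Boolean moving/not-moving samples at a fixed rate."""

    sample_hz: float
    moving: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_hz <= 0:
            raise BehaviorError("sample_hz must be positive")
        self.moving = np.asarray(self.moving, dtype=bool)

    @property
    def session_seconds(self) -> float:
        return self.moving.size / self.sample_hz


@dataclass
class ZoneTrace:
    """Zone label per sample at a fixed rate."""

    sample_hz: float
    zones: np.ndarray  # array of strings

    def __post_init__(self) -> None:
        if self.sample_hz <= 0:
            raise BehaviorError("sample_hz must be positive")
        self.zones = np.asarray(self.zones, dtype=object)


def spontaneous_alternation(seq: EntrySequence) -> tuple[float | None, int, int]:
    """Percent correct triad alternations in a Y-maze entry sequence.

    A triad is any window of 3 consecutive entries; it is correct when all
    three arms are distinct (the mouse visited all three arms before returning
    to a previously-visited one). Returns (percent, n_triads, n_entries);
    percent is None (flagged with a warning) when fewer than 3 entries exist.
    """
    e = seq.entries
    n = len(e)
    if n < 3:
        warnings.warn("fewer than 3 entries: alternation percentage undefined",
                      stacklevel=2)
        return None, 0, n
    triads = n - 2
    correct = sum(len({e[i], e[i + 1], e[i + 2]}) == 3 for i in range(triads))
    return 100.0 * correct / triads, triads, n


def _still_runs(trace: MovementTrace) -> list[tuple[int, int]]:
    """Maximal not-moving runs as (start_index, length_samples)."""
    still = ~trace.moving
    out = []
    i, n = 0, still.size
    while i < n:
        if still[i]:
            j = i
            while j < n and still[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def freezing_metrics(trace: MovementTrace, min_freeze_s: float = 2.0
                     ) -> tuple[float, int]:
    """Percent time freezing and number of freezing episodes.

    Freezing is any maximal run of non-movement lasting at least
    ``min_freeze_s`` (2 s in the study's hand-scoring convention); shorter
    stillness does not count.
    """
    min_samples = int(np.ceil(min_freeze_s * trace.sample_hz))
    runs = [(s, l) for s, l in _still_runs(trace) if l >= min_samples]
    frozen_s = sum(l for _, l in runs) / trace.sample_hz
    return 100.0 * frozen_s / trace.session_seconds, len(runs)


def immobility_latency(trace: MovementTrace, min_immobile_s: float = 2.0,
                       scored_from_s: float = 120.0
                       ) -> tuple[float, float, bool]:
    """Forced-swim immobility: latency to first episode and post-cutoff total.

    Returns (latency_s, immobile_after_cutoff_s, censored). The latency is the
    start time of the first immobile run of at least ``min_immobile_s``; if no
    such run exists the latency is censored at the session duration. The
    post-cutoff total accumulates only qualifying runs, and a run straddling
    ``scored_from_s`` contributes only its post-cutoff portion.
    """
    if trace.session_seconds < scored_from_s:
        raise BehaviorError(
            f"session ({trace.session_seconds:.1f} s) shorter than the scored-from "
            f"cutoff ({scored_from_s} s)")
    hz = trace.sample_hz
    min_samples = int(np.ceil(min_immobile_s * hz))
    runs = [(s, l) for s, l in _still_runs(trace) if l >= min_samples]
    if not runs:
        warnings.warn("no qualifying immobile episode: latency censored at session end",
                      stacklevel=2)
        return trace.session_seconds, 0.0, True
    latency = runs[0][0] / hz
    after = 0.0
    for s, l in runs:
        start_s, end_s = s / hz, (s + l) / hz
        after += max(0.0, end_s - max(start_s, scored_from_s))
    return latency, after, False


def zone_metrics(trace: ZoneTrace, zone_set: tuple[str, ...] | list[str]
                 ) -> tuple[dict[str, float], int]:
    """Percent time per zone and number of boundary crossings (label changes)."""
    labels = set(map(str, trace.zones))
    unknown = labels - set(zone_set)
    if unknown:
        raise BehaviorError(f"unknown zone labels {sorted(unknown)}")
    n = trace.zones.size
    if n == 0:
        raise BehaviorError("empty zone trace")
    percent = {z: 100.0 * float(np.sum(trace.zones == z)) / n for z in zone_set}
    crossings = int(np.sum(trace.zones[1:] != trace.zones[:-1]))
    return percent, crossings


def social_preference(interaction_s_bait1: float, interaction_s_bait2: float,
                      session_s: float) -> tuple[float, float | None]:
    """Sociability percentages for the 3-chamber task.

    Phase 1: ``percent_direct`` = percent of the session spent in direct
    interaction with the single bait mouse (bait1). Phase 2:
    ``novelty_preference`` = novel / (novel + familiar) x 100, with bait1 the
    novel and bait2 the familiar mouse; None (flagged) when the subject
    interacted with neither.
    """
    if interaction_s_bait1 < 0 or interaction_s_bait2 < 0:
        raise BehaviorError("interaction times must be non-negative")
    if max(interaction_s_bait1, interaction_s_bait2) > session_s:
        raise BehaviorError("interaction time exceeds session duration")
    percent_direct = 100.0 * interaction_s_bait1 / session_s
    total = interaction_s_bait1 + interaction_s_bait2
    if total == 0:
        warnings.warn("no interaction with either bait: preference undefined",
                      stacklevel=2)
        return percent_direct, None
    return percent_direct, 100.0 * interaction_s_bait1 / total
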