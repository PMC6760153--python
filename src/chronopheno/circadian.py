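"""Circadian analysis of wheel-running records.

Implements the free-running-period estimate (chi-squared periodogram of
Sokolove & Bushell), the nonparametric rhythm statistics interdaily stability
(IS) and intradaily variability (IV), step-template activity-onset detection,
the 20%-of-active-mean / 3-consecutive-hour sleep-offset rule, and the
2-consecutive-30-min-bin nap/bout scoring, plus daily activity summaries
(peak 4-h activity and percent decline from baseline).

Naming note: IS and IV follow the conventional definitions (IS = ratio of the
24-h profile variance to total variance, 1 for identical days; IV = normalized
mean square of successive hourly differences, ~2 for white noise). Some
software and papers swap the words "stability"/"variability"; the function
names here are unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .actogram import ActivityRecord, ActogramError, Segment, ZTime, hourly_counts, rebin

__all__ = [
    "PeriodogramResult",
    "RhythmStats",
    "SleepTiming",
    "NapBoutSummary",
    "ActivitySummary",
    "DegenerateInputError",
    "chi_squared_periodogram",
    "interdaily_stability",
    "intradaily_variability",
    "rhythm_stats",
    "detect_onsets",
    "active_windows_ld",
    "active_windows_from_onsets",
    "detect_sleep_offsets",
    "score_naps_bouts",
    "activity_summary",
]


class DegenerateInputError(ActogramError):
    """Input carries no variance (or otherwise cannot support the statistic)."""


# ---------------------------------------------------------------------------
# chi-squared periodogram


@dataclass
class PeriodogramResult:
    """Qp statistic over a grid of candidate periods with its significance line.

    The peak period is the candidate maximizing the excess of Qp over the
    (Bonferroni-corrected) chi-squared significance line; ``peak_excess``
    doubles as a periodogram amplitude.
    """

    candidate_periods_h: np.ndarray
    qp: np.ndarray
    significance_line: np.ndarray
    peak_period_h: float
    peak_excess: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.peak_excess > 0

    @property
    def any_significant(self) -> bool:
        return bool(np.any(self.qp > self.significance_line))


def chi_squared_periodogram(record: ActivityRecord,
                            search_window_h: tuple[float, float] = (20.0, 28.0),
                            alpha: float = 0.05) -> PeriodogramResult:
    """Estimate the free-running period by the chi-squared periodogram.

    For each candidate period of ``p`` bins the first ``K*p`` bins are folded
    into ``p`` columns and

        Qp = K*p * K * sum_h (M_h - M)^2 / sum_i (x_i - M)^2

    with ``M_h`` the column means and ``M`` the grand mean of the folded data.
    The same number of complete cycles ``K = floor(N/p_max)`` is used for
    every candidate: letting K vary with the candidate (the textbook
    ``floor(N/p)``) hands extra data to periods that exactly divide the
    record, which biases the peak toward such divisors (e.g. 24.0 h in an
    11-day record of 5-min bins).
    Under the no-rhythm null Qp is asymptotically chi2(p-1); at a finite
    number of cycles the exact null (for Gaussian noise) is
    ``Qp/N' ~ Beta((p-1)/2, (N'-p)/2)``, and the significance line uses that
    exact quantile at ``1 - alpha/n_candidates`` (Bonferroni over the
    candidate grid) — the chi-squared line is noticeably conservative at the
    ~10 cycles a typical DD segment provides. Candidates are every integer
    bin count whose period lies inside ``search_window_h``.
    """
    x = record.counts.astype(float)
    n = x.size
    if np.ptp(x) == 0:
        raise DegenerateInputError("record has zero variance; period undefined")
    bin_h = record.bin_minutes / 60.0
    low, high = search_window_h
    p_lo = int(np.ceil(low / bin_h))
    p_hi = int(np.floor(high / bin_h))
    if p_lo <= 2 or p_hi > n // 2:
        raise ActogramError(
            f"search window {search_window_h} h not representable: candidate folds "
            f"must span >2 bins and at most half the record ({n} bins of {bin_h} h)")
    periods_bins = np.arange(p_lo, p_hi + 1)
    m = periods_bins.size
    qp = np.empty(m)
    n_used = np.empty(m, dtype=int)
    k = n // p_hi  # common cycle count across candidates (see docstring)
    for j, p in enumerate(periods_bins):
        y = x[: k * p].reshape(k, p)
        grand = y.mean()
        col = y.mean(axis=0)
        denom = ((y - grand) ** 2).sum()
        qp[j] = k * p * k * ((col - grand) ** 2).sum() / denom
        n_used[j] = k * p
    sig = n_used * stats.beta.ppf(1 - alpha / m, (periods_bins - 1) / 2,
                                  (n_used - periods_bins) / 2)
    excess = qp - sig
    peak = int(np.argmax(excess))
    return PeriodogramResult(
        candidate_periods_h=periods_bins * bin_h,
        qp=qp,
        significance_line=sig,
        peak_period_h=float(periods_bins[peak] * bin_h),
        peak_excess=float(excess[peak]),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# nonparametric rhythm statistics (hourly binning)


def _hourly(record: ActivityRecord) -> np.ndarray:
    if record.bin_minutes > 60:
        raise ActogramError("rhythm statistics need bins of at most 1 h")
    return hourly_counts(record)


def interdaily_stability(record: ActivityRecord) -> float:
    """IS: variance of the mean 24-h profile over total variance, in [0, 1].

    Computed on hourly-rebinned counts over complete 24-h days; 1 for a
    perfectly day-repeating record, ~1/n_days for structureless noise.
    """
    x = _hourly(record)
    n_days = x.size // 24
    if n_days < 2:
        raise ActogramError("interdaily stability needs >= 2 complete days")
    x = x[: n_days * 24]
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance; IS undefined")
    prof = x.reshape(n_days, 24).mean(axis=0)
    xbar = x.mean()
    return float(x.size * ((prof - xbar) ** 2).sum() / (24 * ((x - xbar) ** 2).sum()))


def intradaily_variability(record: ActivityRecord) -> float:
    """IV: normalized mean square successive difference of hourly counts.

    ~0 for a smooth sinusoidal rhythm, ~2 for white noise, up to 4 for a
    strictly alternating sequence.
    """
    x = _hourly(record)
    if x.size < 24:
        raise ActogramError("intradaily variability needs >= 24 hourly samples")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance; IV undefined")
    n = x.size
    return float(n * (np.diff(x) ** 2).sum() / ((n - 1) * ((x - x.mean()) ** 2).sum()))


@dataclass
class RhythmStats:
    is_value: float
    iv_value: float
    hourly_profile: np.ndarray  # 24 mean counts/hour


def rhythm_stats(record: ActivityRecord) -> RhythmStats:
    x = _hourly(record)
    n_days = x.size // 24
    prof = x[: n_days * 24].reshape(n_days, 24).mean(axis=0)
    return RhythmStats(is_value=interdaily_stability(record),
                       iv_value=intradaily_variability(record),
                       hourly_profile=prof)


# ---------------------------------------------------------------------------
# onset detection


def _smoothed_bins(record: ActivityRecord, smooth_hours: float = 1.0) -> np.ndarray:
    """Centered moving average over ``smooth_hours`` of the bin series."""
    x = record.counts.astype(float)
    w = max(1, int(round(smooth_hours * 60 / record.bin_minutes)))
    kernel = np.ones(w)
    # normalize by actual kernel coverage so record edges carry no ramp artifact
    return (np.convolve(x, kernel, mode="same")
            / np.convolve(np.ones_like(x), kernel, mode="same"))


def detect_onsets(record: ActivityRecord, tau_h: float,
                  template_half_h: float = 6.0,
                  smooth_hours: float = 1.0) -> list[ZTime]:
    """Per-cycle activity onsets by step-template matching.

    The record is folded into cycles of ``tau_h``; within each cycle the onset
    is the time maximizing the contrast between the mean smoothed activity in
    the following ``template_half_h`` hours and the preceding
    ``template_half_h`` hours (a -1/+1 step template). Ties break to the
    earliest time. Cycles without any activity are omitted (with a warning).

    Returned ZTimes use the CT frame anchored so that the first detected onset
    is CT12 (nocturnal convention); ``abs_hours`` carries the absolute onset
    time in hours since record start.
    """
    if not (20.0 < tau_h < 28.0):
        raise ActogramError(f"tau_h={tau_h} outside the plausible (20, 28) h range")
    bin_h = record.bin_minutes / 60.0
    n = record.n_bins
    if n * bin_h < 3 * tau_h:
        raise ActogramError("onset detection needs at least 3 cycles")
    x = _smoothed_bins(record, smooth_hours)
    half = max(1, int(round(template_half_h / bin_h)))
    csum = np.concatenate([[0.0], np.cumsum(x)])
    t_all = np.arange(n)
    hi_edge = np.minimum(t_all + half, n)
    lo_edge = np.maximum(t_all - half, 0)
    after = (csum[hi_edge] - csum[t_all]) / np.maximum(hi_edge - t_all, 1)
    before = (csum[t_all] - csum[lo_edge]) / np.maximum(t_all - lo_edge, 1)
    all_scores = after - before
    all_scores[0] = 0.0  # empty "before" window: not a detectable onset

    raw = record.counts
    n_cycles = int(n * bin_h // tau_h)
    onsets_abs: list[float] = []
    skipped = 0
    for c in range(n_cycles):
        lo = int(round(c * tau_h / bin_h))
        hi = min(int(round((c + 1) * tau_h / bin_h)), n)
        if raw[lo:hi].sum() == 0:
            skipped += 1
            continue
        scores = all_scores[lo:hi]
        if np.ptp(scores) <= 1e-9 * max(1.0, float(np.abs(x[lo:hi]).max())):
            skipped += 1  # flat template response: no rhythm in this cycle
            continue
        onsets_abs.append((lo + int(np.argmax(scores))) * bin_h)
    if skipped:
        warnings.warn(f"detect_onsets: {skipped} cycle(s) without usable activity omitted",
                      stacklevel=2)
    if not onsets_abs:
        return []
    anchor = onsets_abs[0]
    out = []
    for t in onsets_abs:
        ct = (12.0 + ((t - anchor) % tau_h) * 24.0 / tau_h) % 24.0
        out.append(ZTime(value=ct, reference="CT", abs_hours=t))
    return out


# ---------------------------------------------------------------------------
# active-phase windows


def active_windows_ld(segment: Segment, n_days: int | None = None,
                      t0_zt_hour: float = 0.0) -> list[tuple[float, float]]:
    """Per-day dark-phase (active) windows for an LD segment, in absolute hours
    since the start of the sliced segment record.

    ``t0_zt_hour`` is the ZT value at the record's first bin (0 when the record
    starts at lights-on).
    """
    if segment.lighting != "LD":
        raise ActogramError("active_windows_ld needs an LD segment")
    n_days = segment.n_days if n_days is None else n_days
    on, off = segment.lights_on_hour, segment.lights_off_hour
    dark_len = (on - off) % 24 or 24.0
    first_off = (off - t0_zt_hour - on) % 24  # hours from record start to lights-off
    return [(first_off + 24.0 * d, first_off + 24.0 * d + dark_len)
            for d in range(n_days)]


def active_windows_from_onsets(onsets: list[ZTime], tau_h: float,
                               active_hours: float = 12.0) -> list[tuple[float, float]]:
    """DD active windows: ``active_hours`` starting at each detected onset."""
    return [(z.abs_hours, z.abs_hours + active_hours) for z in onsets
            if z.abs_hours is not None]


# ---------------------------------------------------------------------------
# sleep offsets (the 20% / 3-consecutive-hour rule)


@dataclass
class SleepTiming:
    """Per-cycle activity onsets and rule-based sleep offsets.

    An offset is the start of the first run of at least ``run_hours``
    consecutive hours, searched forward from the cycle's activity onset, in
    each of which hourly counts fall below ``threshold_frac`` of the mean
    hourly counts of the active phase of the analyzed segment.
    """

    onsets: list[ZTime]
    offsets: list[ZTime]
    active_mean_hourly: float
    threshold_frac: float = 0.20
    run_hours: int = 3


def detect_sleep_offsets(record: ActivityRecord,
                         active_windows: list[tuple[float, float]],
                         threshold_frac: float = 0.20,
                         run_hours: int = 3,
                         zt0_abs_hour: float | None = 0.0) -> SleepTiming:
    """Apply the sleep-offset rule cycle by cycle.

    ``active_windows`` gives one (start, end) active-phase window per cycle in
    absolute hours since record start (from the phase plan in LD, or from
    detected onsets in DD). The 20% reference is the mean hourly count within
    the active windows of *this* record (i.e. per analyzed segment). The search
    for each cycle runs from its active-window start to the next cycle's start
    (record end for the last cycle). Cycles with no qualifying run contribute
    no offset.

    ``zt0_abs_hour`` maps absolute hours to ZT for reporting (ZT0 at that
    absolute hour, 24-h frame); pass None to report clock-frame hours.
    """
    hours = _hourly_series(record)
    n_h = hours.size
    in_active = np.zeros(n_h, bool)
    for lo, hi in active_windows:
        a = int(np.ceil(lo - 1e-9))
        b = int(np.floor(hi + 1e-9))
        in_active[max(a, 0): min(b, n_h)] = True
    if not in_active.any():
        raise ActogramError("active windows do not overlap the record")
    ref = float(hours[in_active].mean())
    thr = threshold_frac * ref
    below = hours < thr

    onsets, offsets = [], []
    for i, (lo, hi) in enumerate(active_windows):
        start = int(np.ceil(lo - 1e-9))
        stop = int(np.ceil(active_windows[i + 1][0] - 1e-9)) if i + 1 < len(active_windows) else n_h
        start, stop = max(start, 0), min(stop, n_h)
        onsets.append(_to_ztime(lo, zt0_abs_hour))
        run = 0
        found = None
        for h in range(start, stop):
            run = run + 1 if below[h] else 0
            if run == run_hours:
                found = h - run_hours + 1
                break
        if found is not None:
            offsets.append(_to_ztime(float(found), zt0_abs_hour))
    if not offsets:
        warnings.warn("detect_sleep_offsets: no cycle satisfied the rule", stacklevel=2)
    return SleepTiming(onsets=onsets, offsets=offsets, active_mean_hourly=ref,
                       threshold_frac=threshold_frac, run_hours=run_hours)


def _hourly_series(record: ActivityRecord) -> np.ndarray:
    if record.bin_minutes > 60:
        raise ActogramError("sleep-offset scoring needs bins of at most 1 h")
    return hourly_counts(record)


def _to_ztime(abs_hours: float, zt0_abs_hour: float | None) -> ZTime:
    if zt0_abs_hour is None:
        return ZTime(value=abs_hours % 24.0, reference="clock", abs_hours=abs_hours)
    return ZTime(value=(abs_hours - zt0_abs_hour) % 24.0, reference="ZT",
                 abs_hours=abs_hours)


# ---------------------------------------------------------------------------
# naps and bouts (30-min-bin run scoring)


@dataclass
class NapBoutSummary:
    """Naps (>=2 consecutive empty 30-min bins in the active phase) and bouts
    (>=2 consecutive non-empty 30-min bins in the rest phase)."""

    naps: list[tuple[ZTime, float]] = field(default_factory=list)
    bouts: list[tuple[ZTime, float]] = field(default_factory=list)

    @property
    def nap_count(self) -> int:
        return len(self.naps)

    @property
    def bout_count(self) -> int:
        return len(self.bouts)

    @property
    def mean_nap_minutes(self) -> float:
        return float(np.mean([l for _, l in self.naps])) if self.naps else 0.0

    @property
    def total_nap_minutes(self) -> float:
        return float(sum(l for _, l in self.naps))

    @property
    def mean_bout_minutes(self) -> float:
        return float(np.mean([l for _, l in self.bouts])) if self.bouts else 0.0


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal True-runs of length >= min_len as (start, length) index pairs."""
    out = []
    i, n = 0, mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def score_naps_bouts(record: ActivityRecord,
                     active_windows: list[tuple[float, float]],
                     scoring_bin_minutes: int = 30,
                     min_bins: int = 2,
                     zt0_abs_hour: float | None = 0.0) -> NapBoutSummary:
    """Score naps and activity bouts on 30-min rebinned counts.

    A nap is a maximal run of >= ``min_bins`` consecutive zero-count 30-min
    bins lying inside an active-phase window; a bout is a maximal run of
    >= ``min_bins`` consecutive nonzero bins inside the rest phase (the
    complement of the active windows between consecutive cycles). Run lengths
    are reported in minutes.
    """
    rec30 = rebin(record, scoring_bin_minutes) if record.bin_minutes != scoring_bin_minutes else record
    bin_h = scoring_bin_minutes / 60.0
    n = rec30.n_bins
    starts = np.arange(n) * bin_h
    ends = starts + bin_h
    in_active = np.zeros(n, bool)
    for lo, hi in active_windows:
        in_active |= (starts >= lo - 1e-9) & (ends <= hi + 1e-9)
    # rest phase: bins between the end of one active window and the start of the next
    in_rest = np.zeros(n, bool)
    for i, (_, hi) in enumerate(active_windows):
        nxt = active_windows[i + 1][0] if i + 1 < len(active_windows) else n * bin_h
        in_rest |= (starts >= hi - 1e-9) & (ends <= nxt + 1e-9)
    if active_windows:
        in_rest |= ends <= active_windows[0][0] + 1e-9  # rest before the first onset

    zero = rec30.counts == 0
    summary = NapBoutSummary()
    for start, length in _segmented_runs(zero & in_active, in_active, min_bins):
        summary.naps.append((_to_ztime(start * bin_h, zt0_abs_hour),
                             length * scoring_bin_minutes))
    for start, length in _segmented_runs((~zero) & in_rest, in_rest, min_bins):
        summary.bouts.append((_to_ztime(start * bin_h, zt0_abs_hour),
                              length * scoring_bin_minutes))
    return summary


def _segmented_runs(mask: np.ndarray, domain: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """True-runs of mask, not allowed to bridge gaps in the domain mask."""
    out = []
    # split domain into contiguous index blocks
    idx = np.flatnonzero(domain)
    if idx.size == 0:
        return out
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for block in splits:
        sub = mask[block[0]: block[-1] + 1]
        for s, l in _runs(sub, min_len):
            out.append((block[0] + s, l))
    return out


# ---------------------------------------------------------------------------
# activity summaries


@dataclass
class ActivitySummary:
    """Daily activity profile summaries.

    ``peak4h_counts_per_min`` is the mean counts/min over the best contiguous
    4-h window of the day-averaged hourly profile (circular, so a peak spanning
    midnight is found); ``percent_change_vs_baseline`` is the percent *decline*
    from a baseline summary (positive = activity dropped).
    """

    peak4h_counts_per_min: float
    peak4h_start_hour: float
    daily_total: float
    hourly_profile: np.ndarray
    profile_amplitude_counts_per_min: float
    percent_change_vs_baseline: float | None = None


def activity_summary(record: ActivityRecord,
                     baseline: "ActivitySummary | None" = None,
                     window_hours: int = 4) -> ActivitySummary:
    x = _hourly_series(record)
    n_days = x.size // 24
    if n_days < 1:
        raise ActogramError("activity summary needs at least one complete day")
    prof = x[: n_days * 24].reshape(n_days, 24).mean(axis=0)  # counts/hour
    ext = np.concatenate([prof, prof[: window_hours - 1]])
    win = np.convolve(ext, np.ones(window_hours) / window_hours, mode="valid")[:24]
    peak_start = int(np.argmax(win))
    peak = float(win[peak_start] / 60.0)  # counts/min
    change = None
    if baseline is not None:
        if baseline.peak4h_counts_per_min <= 0:
            warnings.warn("baseline peak activity is zero; percent change undefined",
                          stacklevel=2)
        else:
            change = 100.0 * (baseline.peak4h_counts_per_min - peak) / baseline.peak4h_counts_per_min
    if prof.max() == 0:
        warnings.warn("all-zero record: peak activity is 0", stacklevel=2)
    return ActivitySummary(
        peak4h_counts_per_min=peak,
        peak4h_start_hour=float(peak_start),
        daily_total=float(prof.sum()),
        hourly_profile=prof,
        profile_amplitude_counts_per_min=float((prof.max() - prof.min()) / 60.0),
        percent_change_vs_baseline=change,
    )
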