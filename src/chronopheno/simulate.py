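"""Ground-truth simulators for every data type the pipeline consumes.

The actogram generator emulates the structure of mouse wheel-running data:
Poisson counts in fixed-width bins, a free-running active phase of
configurable period and duty cycle with half-cosine 1-h edge ramps (so onset
and offset truths are unambiguous), per-cycle onset jitter, day-by-day
amplitude decay, injected naps (strictly zero-count runs in the active
phase), and multiplicative light masking during lights-on in LD segments.
Behavioral traces and fluorescence section images are generated with the
same philosophy: every knob the downstream scorer estimates is a programmed
truth carried alongside the data.

The default cohort preset mirrors the study design it emulates: APP-PS1 vs
nontransgenic genotypes crossed with 0/10/30 mg/kg dosing, n = 8 per group,
baseline and treatment phases of 11 and 12 days of DD, group mean periods
23.69 h (APP-PS1) and 23.95 h (nTg), period lengthening under treatment,
strong (61%) vs moderate (~43%) activity decline, and a 2.5-h sleep-offset
delay in high-dose APP-PS1 mice. Those numbers are generator inputs, not
reproduction targets: the original per-animal recordings are not deposited.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np
import pandas as pd

from .actogram import ActivityRecord, ActogramError, PhasePlan
from .behavior import EntrySequence, MovementTrace, ZoneTrace
from .histology import SectionImage

__all__ = [
    "ActogramParams",
    "TruthRecord",
    "GroupSpec",
    "CohortSpec",
    "ImageParams",
    "PlaqueSpec",
    "simulate_actogram",
    "simulate_cohort",
    "paper_cohort_spec",
    "simulate_behavior",
    "simulate_section_image",
    "simulate_image_cohort",
]

T0 = datetime(2024, 1, 1, 6, 0)  # nominal lights-on anchor for simulated records

# Between-animal variability defaults (not study-reported; chosen as realistic
# for C57-background mice): tau SD 0.15 h, ~15% lognormal spread in running
# rates, 0.25 h SD day-to-day onset jitter.
TAU_BETWEEN_SD_H = 0.15
RATE_LOGNORM_SD = 0.15


@dataclass
class ActogramParams:
    """Knobs of one simulated wheel-running record."""

    tau_h: float = 23.95
    days: int = 11
    bin_minutes: int = 5
    active_rate: float = 30.0       # counts/min on the active plateau
    rest_rate: float = 0.3          # counts/min in the rest phase
    active_fraction: float = 0.5    # fraction of each cycle spent active
    amplitude_decay_per_day: float = 0.0
    nap_prob_per_30min: float = 0.0
    # nap lengths in record bins; default 60-120 min at 5-min bins, so every
    # injected nap satisfies the >=2-consecutive-30-min-bin scoring rule
    nap_len_bins: tuple[int, int] = (12, 24)
    onset_jitter_sd_h: float = 0.0
    light_masking_factor: float = 1.0  # multiplies rate while lights are on (LD)
    onset_offset_h: float = 6.0     # first activity onset, hours after record start
    ramp_h: float = 1.0
    deterministic: bool = False     # rounded expected counts instead of Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if not (20.0 < self.tau_h < 28.0):
            raise ActogramError(f"tau_h={self.tau_h} outside (20, 28)")
        if self.active_rate < 0 or self.rest_rate < 0:
            raise ActogramError("rates must be non-negative")
        if not (0.0 <= self.nap_prob_per_30min <= 1.0):
            raise ActogramError("nap_prob_per_30min must be a probability")
        if not (0.0 <= self.light_masking_factor <= 1.0):
            raise ActogramError("light_masking_factor must lie in [0, 1]")
        if not (0.0 < self.active_fraction < 1.0):
            raise ActogramError("active_fraction must lie in (0, 1)")
        if self.days < 1:
            raise ActogramError("days must be >= 1")


@dataclass
class TruthRecord:
    """Everything needed to score the analyses of one simulated record."""

    tau_h: float
    onsets_h: list[float]                    # activity-onset time per cycle
    active_windows: list[tuple[float, float]]  # (onset, activity end) per cycle
    naps: list[tuple[int, int]]              # (start_bin, length_bins)
    params: ActogramParams = None


def _envelope(t: np.ndarray, onsets: list[float], active_len_h: float,
              ramp_h: float) -> np.ndarray:
    env = np.zeros_like(t)
    for o in onsets:
        end = o + active_len_h
        rise = (t >= o) & (t < o + ramp_h)
        plateau = (t >= o + ramp_h) & (t < end - ramp_h)
        fall = (t >= end - ramp_h) & (t < end)
        env[rise] = np.maximum(env[rise], 0.5 * (1 - np.cos(np.pi * (t[rise] - o) / ramp_h)))
        env[plateau] = 1.0
        env[fall] = np.maximum(env[fall], 0.5 * (1 - np.cos(np.pi * (end - t[fall]) / ramp_h)))
    return env


def simulate_actogram(params: ActogramParams, plan: PhasePlan | None = None,
                      subject_id: str = "sim", rng: np.random.Generator | None = None
                      ) -> tuple[ActivityRecord, TruthRecord]:
    """Simulate one wheel-running record plus its ground truth.

    When ``plan`` is given, LD segments multiply the rate by
    ``light_masking_factor`` during lights-on hours (ZT0 taken as the record
    start). Fully reproducible from ``params.seed`` (or an explicit ``rng``).
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    bin_h = params.bin_minutes / 60.0
    n_bins = params.days * 24 * 60 // params.bin_minutes
    t = (np.arange(n_bins) + 0.5) * bin_h  # bin centers, hours since start

    total_h = n_bins * bin_h
    active_len = params.active_fraction * params.tau_h
    n_cycles = int(np.ceil(total_h / params.tau_h)) + 1
    onsets = []
    for c in range(n_cycles):
        o = params.onset_offset_h + c * params.tau_h
        if params.onset_jitter_sd_h > 0:
            o += rng.normal(0.0, params.onset_jitter_sd_h)
        if o < total_h:
            onsets.append(float(o))
    env = _envelope(t, onsets, active_len, params.ramp_h)

    # continuous exponential decay (per 24 h) — a day-stepped decay would
    # inject a spurious exact-24.0-h component into the periodogram
    active_now = params.active_rate * (1.0 - params.amplitude_decay_per_day) ** (t / 24.0)
    rate = params.rest_rate + (active_now - params.rest_rate) * env  # counts/min

    # naps: strictly-zero runs starting on the record's 30-min grid, inside the
    # active plateau, non-overlapping
    naps: list[tuple[int, int]] = []
    if params.nap_prob_per_30min > 0:
        bins_per_30 = 30 // params.bin_minutes
        slot = 0
        n_slots = n_bins // bins_per_30
        while slot < n_slots:
            b0 = slot * bins_per_30
            t0h, t1h = b0 * bin_h, (b0 + bins_per_30) * bin_h
            plateau_end = next(
                (o + active_len - params.ramp_h for o in onsets
                 if o + params.ramp_h <= t0h and t1h <= o + active_len - params.ramp_h),
                None)
            if plateau_end is not None and rng.random() < params.nap_prob_per_30min:
                length = int(rng.integers(params.nap_len_bins[0], params.nap_len_bins[1] + 1))
                length = (length // bins_per_30) * bins_per_30 or bins_per_30
                # clip to the plateau so the whole nap is scoreable truth
                max_len = int(plateau_end / bin_h) - b0
                length = min(length, (max_len // bins_per_30) * bins_per_30, n_bins - b0)
                if length < 2 * bins_per_30:
                    slot += 1
                    continue
                rate[b0: b0 + length] = 0.0
                naps.append((b0, length))
                slot += length // bins_per_30 + 1  # leave a gap so naps stay maximal
            else:
                slot += 1

    if plan is not None:
        lights_on = np.zeros(n_bins, bool)
        for seg in plan.segments:
            if seg.lighting != "LD":
                continue
            seg_mask = (t >= seg.start_day * 24) & (t < seg.end_day * 24)
            zt = t % 24.0  # record starts at lights-on (ZT0)
            day_len = (seg.lights_off_hour - seg.lights_on_hour) % 24 or 24.0
            lights_on |= seg_mask & (zt < day_len)
        rate[lights_on] *= params.light_masking_factor

    lam = rate * params.bin_minutes
    counts = np.round(lam).astype(np.int64) if params.deterministic else rng.poisson(lam)
    record = ActivityRecord(subject_id=subject_id, t0=T0,
                            bin_minutes=params.bin_minutes, counts=counts)
    truth = TruthRecord(tau_h=params.tau_h, onsets_h=onsets,
                        active_windows=[(o, o + active_len) for o in onsets],
                        naps=naps, params=params)
    return record, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class GroupSpec:
    """One genotype x dose cell with baseline parameters and treatment effects."""

    genotype: str
    dose_mg_kg: float
    n: int
    baseline: ActogramParams
    treatment_days: int = 12
    tau_add_h: float = 0.0            # period lengthening under treatment
    activity_retention: float = 1.0   # treated active rate / baseline active rate
    active_extension_h: float = 0.0   # sleep-offset delay under treatment
    nap_prob_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ActogramError("each group needs n >= 1")


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    tau_between_sd_h: float = TAU_BETWEEN_SD_H
    rate_lognorm_sd: float = RATE_LOGNORM_SD
    tau_response_sd_h: float = 0.05
    seed: int = 0


def paper_cohort_spec(n_per_group: int = 8, days_baseline: int = 11,
                      days_treatment: int = 12, seed: int = 0) -> CohortSpec:
    """The default preset: 2 genotypes x 3 doses in DD, baseline vs treatment.

    Group means follow the study structure this simulator emulates: periods
    23.69 h (APP-PS1) vs 23.95 h (nTg); treatment lengthens the period by
    ~0.3 h at both doses in APP-PS1 and at the high dose in nTg; treated-phase
    activity retains 39% (APP-PS1) or 57% (nTg) of baseline (61%/43% declines);
    the high dose extends the APP-PS1 active phase by 2.5 h (delayed sleep
    offset); APP-PS1 mice nap more (greater fragmentation), and the high dose
    makes naps fewer but longer.
    """
    groups: list[GroupSpec] = []
    for genotype, tau in (("APP-PS1", 23.69), ("nTg", 23.95)):
        for dose in (0.0, 10.0, 30.0):
            base = ActogramParams(
                tau_h=tau, days=days_baseline, active_rate=30.0, rest_rate=0.3,
                amplitude_decay_per_day=0.01,
                nap_prob_per_30min=0.10 if genotype == "APP-PS1" else 0.05,
                onset_jitter_sd_h=0.25)
            if genotype == "APP-PS1":
                tau_add = 0.3 if dose > 0 else 0.0
                retention, ext = 0.39, (2.5 if dose == 30.0 else 0.0)
                napf = 0.5 if dose == 30.0 else 1.0
            else:
                tau_add = {0.0: 0.0, 10.0: 0.1, 30.0: 0.3}[dose]
                retention, ext, napf = 0.57, 0.0, 1.0
            groups.append(GroupSpec(
                genotype=genotype, dose_mg_kg=dose, n=n_per_group, baseline=base,
                treatment_days=days_treatment, tau_add_h=tau_add,
                activity_retention=retention, active_extension_h=ext,
                nap_prob_factor=napf))
    return CohortSpec(groups=groups, seed=seed)


def simulate_cohort(spec: CohortSpec
                    ) -> tuple[dict[tuple[str, str], ActivityRecord],
                               pd.DataFrame, pd.DataFrame]:
    """Simulate every subject of a cohort in both phases.

    Returns ``(records, manifest, truth)``: records keyed by
    ``(subject_id, phase)``; a manifest of subject to genotype/dose; and a
    truth table with each subject's programmed per-phase parameters.
    """
    rng = np.random.default_rng(spec.seed)
    records: dict[tuple[str, str], ActivityRecord] = {}
    manifest_rows, truth_rows = [], []
    sid = 0
    for g in spec.groups:
        for _ in range(g.n):
            sid += 1
            subject = f"M{sid:03d}"
            tau_s = g.baseline.tau_h + rng.normal(0.0, spec.tau_between_sd_h)
            rate_s = g.baseline.active_rate * np.exp(rng.normal(0.0, spec.rate_lognorm_sd))
            base_params = replace(g.baseline, tau_h=tau_s, active_rate=rate_s,
                                  seed=int(rng.integers(2 ** 31)))
            tau_t = tau_s + g.tau_add_h + rng.normal(0.0, spec.tau_response_sd_h)
            af = g.baseline.active_fraction
            af_t = min(0.9, af + g.active_extension_h / tau_t)
            treat_params = replace(
                g.baseline, tau_h=tau_t, days=g.treatment_days,
                active_rate=rate_s * g.activity_retention,
                active_fraction=af_t,
                nap_prob_per_30min=g.baseline.nap_prob_per_30min * g.nap_prob_factor,
                seed=int(rng.integers(2 ** 31)))
            for phase, params in (("baseline", base_params), ("treatment", treat_params)):
                rec, truth = simulate_actogram(params, subject_id=subject)
                rec.genotype, rec.dose_mg_kg = g.genotype, g.dose_mg_kg
                records[(subject, phase)] = rec
                truth_rows.append({
                    "subject_id": subject, "genotype": g.genotype,
                    "dose_mg_kg": g.dose_mg_kg, "phase": phase,
                    "tau_true_h": params.tau_h,
                    "active_rate": params.active_rate,
                    "active_fraction": params.active_fraction,
                    "nap_prob_per_30min": params.nap_prob_per_30min,
                    "n_naps_injected": len(truth.naps)})
            manifest_rows.append({"subject_id": subject, "genotype": g.genotype,
                                  "dose_mg_kg": g.dose_mg_kg})
    return records, pd.DataFrame(manifest_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(kind: str, params: dict | None = None, seed: int = 0):
    """Simulate one behavioral trace plus its truth dict.

    kinds: ``ymaze`` (Markov entry sequence with alternation propensity
    ``p_alt``), ``swim``/``fear`` (alternating mobile/immobile interval
    process with a programmed first-immobility latency), ``zones`` (two-state
    dwell process with programmed occupancy), ``sociability`` (interaction
    times).
    """
    rng = np.random.default_rng(seed)
    p = dict(params or {})
    if kind == "ymaze":
        p_alt = float(p.get("p_alt", 0.7))
        n = int(p.get("n_entries", 20))
        arms = ("A", "B", "C")
        entries = list(rng.choice(arms, size=2, replace=False))
        while len(entries) < n:
            last, prev = entries[-1], entries[-2]
            novel = ({*arms} - {last, prev}).pop()
            entries.append(novel if rng.random() < p_alt else prev)
        seq = EntrySequence(subject_id=p.get("subject_id", "sim"), entries=entries)
        return seq, {"p_alt": p_alt, "n_entries": n}
    if kind in ("swim", "fear"):
        hz = float(p.get("sample_hz", 5.0))
        session = float(p.get("session_s", 360.0))
        latency = float(p.get("first_latency_s", 45.0))
        im_mean = float(p.get("immobile_mean_s", 10.0))
        mob_mean = float(p.get("mobile_mean_s", 20.0))
        n = int(round(session * hz))
        moving = np.ones(n, bool)
        t = latency
        immobile = True
        while t < session:
            dur = 2.0 + rng.exponential(im_mean - 2.0) if immobile else rng.exponential(mob_mean)
            a, b = int(round(t * hz)), int(round(min(t + dur, session) * hz))
            if immobile:
                moving[a:b] = False
            t += dur
            immobile = not immobile
        trace = MovementTrace(sample_hz=hz, moving=moving)
        return trace, {"first_latency_s": latency, "session_s": session}
    if kind == "zones":
        hz = float(p.get("sample_hz", 5.0))
        session = float(p.get("session_s", 600.0))
        zones = tuple(p.get("zone_set", ("center", "periphery")))
        occ = float(p.get("occupancy_first", 0.3))
        dwell = float(p.get("mean_dwell_s", 5.0))
        mean_first = dwell * occ / (1 - occ) if occ < 1 else dwell
        n = int(round(session * hz))
        labels = np.empty(n, dtype=object)
        t, in_first = 0.0, rng.random() < occ
        while t < session:
            dur = rng.exponential(mean_first if in_first else dwell)
            a, b = int(round(t * hz)), int(round(min(t + dur, session) * hz))
            labels[a:b] = zones[0] if in_first else zones[1]
            t += dur
            in_first = not in_first
        labels[labels == None] = zones[1]  # noqa: E711  (guard against rounding gaps)
        trace = ZoneTrace(sample_hz=hz, zones=labels)
        return trace, {"occupancy_first": occ, "zone_set": zones}
    if kind == "sociability":
        session = float(p.get("session_s", 900.0))
        direct = float(p.get("direct_fraction", 0.15))
        novel = float(p.get("novel_s", 90.0))
        familiar = float(p.get("familiar_s", 90.0))
        return ((direct * session, novel, familiar, session),
                {"direct_fraction": direct,
                 "novelty_preference": 100.0 * novel / (novel + familiar)
                 if novel + familiar else None})
    raise ValueError(f"unknown behavior task {kind!r}")


# ---------------------------------------------------------------------------
# histology images


@dataclass
class PlaqueSpec:
    center_px: tuple[float, float]
    radius_um: float
    peak_intensity: float
    profile: str = "disc"  # disc | gaussian


@dataclass
class ImageParams:
    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    background_mean: float = 50.0
    background_sd: float = 10.0
    plaques: list[PlaqueSpec] = field(default_factory=list)
    diffuse_amplitude: float = 0.0  # smooth low-frequency background modulation
    seed: int = 0


def simulate_section_image(params: ImageParams
                           ) -> tuple[SectionImage, dict]:
    """Gaussian background (clipped at 0) with programmed plaque profiles.

    Truth lists each plaque's center, radius, disc area, and whether any two
    plaques overlap (flagged, not forbidden).
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    img = rng.normal(params.background_mean, params.background_sd, size=(h, w))
    if params.diffuse_amplitude > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        phase = rng.uniform(0, 2 * np.pi, size=2)
        img += params.diffuse_amplitude * (
            np.sin(2 * np.pi * xx / w + phase[0]) * np.sin(2 * np.pi * yy / h + phase[1]))
    yy, xx = np.mgrid[0:h, 0:w]
    truth_plaques = []
    for pl in params.plaques:
        cy, cx = pl.center_px
        r_px = pl.radius_um / params.pixel_size_um
        if not (0 <= cy < h and 0 <= cx < w) or r_px <= 0:
            raise ValueError(f"plaque at {pl.center_px} outside image or r <= 0")
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        if pl.profile == "disc":
            img[d2 <= r_px ** 2] += pl.peak_intensity
        elif pl.profile == "gaussian":
            sigma = r_px / 2.0
            img += pl.peak_intensity * np.exp(-d2 / (2 * sigma ** 2))
        else:
            raise ValueError(f"unknown plaque profile {pl.profile!r}")
        truth_plaques.append({
            "center_px": (cy, cx), "radius_um": pl.radius_um,
            "area_um2": np.pi * pl.radius_um ** 2,
            "equivalent_diameter_um": 2.0 * pl.radius_um,
            "profile": pl.profile})
    overlap = False
    for i in range(len(params.plaques)):
        for j in range(i + 1, len(params.plaques)):
            a, b = params.plaques[i], params.plaques[j]
            dist = np.hypot(a.center_px[0] - b.center_px[0],
                            a.center_px[1] - b.center_px[1]) * params.pixel_size_um
            if dist < a.radius_um + b.radius_um:
                overlap = True
    img = np.clip(img, 0.0, None)
    image = SectionImage(pixels=img, pixel_size_um=params.pixel_size_um)
    return image, {"plaques": truth_plaques, "overlapping": overlap,
                   "background_mean": params.background_mean,
                   "background_sd": params.background_sd}


def simulate_image_cohort(groups: dict[str, dict], n_per_group: int = 5,
                          seed: int = 0) -> tuple[list[SectionImage], pd.DataFrame]:
    """Small per-group image sets with programmed intensity factors.

    ``groups`` maps group label -> overrides of :class:`ImageParams` fields
    (e.g. ``{"background_mean": 25.0}`` for a 0.5x intensity group).
    """
    rng = np.random.default_rng(seed)
    images, rows = [], []
    for label, overrides in groups.items():
        for i in range(n_per_group):
            params = ImageParams(seed=int(rng.integers(2 ** 31)), **overrides)
            img, truth = simulate_section_image(params)
            img.subject_id = f"{label}-{i + 1}"
            images.append(img)
            rows.append({"subject_id": img.subject_id, "group": label,
                         "background_mean": params.background_mean,
                         "n_plaques_true": len(truth["plaques"])})
    return images, pd.DataFrame(rows)
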