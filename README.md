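# chronopheno

Quantitative phenotyping for mouse chronotherapy studies: circadian
wheel-running analysis, cognitive-affective behavioral scoring, fluorescence
histology quantification, and the accompanying group statistics — all driven
by ground-truth simulators so every estimator in the pipeline is verifiable
without animal data.

The package is aimed at circadian/behavioral-neuroscience labs analyzing
wheel-running experiments in models of Alzheimer's disease (e.g. APP-PS1 mice
under CK1δ/ε-inhibitor dosing), where the endpoints are: the free-running
period τ, rhythm amplitude and fragmentation, sleep timing, a behavioral
battery, and amyloid/PER1 immunofluorescence.

## What it computes

**Circadian** (`chronopheno.circadian`), on wheel counts in 5-min bins:

- **χ² periodogram**: for a candidate period of *p* bins folded over *K*
  cycles, Q<sub>p</sub> = K·N′·Σ<sub>h</sub>(M<sub>h</sub>−M̄)² /
  Σ<sub>i</sub>(x<sub>i</sub>−M̄)² with N′ = K·p; τ is the candidate
  maximizing the excess of Q<sub>p</sub> over a Bonferroni-corrected
  significance line. Q<sub>p</sub> is asymptotically χ²(p−1) under the null;
  the line uses the exact finite-cycle quantile
  Q<sub>p</sub>/N′ ~ Beta((p−1)/2, (N′−p)/2), and all candidates are folded
  with a common K (see `docs/methods.md` for why both choices matter).
- **Interdaily stability** IS = N·Σ<sub>h</sub>(x̄<sub>h</sub>−x̄)² /
  (24·Σ<sub>i</sub>(x<sub>i</sub>−x̄)²) and **intradaily variability**
  IV = N·Σ(x<sub>i</sub>−x<sub>i−1</sub>)² / ((N−1)·Σ(x<sub>i</sub>−x̄)²) on
  hourly counts (IS = 1 for identical days; IV ≈ 2 for white noise).
- **Activity onsets** by ±6-h step-template matching; **sleep offsets** by the
  rule "first run of ≥3 consecutive hours each below 20% of the active-phase
  mean hourly counts"; **naps/bouts** as runs of ≥2 consecutive 30-min bins
  without/with activity in the active/rest phase; **peak 4-h activity** in
  counts/min and its percent decline from baseline.

**Behavior** (`chronopheno.behavior`): Y-maze triad alternation (% of
3-entry windows visiting all three arms), freezing (still runs ≥ 2 s),
forced-swim immobility latency and post-2-min immobility, zone occupancy and
boundary crossings, sociability/novelty preference.

**Histology** (`chronopheno.histology`): plaques segmented at mean + 1 SD of
the cropped section, kept when well circumscribed (circularity ≥ 0.4, area
≥ 50 μm²); per-subject size = equivalent diameters (2·√(area/π)) of the 3
largest plaques; percent area above threshold; intensity normalized to a
reference group.

**Statistics** (`chronopheno.stats`): the study pipeline — single-pass 2-SD
outlier exclusion, Shapiro-Wilk, Levene, then one-way ANOVA or mixed
(genotype × dose between, baseline/treatment within) repeated-measures
ANOVA, with Tukey HSD only after a significant omnibus; reported in the
`F(df1,df2) = x, p < y` format.

**Simulators** (`chronopheno.simulate`): Poisson-count actograms with
configurable τ, duty cycle, amplitude decay, onset jitter, injected naps and
light masking; Markov behavior traces; plaque images over noisy background —
each returning the ground truth the scorers are tested against. The default
cohort preset programs the study structure: τ 23.69 h (APP-PS1) vs 23.95 h
(nTg), treatment lengthening, 61% vs ~43% activity decline, and a 2.5-h
sleep-offset delay at the high dose.

## Worked example

```python
from chronopheno.simulate import ActogramParams, simulate_actogram
from chronopheno.circadian import chi_squared_periodogram

rec, truth = simulate_actogram(ActogramParams(
    tau_h=23.7, days=11, nap_prob_per_30min=0.1, onset_jitter_sd_h=0.25, seed=3))
res = chi_squared_periodogram(rec)
print(f"tau = {res.peak_period_h:.3f} h (true {truth.tau_h} h), "
      f"amplitude (Qp excess) = {res.peak_excess:.0f}")
```

prints

```
tau = 23.667 h (true 23.7 h), amplitude (Qp excess) = 1603
```

i.e. the period of the 11-day DD record is recovered to the 5-min grid
(±0.033 h here), and the peak clears the significance line by a wide margin —
a strongly rhythmic record.

The full analysis is a chain of numbered drivers:

```bash
python analysis/01_simulate_cohort.py      # default cohort -> results/data/
python analysis/02_circadian_analysis.py   # metrics + mixed RM ANOVA report
python analysis/03_behavior_battery.py     # battery + one-way ANOVA/Tukey
python analysis/04_histology_quant.py      # plaques/intensity + ANOVA/Tukey
python analysis/05_method_validation.py    # quick estimator calibration
```

On the default simulated cohort (seed 0, n = 8/group), the circadian report
includes, for the period metric:

```
genotype: F(1,41) = 18.12, p < 0.001
phase: F(1,41) = 374.67, p < 0.001
phase:dose: F(2,41) = 92.65, p < 0.001
```

— the programmed genotype period difference, the treatment-phase lengthening,
and its dose dependence, recovered end to end from raw simulated counts. The
same commands accept real data in the canonical CSV format (see
`chronopheno simulate --help` for the layout).

A `chronopheno` CLI wraps the same stages
(`simulate | circadian | behavior | histology | stats | report`).

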