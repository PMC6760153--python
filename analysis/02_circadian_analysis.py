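"""Circadian analysis of the simulated cohort.

Per subject and phase: chi-squared periodogram period and amplitude, IS/IV,
activity-onset detection, the 20%/3-h sleep-offset rule, 30-min nap/bout
scoring, and peak 4-h activity — followed by the study's mixed
(genotype x dose, baseline vs treatment) repeated-measures statistics with
Tukey post-hoc tests. Reads results/data if 01_simulate_cohort.py was run,
otherwise simulates in memory.
"""

import sys
from pathlib import Path

from chronopheno.pipeline import RunConfig, run_circadian

DATA = Path("results/data")


def main(seed: int = 0) -> None:
    cfg = RunConfig(output_dir=Path("results/circadian"), seed=seed,
                    data_dir=DATA if (DATA / "manifest.csv").exists() else None)
    tidy, report = run_circadian(cfg)
    print(report)
    print(f"\nwrote {cfg.output_dir}/circadian_metrics.csv "
          f"({tidy.subject_id.nunique()} subjects, {tidy.metric.nunique()} metrics)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
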