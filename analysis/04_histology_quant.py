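"""Fluorescence-histology quantification of simulated sections.

Simulates per-group section images (plaque-laden APP-PS1 vehicle sections,
treatment-reduced burden, clean nontransgenic background), applies the
mean+1SD plaque segmentation with the circumscription filter, and reports
intensity (normalized to the nTg vehicle group), percent area, plaque counts
and top-3 plaque diameters with one-way ANOVA + Tukey statistics.
"""

import sys
from pathlib import Path

from chronopheno.pipeline import RunConfig, run_histology


def main(seed: int = 0) -> None:
    cfg = RunConfig(output_dir=Path("results/histology"), seed=seed)
    _, report = run_histology(cfg)
    print(report)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
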