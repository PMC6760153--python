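"""Behavioral battery of the simulated treatment groups.

Simulates the 4-group design (nTg vehicle, APP-PS1 vehicle/10/30 mg/kg) with
programmed deficits and rescues, scores Y-maze alternation, fear-conditioning
freezing, forced-swim immobility, open-field zones, and sociability, then runs
one-way ANOVA with Tukey post-hoc tests per endpoint.
"""

import sys
from pathlib import Path

from chronopheno.pipeline import RunConfig, run_behavior


def main(seed: int = 0) -> None:
    cfg = RunConfig(output_dir=Path("results/behavior"), seed=seed)
    _, report = run_behavior(cfg)
    print(report)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
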