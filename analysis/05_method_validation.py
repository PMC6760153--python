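"""Scaled-down method validation (the full version is scripts/acceptance.py).

Quick checks that the estimators are calibrated on simulated ground truth:
period recovery across tau in [23, 25] h, periodogram false-positive rate on
rhythm-free records, and plaque-detector false positives on pure-noise images.
"""

import sys
from datetime import datetime

import numpy as np

from chronopheno.actogram import ActivityRecord
from chronopheno.circadian import chi_squared_periodogram
from chronopheno.histology import detect_plaques
from chronopheno.simulate import ActogramParams, ImageParams, simulate_actogram, simulate_section_image


def main(seed: int = 0) -> None:
    rng = np.random.default_rng(seed)
    errs = []
    for i in range(40):
        tau = float(rng.uniform(23.0, 25.0))
        rec, _ = simulate_actogram(ActogramParams(
            tau_h=tau, days=11, nap_prob_per_30min=0.1, onset_jitter_sd_h=0.25,
            seed=int(rng.integers(2 ** 31))))
        errs.append(abs(chi_squared_periodogram(rec).peak_period_h - tau))
    errs = np.array(errs)
    print(f"period recovery: {100 * np.mean(errs <= 0.1):.0f}% within 0.1 h "
          f"(max error {errs.max():.3f} h, n=40)")

    hits = 0
    for i in range(100):
        counts = rng.poisson(10.0, 11 * 288)
        rec = ActivityRecord("null", datetime(2024, 1, 1), 5, counts)
        hits += chi_squared_periodogram(rec).any_significant
    print(f"periodogram false-positive rate on rhythm-free records: {hits}/100")

    fp = 0
    for i in range(50):
        img, _ = simulate_section_image(ImageParams(seed=int(rng.integers(2 ** 31))))
        fp += len(detect_plaques(img)) > 0
    print(f"plaque false positives on pure-noise images: {fp}/50")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
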