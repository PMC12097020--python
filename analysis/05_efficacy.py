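#!/usr/bin/env python
"""Efficacy and culture-health metrics on simulated co-culture readouts.

Builds a dual-stain co-culture label table with known per-condition killing
probabilities, recovers the killing fractions per condition x timepoint,
fits the organoid diameter -> cell-count power law on noisy synthetic
calibration data, computes relative growth curves, and reports the culture
success rate and GvHD score range.

Writes results/05_killing.tsv and results/05_calibration.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from covpanel import (
    diameter_count_fit,
    growth_curve,
    gvhd_score,
    killing_fraction,
    success_rate,
)

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results"

# Per-condition true killing probability of a tumor cell, by timepoint (h).
KILL_PROBS = {
    ("control", 24.0): 0.05,
    ("control", 48.0): 0.08,
    ("CAR_single", 24.0): 0.35,
    ("CAR_single", 48.0): 0.55,
    ("CAR_dual", 24.0): 0.60,
    ("CAR_dual", 48.0): 0.85,
}


def simulate_labels(rng: np.random.Generator, n_tumor=600, n_bystander=150):
    rows = []
    for (cond, tp), p in KILL_PROBS.items():
        for i in range(n_tumor):
            rows.append((f"{cond}_{tp}_t{i}", 1, int(rng.random() < p), cond, tp))
        for i in range(n_bystander):
            rows.append((f"{cond}_{tp}_b{i}", 0, int(rng.random() < 0.1), cond, tp))
    return pd.DataFrame(
        rows, columns=["cell_id", "tumor_stain", "death_stain", "condition",
                       "timepoint_h"]
    )


def main() -> None:
    rng = np.random.default_rng(SEED)
    labels = simulate_labels(rng)
    kill_rows = [
        {
            "condition": cond,
            "timepoint_h": tp,
            "true_pct": 100 * p,
            "measured_pct": round(killing_fraction(labels, cond, tp), 2),
        }
        for (cond, tp), p in KILL_PROBS.items()
    ]
    kill_df = pd.DataFrame(kill_rows)

    d = rng.uniform(150, 1000, 40)
    counts = 0.0012 * d**3 * rng.lognormal(0.0, 0.08, 40)
    fit = diameter_count_fit(d, counts)
    calib = pd.DataFrame(
        [{"a": fit.a, "b": round(fit.b, 4), "r_squared": round(fit.r_squared, 4),
          "n_pairs": 40}]
    )

    growth = growth_curve(
        pd.DataFrame(
            {
                "spheroid_id": ["g1"] * 4 + ["g2"] * 4,
                "day": [0, 7, 14, 21] * 2,
                "diameter_um": [520, 600, 705, 830, 610, 640, 700, 790],
            }
        )
    )

    OUT.mkdir(exist_ok=True)
    kill_df.to_csv(OUT / "05_killing.tsv", sep="\t", index=False)
    calib.to_csv(OUT / "05_calibration.tsv", sep="\t", index=False)
    print(kill_df.to_string(index=False))
    print()
    print(calib.to_string(index=False))
    print()
    print(growth.to_string(index=False))
    print(
        f"\nMeasured killing tracks the generative probabilities (dual-target "
        f"CAR at 48 h: {kill_df.iloc[-1]['measured_pct']:.1f}% vs 85% true); "
        f"bystander cells never enter the fractions. Calibration recovers a "
        f"near-cubic exponent b = {fit.b:.3f}. Culture success rate "
        f"{success_rate(23, 26):.2f}% (23/26); GvHD score spans "
        f"{gvhd_score([0]*5).total}-{gvhd_score([2]*5).total}."
    )


if __name__ == "__main__":
    main()
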