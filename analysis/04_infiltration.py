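#!/usr/bin/env python
"""Quantify T-cell infiltration geometry and movement in organoid co-culture.

Compares the concentric-ring infiltration profile of a fully infiltrating
(uniform) T-cell population against a rim-excluded one, then summarizes
simulated 24-hour T-cell tracks by total path length and groups them into
50-µm distance bins.

Writes results/04_ring_profiles.tsv and results/04_distance_groups.tsv.
"""

from pathlib import Path

import pandas as pd

from covpanel import (
    SimConfig,
    distance_group_proportions,
    movement_distances,
    ring_infiltration_profile,
    ring_profile_table,
    simulate_spatial_organoid,
    simulate_trajectories,
)

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    frames = []
    for mode in ("uniform", "rim"):
        cfg = SimConfig(seed=SEED, cells_per_patient=3000, t_cell_count=3000,
                        spatial_radius_um=400.0, t_cell_mode=mode)
        profiles = ring_infiltration_profile(
            simulate_spatial_organoid(cfg), seed=SEED
        )
        df = ring_profile_table(profiles)
        df.insert(0, "mode", mode)
        frames.append(df)
    rings = pd.concat(frames, ignore_index=True)

    cfg = SimConfig(seed=SEED, t_cell_count=1000, n_timepoints=49,
                    walk_step_sd_um=2.0)
    dist = movement_distances(simulate_trajectories(cfg))
    groups = distance_group_proportions(
        dist["path_length_um"], [0, 50, 100, 150, 200]
    )

    OUT.mkdir(exist_ok=True)
    rings.to_csv(OUT / "04_ring_profiles.tsv", sep="\t", index=False)
    groups.to_csv(OUT / "04_distance_groups.tsv", sep="\t", index=False)
    print(rings.to_string(index=False))
    print()
    print(groups.to_string(index=False))
    u = rings[rings["mode"] == "uniform"]["mean_t_cell_proportion"]
    r = rings[rings["mode"] == "rim"]
    inner_rim = r[r["ring_index"] < 4]["mean_t_cell_proportion"].mean()
    print(
        f"\nUniform co-culture: ring proportions flat at ~{u.mean():.2f} "
        f"(range {u.min():.2f}-{u.max():.2f}). Rim-excluded co-culture: inner "
        f"rings drop to ~{inner_rim:.2f}, the signature of failed "
        f"infiltration. Median 24-h path length "
        f"{dist['path_length_um'].median():.1f} µm vs net displacement "
        f"{dist['net_displacement_um'].median():.1f} µm."
    )


if __name__ == "__main__":
    main()
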