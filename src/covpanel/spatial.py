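"""Organoid infiltration geometry and T-cell trajectory analysis.

Infiltration is quantified region-wise: concentric rings are tiled outward
from the organoid center (the tumor-cell centroid) at a fixed interval
(default 50 µm); on each ring's mid-radius circle, probe circles of fixed
diameter (default 50 µm) are dropped at seeded-uniform angles and the T-cell
proportion inside each probe is recorded. Trajectories are summarized by
total path length (sum of Euclidean step lengths; net displacement is also
reported) and grouped into left-closed/right-open distance bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, InputError
from .synthetic import T_CELL, TUMOR


@dataclass
class RingProfile:
    """Probe-circle T-cell proportions for one concentric ring."""

    ring_index: int
    inner_um: float
    outer_um: float
    probe_proportions: np.ndarray  # one value per probe circle
    probe_empty: np.ndarray  # True where a probe contained no cells
    n_probes: int
    seed: int

    @property
    def mean_proportion(self) -> float:
        return float(self.probe_proportions.mean())


def organoid_center(table: pd.DataFrame) -> tuple[float, float]:
    """Center of the organoid: arithmetic centroid of tumor-class cells."""
    tumor = table[table["class"] == TUMOR]
    if tumor.empty:
        raise InputError("cannot locate organoid center: no tumor-class cells")
    return float(tumor["x"].mean()), float(tumor["y"].mean())


def ring_infiltration_profile(
    table: pd.DataFrame,
    interval_um: float = 50.0,
    probe_diameter_um: float = 50.0,
    n_probes_per_ring: int = 8,
    seed: int = 0,
) -> list[RingProfile]:
    """Concentric-ring T-cell infiltration profile of a co-culture image.

    Rings of width ``interval_um`` are tiled from the center out to the
    maximum tumor-cell radius. For each ring, ``n_probes_per_ring`` probe
    circles of diameter ``probe_diameter_um`` are centered at seeded-uniform
    angles on the ring's mid-radius circle; each probe reports
    (T cells inside) / (all cells inside), 0 when the probe is empty (the
    emptiness is flagged rather than dropped so ring means stay defined at
    sparse rims). Deterministic given ``seed``.
    """
    if interval_um <= 0 or probe_diameter_um <= 0:
        raise ConfigurationError("interval and probe diameter must be positive")
    if n_probes_per_ring < 1:
        raise ConfigurationError("need at least one probe per ring")
    cx, cy = organoid_center(table)
    xy = table[["x", "y"]].to_numpy(dtype=float)
    is_t = (table["class"] == T_CELL).to_numpy()
    tumor_r = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)[
        (table["class"] == TUMOR).to_numpy()
    ]
    max_r = float(tumor_r.max())
    # Tile rings outward while the ring's mid-radius (where probe circles are
    # centered) still lies within the tumor extent, so probes are never
    # centered beyond the organoid.
    n_rings = max(1, int(np.floor(max_r / interval_um + 0.5)))

    tree = cKDTree(xy)
    rng = np.random.default_rng(seed)
    probe_radius = probe_diameter_um / 2.0
    profiles: list[RingProfile] = []
    for ring in range(n_rings):
        inner, outer = ring * interval_um, (ring + 1) * interval_um
        mid = (inner + outer) / 2.0
        angles = rng.uniform(0.0, 2.0 * np.pi, n_probes_per_ring)
        centers = np.column_stack(
            [cx + mid * np.cos(angles), cy + mid * np.sin(angles)]
        )
        props = np.zeros(n_probes_per_ring)
        empty = np.zeros(n_probes_per_ring, dtype=bool)
        for j, hit in enumerate(tree.query_ball_point(centers, probe_radius)):
            if not hit:
                empty[j] = True
                continue
            hit = np.asarray(hit)
            props[j] = is_t[hit].sum() / hit.size
        profiles.append(
            RingProfile(
                ring_index=ring,
                inner_um=inner,
                outer_um=outer,
                probe_proportions=props,
                probe_empty=empty,
                n_probes=n_probes_per_ring,
                seed=seed,
            )
        )
    return profiles


def ring_profile_table(profiles: list[RingProfile]) -> pd.DataFrame:
    """Tidy per-ring summary of an infiltration profile."""
    return pd.DataFrame(
        {
            "ring_index": [p.ring_index for p in profiles],
            "inner_um": [p.inner_um for p in profiles],
            "outer_um": [p.outer_um for p in profiles],
            "mean_t_cell_proportion": [p.mean_proportion for p in profiles],
            "n_probes": [p.n_probes for p in profiles],
            "n_empty_probes": [int(p.probe_empty.sum()) for p in profiles],
        }
    )


def movement_distances(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Per-cell movement summary from a time-lapse track table.

    Returns one row per cell with ``path_length_um`` (sum of Euclidean step
    lengths over consecutive timepoints — the headline statistic) and
    ``net_displacement_um`` (straight-line start-to-end distance). Cells
    with a single timepoint are excluded with a warning and listed in the
    ``excluded`` attribute of the returned frame.
    """
    required = {"cell_id", "time_h", "x", "y"}
    missing = required - set(trajectories.columns)
    if missing:
        raise InputError(f"trajectory table missing columns: {sorted(missing)}")
    df = trajectories.sort_values(["cell_id", "time_h"], kind="stable")
    counts = df.groupby("cell_id", sort=True).size()
    excluded = counts[counts < 2].index.tolist()
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} single-timepoint cells: {excluded[:5]}..."
        )
        df = df[~df["cell_id"].isin(excluded)]
    if df.empty:
        raise InputError("no cells with >= 2 timepoints")

    rows = []
    for cid, g in df.groupby("cell_id", sort=True):
        dx = np.diff(g["x"].to_numpy())
        dy = np.diff(g["y"].to_numpy())
        steps = np.hypot(dx, dy)
        rows.append(
            {
                "cell_id": cid,
                "path_length_um": float(steps.sum()),
                "net_displacement_um": float(
                    np.hypot(
                        g["x"].iloc[-1] - g["x"].iloc[0],
                        g["y"].iloc[-1] - g["y"].iloc[0],
                    )
                ),
                "n_timepoints": len(g),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out


def distance_group_proportions(
    distances, bin_edges
) -> pd.DataFrame:
    """Proportion of cells per movement-distance group.

    Bins are left-closed/right-open on the given strictly increasing edges,
    with a final open-ended bin above the last edge; proportions sum to 1
    over the provided distances.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise InputError("empty distance list")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 1 or np.any(np.diff(edges) <= 0):
        raise InputError("bin edges must be strictly increasing")
    if np.any(d < edges[0]):
        raise InputError("distances below the first bin edge; extend the edges")
    full_edges = np.concatenate([edges, [np.inf]])
    counts, _ = np.histogram(d, bins=full_edges)
    labels = [
        f"[{full_edges[i]:g}, {full_edges[i + 1]:g})" for i in range(len(counts))
    ]
    return pd.DataFrame(
        {
            "group": labels,
            "count": counts,
            "proportion": counts / d.size,
        }
    )
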