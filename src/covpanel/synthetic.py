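"""Synthetic cohort generator with known ground truth.

Real patient single-cell, imaging and organoid data for this problem are not
publicly shared, so every downstream stage (QC, positivity calling, panel
coverage, infiltration geometry) is exercised against cohorts simulated here
with a fully known generative state: per-patient mixtures of malignant
subclones with distinct antigen-positivity probabilities, count noise with
dropout, planted QC-violating cells, disc-shaped organoid cell placements,
and Gaussian random-walk T-cell trajectories.

Model summary
-------------
* A patient is a mixture of ``subclones_per_patient`` subclones (Dirichlet or
  user-given weights). Within a subclone, antigen positivities are
  independent Bernoulli draws, which gives the closed-form expected panel
  coverage ``sum_s w_s * (1 - prod_a (1 - p_sa))`` used as the oracle.
* A truly positive antigen transcript survives dropout with probability
  ``1 - dropout_rate``; surviving transcripts are counted as
  ``1 + Poisson(2)`` so a surviving positive is never a zero count.
* Background genes are detected per-cell at a rate targeting a realistic
  detected-gene count; per-cell library size is lognormal around
  ``mean_library_size`` and spread over detected genes.
* QC violators are planted explicitly (high mito fraction, too few or too
  many detected genes) and their identities recorded in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import SimConfig
from .errors import ConfigurationError

TUMOR = "tumor"
T_CELL = "t_cell"
CLASS_VOCAB = (TUMOR, T_CELL, "other")

# Planted-violator draw ranges; non-violators are kept well inside the QC
# boundaries so the planted set is exactly the removed set.
_VIOL_MITO = (0.25, 0.60)
_NORMAL_MITO = (0.0, 0.15)
_VIOL_LOW_GENES = (20, 150)
_VIOL_HIGH_GENES = (2650, 2900)
_SAFE_GENE_BAND = (260, 2380)
_ANTIGEN_COUNT_MEAN = 3.0  # mean transcript count of a surviving positive
_LIBRARY_SIGMA = 0.35  # lognormal sigma of per-cell library size
_CHUNK = 2048


def _patient_id(i: int) -> str:
    return f"P{i + 1:02d}"


@dataclass
class GroundTruth:
    """Generative state of a simulated cohort.

    Holds, per patient: the subclone id of every cell, the true
    antigen-positivity flags (pre-dropout), the planted QC violators, and
    the mixture parameters needed for closed-form expected coverage.
    """

    antigens: list[str]
    weights: np.ndarray  # (n_patients, n_subclones)
    probs: np.ndarray  # (n_patients, n_subclones, n_antigens)
    subclone: dict[str, np.ndarray] = field(default_factory=dict)
    flags: dict[str, pd.DataFrame] = field(default_factory=dict)
    qc_violators: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.flags)

    def expected_coverage(self, panel, patient: str | int) -> float:
        """Closed-form expected union coverage of ``panel`` for one patient.

        Under within-subclone independence the chance a subclone-``s`` cell
        is positive for at least one panel antigen is
        ``1 - prod_a (1 - p_sa)``; mixing over subclone weights gives the
        patient-level expectation.
        """
        panel = list(panel)
        if isinstance(patient, str):
            patient = self.patient_ids.index(patient)
        idx = [self.antigens.index(a) for a in panel]
        p = self.probs[patient][:, idx]  # (n_subclones, k)
        per_subclone = 1.0 - np.prod(1.0 - p, axis=1)
        return float(self.weights[patient] @ per_subclone)

    def empirical_coverage(self, panel, patient: str) -> float:
        """Union coverage of the true flags (no noise) for one patient."""
        f = self.flags[patient][list(panel)]
        return float(f.any(axis=1).mean())


def _simulate_patient(
    config: SimConfig,
    patient_index: int,
    weights: np.ndarray,
    probs: np.ndarray,
) -> tuple[ad.AnnData, np.ndarray, pd.DataFrame, pd.DataFrame]:
    rng = config.patient_rng(patient_index)
    pid = _patient_id(patient_index)
    n_cells = config.cells_per_patient
    antigens = list(config.antigens)
    n_ant = len(antigens)
    n_bg = config.n_background_genes

    barcodes = np.array([f"{pid}_C{i + 1:05d}" for i in range(n_cells)])
    subclone = rng.choice(len(weights), size=n_cells, p=weights)
    flags = rng.random((n_cells, n_ant)) < probs[subclone]  # true positivity
    dropped = rng.random((n_cells, n_ant)) < config.dropout_rate
    observed = flags & ~dropped

    # Antigen-gene counts: a surviving positive is 1 + Poisson so it can
    # never drop to zero except through the modeled dropout itself.
    ant_counts = np.zeros((n_cells, n_ant), dtype=np.int32)
    ant_counts[observed] = 1 + rng.poisson(_ANTIGEN_COUNT_MEAN - 1.0, observed.sum())

    # Plant QC violators.
    n_viol = int(round(config.frac_qc_violators * n_cells))
    if n_viol > 0 and n_bg < 600:
        raise ConfigurationError(
            "planting QC violators needs n_background_genes >= 600"
        )
    rules = ["high_mito", "low_genes"]
    if n_bg >= _VIOL_HIGH_GENES[1]:
        rules.append("high_genes")
    viol_idx = rng.choice(n_cells, size=n_viol, replace=False)
    viol_rule = np.array([rules[i % len(rules)] for i in range(n_viol)])

    mito = rng.uniform(*_NORMAL_MITO, size=n_cells)
    target = rng.normal(config.genes_detected_mean, config.genes_detected_sd, n_cells)
    if n_viol > 0:
        lo, hi = _SAFE_GENE_BAND
        target = np.clip(target, lo, min(hi, n_bg))
        mito[viol_idx[viol_rule == "high_mito"]] = rng.uniform(
            *_VIOL_MITO, size=int((viol_rule == "high_mito").sum())
        )
        low = viol_idx[viol_rule == "low_genes"]
        target[low] = rng.integers(*_VIOL_LOW_GENES, size=low.size)
        high = viol_idx[viol_rule == "high_genes"]
        target[high] = rng.integers(*_VIOL_HIGH_GENES, size=high.size)
    target = np.clip(target, 1, n_bg)

    # Library size spread over detected background genes.
    mean_log = np.log(config.mean_library_size) - _LIBRARY_SIGMA**2 / 2
    library = rng.lognormal(mean_log, _LIBRARY_SIGMA, size=n_cells)
    per_gene_extra = np.maximum(library / target - 1.0, 0.0)

    rows, cols, vals = [], [], []
    p_detect = target / n_bg
    for start in range(0, n_cells, _CHUNK):
        stop = min(start + _CHUNK, n_cells)
        mask = rng.random((stop - start, n_bg)) < p_detect[start:stop, None]
        r, c = np.nonzero(mask)
        rows.append(r + start)
        cols.append(c)
        vals.append(1 + rng.poisson(per_gene_extra[start:stop][r]))
    bg = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_cells, n_bg),
        dtype=np.int32,
    ).tocsr()

    X = sp.hstack([sp.csr_matrix(ant_counts), bg], format="csr", dtype=np.int32)
    gene_names = [config.antigen_gene_map[a] for a in antigens] + [
        f"BG{i + 1:05d}" for i in range(n_bg)
    ]
    var = pd.DataFrame(
        {"antigen": antigens + [""] * n_bg}, index=pd.Index(gene_names, name="gene")
    )
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    rule_col = np.full(n_cells, "", dtype=object)
    rule_col[viol_idx] = viol_rule
    obs = pd.DataFrame(
        {
            "patient": pid,
            "subclone": subclone,
            "mito_fraction": mito,
            "detected_genes": detected,
            "malignant": True,
            "planted_qc_violation": rule_col,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    adata = ad.AnnData(X=X, obs=obs, var=var)

    flags_df = pd.DataFrame(flags, index=obs.index, columns=antigens)
    viol_df = pd.DataFrame(
        {"barcode": barcodes[viol_idx], "rule": viol_rule}
    ).sort_values("barcode", ignore_index=True)
    return adata, subclone, flags_df, viol_df


def simulate_cohort(config: SimConfig) -> tuple[dict[str, ad.AnnData], GroundTruth]:
    """Simulate a cohort of per-patient count matrices with ground truth.

    Returns
    -------
    cohort
        ``patient id -> AnnData`` with integer counts in ``X`` (antigen genes
        first, then background genes), per-cell metadata in ``obs``
        (``mito_fraction``, ``detected_genes``, ``subclone``, ``malignant``,
        ``planted_qc_violation``).
    truth
        :class:`GroundTruth` with true flags, subclone ids, planted QC
        violators and closed-form expected coverages.
    """
    weights = config.resolved_weights()
    probs = config.resolved_probs()
    truth = GroundTruth(antigens=list(config.antigens), weights=weights, probs=probs)
    cohort: dict[str, ad.AnnData] = {}
    for i in range(config.n_patients):
        adata, subclone, flags_df, viol_df = _simulate_patient(
            config, i, weights[i], probs[i]
        )
        pid = _patient_id(i)
        cohort[pid] = adata
        truth.subclone[pid] = subclone
        truth.flags[pid] = flags_df
        truth.qc_violators[pid] = viol_df
    return cohort, truth


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _rim_annulus(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    # Uniform in the annulus [0.8 R, R]: area-uniform radius in r^2.
    r2 = rng.uniform(0.64, 1.0, n) * radius**2
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([np.sqrt(r2) * np.cos(theta), np.sqrt(r2) * np.sin(theta)])


def simulate_spatial_organoid(config: SimConfig) -> pd.DataFrame:
    """Simulate an organoid/T-cell co-culture cell table.

    Tumor cells are placed uniformly in a disc of ``spatial_radius_um``; T
    cells either uniformly in the same disc (``t_cell_mode="uniform"``,
    emulating full infiltration) or concentrated in the outer rim
    (``"rim"``, emulating exclusion). Tumor cells carry per-antigen marker
    intensities drawn from the patient-1 mixture, so the spatial positivity
    caller can be exercised on the same ground truth.
    """
    rng = config.spatial_rng()
    n_tumor = config.cells_per_patient
    tumor_xy = _uniform_disc(rng, n_tumor, config.spatial_radius_um)
    if config.t_cell_mode == "uniform":
        t_xy = _uniform_disc(rng, config.t_cell_count, config.spatial_radius_um)
    else:
        t_xy = _rim_annulus(rng, config.t_cell_count, config.spatial_radius_um)

    weights = config.resolved_weights()[0]
    probs = config.resolved_probs()[0]
    subclone = rng.choice(len(weights), size=n_tumor, p=weights)
    pos = rng.random((n_tumor, len(config.antigens))) < probs[subclone]
    # Positive markers: bright lognormal signal; negatives: faint background.
    intens = np.abs(rng.normal(0.0, 1.0, pos.shape))
    intens[pos] = rng.lognormal(np.log(50.0), 0.4, int(pos.sum()))

    n = n_tumor + config.t_cell_count
    table = pd.DataFrame(
        {
            "id": [f"S{i + 1:06d}" for i in range(n)],
            "x": np.concatenate([tumor_xy[:, 0], t_xy[:, 0]]),
            "y": np.concatenate([tumor_xy[:, 1], t_xy[:, 1]]),
            "class": [TUMOR] * n_tumor + [T_CELL] * config.t_cell_count,
        }
    )
    for j, a in enumerate(config.antigens):
        col = np.zeros(n)
        col[:n_tumor] = intens[:, j]
        table[f"intensity_{a}"] = col
    return table


def simulate_trajectories(config: SimConfig) -> pd.DataFrame:
    """Simulate 24-hour T-cell tracks as isotropic Gaussian random walks.

    Each of ``t_cell_count`` cells starts uniformly in the organoid disc and
    takes ``n_timepoints - 1`` steps with per-axis SD ``walk_step_sd_um``.
    Returns a long table (cell_id, time_h, x, y), time strictly increasing
    within each cell.
    """
    if config.n_timepoints < 2:
        raise ConfigurationError("n_timepoints must be >= 2")
    rng = config.trajectory_rng()
    n = config.t_cell_count
    T = config.n_timepoints
    start = _uniform_disc(rng, n, config.spatial_radius_um)
    steps = rng.normal(0.0, config.walk_step_sd_um, size=(n, T - 1, 2))
    paths = np.concatenate(
        [start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)], axis=1
    )
    time_h = np.linspace(0.0, 24.0, T)
    return pd.DataFrame(
        {
            "cell_id": np.repeat([f"T{i + 1:05d}" for i in range(n)], T),
            "time_h": np.tile(time_h, n),
            "x": paths[:, :, 0].ravel(),
            "y": paths[:, :, 1].ravel(),
        }
    )
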