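"""Simulation and run configuration.

``SimConfig`` fully parameterizes a synthetic patient cohort: every output of
the generator modules is a pure function of it (the single ``seed`` drives
independent per-purpose substreams, so e.g. adding a patient never perturbs
the cells simulated for earlier patients).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import ConfigurationError

#: Curated candidate CAR antigens for glioblastoma ("target bank"),
#: in canonical lexicographic order.
DEFAULT_TARGET_BANK: tuple[str, ...] = (
    "B7-H3",
    "CD133",
    "CD70",
    "EGFR",
    "EphA2",
    "GD2",
    "Her2",
    "IL-13Ra2",
    "NKG2DL",
)

#: Default antigen -> RNA gene symbol map. GD2 is a ganglioside and is proxied
#: by its synthase gene ST8SIA1; NKG2DL is a ligand family proxied by MICA.
DEFAULT_ANTIGEN_GENE_MAP: dict[str, str] = {
    "B7-H3": "CD276",
    "CD133": "PROM1",
    "CD70": "CD70",
    "EGFR": "EGFR",
    "EphA2": "EPHA2",
    "GD2": "ST8SIA1",
    "Her2": "ERBB2",
    "IL-13Ra2": "IL13RA2",
    "NKG2DL": "MICA",
}

# Named RNG substream keys (spawn_key prefixes) so each generator purpose has
# an independent, reorder-stable stream.
_STREAM_PATIENT = 0
_STREAM_PARAMS = 1
_STREAM_SPATIAL = 2
_STREAM_TRAJECTORY = 3


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return the RNG for a named substream of the config seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class SimConfig:
    """Full parameterization of a synthetic cohort.

    Parameters
    ----------
    seed
        Master seed; determines every output byte-for-byte.
    n_patients, cells_per_patient
        Cohort size.
    antigens
        Antigen names (the target bank); defaults to the 9-member bank.
    subclones_per_patient
        Number of malignant subclones mixed within each patient.
    subclone_weights
        Mixture weights over subclones (simplex); ``None`` draws a
        Dirichlet(2,...,2) per patient from the seed.
    positivity_probs
        ``[patient][subclone][antigen]`` true-positivity probabilities in
        [0, 1]; ``None`` draws Beta(2, 2) per entry from the seed, emulating
        inter- and intra-tumor heterogeneity.
    mean_library_size
        Mean per-cell total UMI count (library sizes are lognormal about it).
    dropout_rate
        Probability that a truly-positive antigen transcript is lost from the
        count matrix for a given cell.
    frac_qc_violators
        Fraction of cells planted to violate a QC rule by construction
        (high mito fraction, too few, or too many detected genes, cycled).
    n_background_genes
        Non-antigen genes padded into the matrix so detected-gene counts are
        realistic. Must exceed ``genes_detected_max_violator`` for high-gene
        QC violators to be constructible.
    genes_detected_mean / genes_detected_sd
        Target detected-gene count for QC-passing cells (clipped away from
        the QC boundaries).
    spatial_radius_um
        Organoid (tumor disc) radius in micrometers.
    t_cell_count
        Number of T cells placed in the spatial simulation.
    t_cell_mode
        ``"uniform"`` (uniform in the disc) or ``"rim"`` (concentrated near
        the rim, emulating poor infiltration).
    walk_step_sd_um
        Per-axis Gaussian step SD of the T-cell random walk, µm per frame.
    n_timepoints
        Frames per trajectory (24 h imaged at 30-min intervals by default).
    """

    seed: int = 0
    n_patients: int = 3
    cells_per_patient: int = 1000
    antigens: Sequence[str] = field(default_factory=lambda: list(DEFAULT_TARGET_BANK))
    subclones_per_patient: int = 3
    subclone_weights: Sequence[float] | None = None
    positivity_probs: Sequence[Sequence[Sequence[float]]] | None = None
    mean_library_size: float = 5000.0
    dropout_rate: float = 0.3
    frac_qc_violators: float = 0.05
    n_background_genes: int = 3000
    genes_detected_mean: float = 1000.0
    genes_detected_sd: float = 150.0
    spatial_radius_um: float = 400.0
    t_cell_count: int = 500
    t_cell_mode: str = "uniform"
    walk_step_sd_um: float = 2.0
    n_timepoints: int = 49
    antigen_gene_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ANTIGEN_GENE_MAP)
    )

    def __post_init__(self) -> None:
        self.antigens = list(self.antigens)
        if self.n_patients < 1 or self.cells_per_patient < 1:
            raise ConfigurationError("n_patients and cells_per_patient must be >= 1")
        if len(set(self.antigens)) != len(self.antigens):
            raise ConfigurationError("antigen names must be unique")
        if self.subclones_per_patient < 1:
            raise ConfigurationError("subclones_per_patient must be >= 1")
        if self.subclone_weights is not None:
            w = np.asarray(self.subclone_weights, dtype=float)
            if w.shape != (self.subclones_per_patient,):
                raise ConfigurationError(
                    f"subclone_weights must have length {self.subclones_per_patient}"
                )
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
                raise ConfigurationError("subclone_weights must be a simplex (sum to 1)")
        if self.positivity_probs is not None:
            p = np.asarray(self.positivity_probs, dtype=float)
            want = (self.n_patients, self.subclones_per_patient, len(self.antigens))
            if p.shape != want:
                raise ConfigurationError(
                    f"positivity_probs must have shape {want}, got {p.shape}"
                )
            if np.any(p < 0) or np.any(p > 1):
                raise ConfigurationError("positivity_probs must lie in [0, 1]")
        for name, lo, hi in (
            ("dropout_rate", 0.0, 1.0),
            ("frac_qc_violators", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigurationError(f"{name} must be in [{lo}, {hi}]")
        if self.mean_library_size <= 0:
            raise ConfigurationError("mean_library_size must be positive")
        if self.spatial_radius_um <= 0:
            raise ConfigurationError("spatial_radius_um must be positive")
        if self.walk_step_sd_um < 0:
            raise ConfigurationError("walk_step_sd_um must be non-negative")
        if self.t_cell_mode not in ("uniform", "rim"):
            raise ConfigurationError("t_cell_mode must be 'uniform' or 'rim'")
        missing = [a for a in self.antigens if a not in self.antigen_gene_map]
        if missing:
            raise ConfigurationError(f"antigens without a gene mapping: {missing}")

    # --- resolved (seed-drawn when unspecified) parameters -----------------

    def resolved_weights(self) -> np.ndarray:
        """Per-patient subclone weights, shape (n_patients, n_subclones)."""
        if self.subclone_weights is not None:
            w = np.asarray(self.subclone_weights, dtype=float)
            return np.tile(w, (self.n_patients, 1))
        rng = substream(self.seed, _STREAM_PARAMS, 0)
        return rng.dirichlet(
            np.full(self.subclones_per_patient, 2.0), size=self.n_patients
        )

    def resolved_probs(self) -> np.ndarray:
        """Positivity probabilities, shape (n_patients, n_subclones, n_antigens)."""
        if self.positivity_probs is not None:
            return np.asarray(self.positivity_probs, dtype=float)
        rng = substream(self.seed, _STREAM_PARAMS, 1)
        return rng.beta(
            2.0,
            2.0,
            size=(self.n_patients, self.subclones_per_patient, len(self.antigens)),
        )

    def patient_rng(self, patient_index: int) -> np.random.Generator:
        return substream(self.seed, _STREAM_PATIENT, patient_index)

    def spatial_rng(self) -> np.random.Generator:
        return substream(self.seed, _STREAM_SPATIAL)

    def trajectory_rng(self) -> np.random.Generator:
        return substream(self.seed, _STREAM_TRAJECTORY)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["antigens"] = list(self.antigens)
        return d
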