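"""Cell quality control and antigen positivity calling.

QC removes cells with a high mitochondrial read fraction (> 20% by default)
or an implausibly low/high detected-gene count (< 200 or > 2500 by default);
all three comparisons are strict, so boundary cells are retained.
Normalization is counts-per-10k followed by log1p (natural log). Positivity
is binarized per antigen by a strict threshold on the normalized value
(default tau = 0: any detected transcript counts as positive — with
dropout-heavy data a higher threshold only loses true positives) or, for
imaging data, on a per-marker stain intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, InputError, NoCellsPassQCError
from .synthetic import TUMOR

REQUIRED_OBS = ("mito_fraction", "detected_genes")


@dataclass(frozen=True)
class QCThresholds:
    """Strict QC cutoffs: remove iff mito > mito_max, genes < genes_min or
    genes > genes_max."""

    mito_max: float = 0.20
    genes_min: int = 200
    genes_max: int = 2500

    def __post_init__(self) -> None:
        if not 0 < self.mito_max < 1:
            raise ConfigurationError("mito_max must be in (0, 1)")
        if self.genes_min >= self.genes_max:
            raise ConfigurationError("genes_min must be < genes_max")


@dataclass
class QCReport:
    n_input: int
    n_retained: int
    removed_high_mito: int
    removed_low_genes: int
    removed_high_genes: int
    removed_barcodes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_high_mito": self.removed_high_mito,
            "removed_low_genes": self.removed_low_genes,
            "removed_high_genes": self.removed_high_genes,
            "removed_barcodes": list(self.removed_barcodes),
        }


@dataclass
class PositivityMatrix:
    """Binary cells x antigens table — the substrate of all coverage math.

    ``flags`` is a 0/1 integer DataFrame indexed by cell id with one column
    per antigen; ``rule`` records how the calls were made (threshold value
    and modality) so results are auditable.
    """

    flags: pd.DataFrame
    rule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.flags.shape[0] == 0:
            raise InputError("PositivityMatrix requires at least one cell")
        if self.flags.columns.duplicated().any():
            raise InputError("antigen names must be unique")
        vals = self.flags.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise InputError("positivity flags must be 0/1")
        self.flags = self.flags.astype(np.int8)

    @property
    def antigens(self) -> list[str]:
        return list(self.flags.columns)

    @property
    def n_cells(self) -> int:
        return int(self.flags.shape[0])


def compute_mito_fraction(adata: ad.AnnData, prefix: str = "MT-") -> pd.Series:
    """Fraction of each cell's counts on mitochondrial genes (by name prefix).

    Helper for real data where the fraction is not already in the metadata;
    simulated cohorts carry it as a column directly.
    """
    mito = adata.var_names.str.startswith(prefix)
    total = np.asarray(adata.X.sum(axis=1)).ravel()
    if not mito.any():
        warnings.warn(f"no genes with prefix {prefix!r}; mito fraction is 0")
        return pd.Series(0.0, index=adata.obs_names, name="mito_fraction")
    m = np.asarray(adata.X[:, mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, m / total, 0.0)
    return pd.Series(frac, index=adata.obs_names, name="mito_fraction")


def qc_filter(
    adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()
) -> tuple[ad.AnnData, QCReport]:
    """Remove QC-failing cells; returns the filtered matrix and a report.

    A cell is removed iff ``mito_fraction > mito_max`` OR
    ``detected_genes < genes_min`` OR ``detected_genes > genes_max``
    (all strict). Idempotent: filtering a filtered matrix removes nothing.
    """
    for col in REQUIRED_OBS:
        if col not in adata.obs:
            raise InputError(f"missing per-cell metadata column {col!r}")
    mito = adata.obs["mito_fraction"].to_numpy(dtype=float)
    genes = adata.obs["detected_genes"].to_numpy()
    high_mito = mito > thresholds.mito_max
    low_genes = genes < thresholds.genes_min
    high_genes = genes > thresholds.genes_max
    removed = high_mito | low_genes | high_genes
    report = QCReport(
        n_input=adata.n_obs,
        n_retained=int((~removed).sum()),
        removed_high_mito=int(high_mito.sum()),
        removed_low_genes=int(low_genes.sum()),
        removed_high_genes=int(high_genes.sum()),
        removed_barcodes=list(adata.obs_names[removed]),
    )
    if report.n_retained == 0:
        raise NoCellsPassQCError("no cells pass QC under the given thresholds")
    return adata[~removed].copy(), report


def normalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Depth-normalize to ``scale`` counts per cell and log1p (natural log).

    value = log(1 + count / cell_total * scale); scale-invariant per cell.
    """
    if scale <= 0:
        raise ConfigurationError("scale must be positive")
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        raise InputError(
            "cells with zero total counts present; run qc_filter first"
        )
    import scanpy as sc

    out = adata.copy()
    out.X = out.X.astype(np.float64)
    sc.pp.normalize_total(out, target_sum=scale)
    sc.pp.log1p(out)
    return out


def call_positivity(
    normalized: ad.AnnData,
    antigen_map: dict[str, str],
    tau: float = 0.0,
    malignant_only: bool = True,
) -> PositivityMatrix:
    """Binarize antigen expression: positive iff normalized value > tau.

    ``antigen_map`` maps each antigen name to exactly one gene present in the
    matrix. With the default ``tau = 0`` any detected transcript is positive.
    When ``malignant_only`` and a boolean ``malignant`` obs column exists,
    only malignant cells are scored (the upstream malignant annotation is an
    input, not computed here).
    """
    if tau < 0:
        raise ConfigurationError("tau must be >= 0")
    missing = {a: g for a, g in antigen_map.items() if g not in normalized.var_names}
    if missing:
        raise ConfigurationError(
            f"antigens mapped to genes absent from the matrix: {missing}"
        )
    adata = normalized
    if malignant_only and "malignant" in adata.obs:
        adata = adata[adata.obs["malignant"].astype(bool)]
    genes = [antigen_map[a] for a in antigen_map]
    sub = adata[:, genes].X
    vals = sub.toarray() if sp.issparse(sub) else np.asarray(sub)
    flags = pd.DataFrame(
        (vals > tau).astype(np.int8),
        index=adata.obs_names.copy(),
        columns=list(antigen_map),
    )
    return PositivityMatrix(
        flags=flags, rule={"modality": "expression", "tau": tau}
    )


def call_positivity_spatial(
    table: pd.DataFrame, thresholds: dict[str, float]
) -> PositivityMatrix:
    """Binarize stain intensities on an imaging cell table.

    Only tumor-class cells are scored; a cell is positive for a marker iff
    its ``intensity_<marker>`` strictly exceeds the marker's threshold.
    """
    missing_cols = [
        f"intensity_{m}" for m in thresholds if f"intensity_{m}" not in table.columns
    ]
    if missing_cols:
        raise InputError(f"missing marker columns: {missing_cols}")
    tumor = table[table["class"] == TUMOR]
    if tumor.empty:
        raise InputError("no tumor-class cells to score")
    flags = pd.DataFrame(index=pd.Index(tumor["id"], name="id"))
    for marker, thr in thresholds.items():
        flags[marker] = (tumor[f"intensity_{marker}"].to_numpy() > thr).astype(np.int8)
    return PositivityMatrix(
        flags=flags,
        rule={"modality": "spatial_intensity", "thresholds": dict(thresholds)},
    )
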