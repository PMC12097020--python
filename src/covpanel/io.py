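"""Readers and writers for every on-disk format the pipeline touches.

Count matrices travel as 10x-style MatrixMarket triplets (matrix.mtx +
features.tsv + barcodes.tsv, 1-based indices on disk, 0-based in memory)
with a metadata.tsv joined on barcode, or as dense CSV. Imaging-derived
tables (spatial cells, trajectories, co-culture labels) are headered CSV;
positivity matrices and reports are TSV/JSON. All validation errors are
typed and carry file/line context where a line is identifiable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import InputError, ParseError
from .qc import PositivityMatrix
from .synthetic import CLASS_VOCAB, GroundTruth

SPATIAL_COLUMNS = ("id", "x", "y", "class")
TRAJECTORY_COLUMNS = ("cell_id", "time_h", "x", "y")
LABEL_COLUMNS = ("cell_id", "tumor_stain", "death_stain", "condition", "timepoint_h")


# --------------------------------------------------------------------------
# Count matrices
# --------------------------------------------------------------------------

def write_count_matrix(adata: ad.AnnData, out_dir: str | Path) -> Path:
    """Write an AnnData as a 10x-style MTX triplet plus metadata.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X)
    # genes x cells, as 10x writes it
    scipy.io.mmwrite(out / "matrix.mtx", X.T.astype(np.int64), field="integer")
    features = pd.DataFrame({"gene": adata.var_names})
    if "antigen" in adata.var:
        features["antigen"] = adata.var["antigen"].to_numpy()
    features.to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(
        out / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(out / "metadata.tsv", sep="\t", index_label="barcode")
    return out


def _scan_mtx(path: Path) -> None:
    """Pre-validate an MTX file: header, declared vs actual entry count."""
    declared = None
    n_entries = 0
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("%%MatrixMarket"):
            raise ParseError("missing MatrixMarket header", str(path), 1)
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("%") or not line.strip():
                continue
            if declared is None:
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError("malformed size line", str(path), lineno)
                declared = int(parts[2])
                continue
            n_entries += 1
    if declared is None:
        raise ParseError("no size line found", str(path))
    if n_entries != declared:
        raise ParseError(
            f"declared {declared} entries but found {n_entries}", str(path)
        )


def read_count_matrix(path: str | Path, dialect: str = "mtx_triplet") -> ad.AnnData:
    """Read a count matrix (``mtx_triplet`` directory or ``dense_csv`` file).

    Validates dimensions against features/barcodes, integrality,
    non-negativity and barcode uniqueness; joins per-cell metadata on
    barcode when a metadata.tsv sits next to the triplet.
    """
    path = Path(path)
    if dialect == "mtx_triplet":
        return _read_mtx_triplet(path)
    if dialect == "dense_csv":
        return _read_dense_csv(path)
    raise InputError(f"unknown dialect {dialect!r}; use mtx_triplet or dense_csv")


def _read_mtx_triplet(directory: Path) -> ad.AnnData:
    mtx = directory / "matrix.mtx"
    for f in (mtx, directory / "features.tsv", directory / "barcodes.tsv"):
        if not f.exists():
            raise ParseError("required file missing", str(f))
    _scan_mtx(mtx)
    M = scipy.io.mmread(mtx)  # genes x cells
    dense_min = M.min()
    if dense_min < 0:
        raise ParseError(f"negative entry ({dense_min}) in matrix", str(mtx))
    data = M.data if sp.issparse(M) else np.asarray(M).ravel()
    if not np.all(np.equal(np.mod(data, 1), 0)):
        raise ParseError("non-integer entries in count matrix", str(mtx))
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0]
    n_genes, n_cells = M.shape
    if len(features) != n_genes:
        raise ParseError(
            f"features.tsv has {len(features)} rows but matrix declares "
            f"{n_genes} genes",
            str(directory / "features.tsv"),
        )
    if len(barcodes) != n_cells:
        raise ParseError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix declares "
            f"{n_cells} cells",
            str(directory / "barcodes.tsv"),
        )
    dup = barcodes[barcodes.duplicated()]
    if not dup.empty:
        raise ParseError(
            f"duplicate barcodes (first: {dup.iloc[0]!r} at row {dup.index[0] + 1})",
            str(directory / "barcodes.tsv"),
        )
    var = pd.DataFrame(index=pd.Index(features[0], name="gene"))
    if features.shape[1] > 1:
        var["antigen"] = features[1].fillna("").to_numpy()
    adata = ad.AnnData(
        X=sp.csr_matrix(M.T).astype(np.int32),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=var,
    )
    meta_path = directory / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="barcode")
        missing = adata.obs_names.difference(meta.index)
        if len(missing):
            raise ParseError(
                f"metadata missing for {len(missing)} barcodes "
                f"(first: {missing[0]!r})",
                str(meta_path),
            )
        adata.obs = meta.loc[adata.obs_names]
    return adata


def _read_dense_csv(path: Path) -> ad.AnnData:
    if not path.exists():
        raise ParseError("file missing", str(path))
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        bad = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate barcode {bad!r}", str(path))
    vals = df.to_numpy()
    neg = np.argwhere(vals < 0)
    if neg.size:
        i, j = neg[0]
        raise ParseError(
            f"negative count at cell {df.index[i]!r}, gene {df.columns[j]!r}",
            str(path),
        )
    if not np.all(np.equal(np.mod(vals, 1), 0)):
        i, j = np.argwhere(np.mod(vals, 1) != 0)[0]
        raise ParseError(
            f"non-integer count at cell {df.index[i]!r}, gene {df.columns[j]!r}",
            str(path),
        )
    return ad.AnnData(
        X=sp.csr_matrix(vals.astype(np.int32)),
        obs=pd.DataFrame(index=pd.Index(df.index.astype(str), name="barcode")),
        var=pd.DataFrame(index=pd.Index(df.columns.astype(str), name="gene")),
    )


# --------------------------------------------------------------------------
# Imaging-derived tables
# --------------------------------------------------------------------------

def _read_schema_csv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError("file missing", str(path))
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"missing required columns {missing}; expected schema {list(required)}",
            str(path),
        )
    if df.empty:
        warnings.warn(f"{path} contains a header but no rows")
    return df


def read_spatial(path: str | Path) -> pd.DataFrame:
    """Read a spatial cell table (id, x, y in µm, class, marker columns)."""
    df = _read_schema_csv(path, SPATIAL_COLUMNS)
    bad = ~df["class"].isin(CLASS_VOCAB)
    if bad.any():
        row = int(np.argmax(bad.to_numpy()))
        raise ParseError(
            f"class {df['class'].iloc[row]!r} outside vocabulary {CLASS_VOCAB} "
            f"(data row {row + 1})",
            str(path),
        )
    if not df.empty and not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ParseError("non-finite coordinates", str(path))
    return df


def read_trajectories(path: str | Path) -> pd.DataFrame:
    """Read a time-lapse track table; out-of-order rows are sorted with a
    warning."""
    df = _read_schema_csv(path, TRAJECTORY_COLUMNS)
    if df.empty:
        return df
    in_order = df.groupby("cell_id")["time_h"].is_monotonic_increasing.all()
    if not in_order:
        warnings.warn(f"{path}: trajectory rows out of time order; sorting")
        df = df.sort_values(["cell_id", "time_h"], kind="stable", ignore_index=True)
    return df


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a co-culture label table (tumor/death stain flags per cell)."""
    df = _read_schema_csv(path, LABEL_COLUMNS)
    for col in ("tumor_stain", "death_stain"):
        if not df.empty and not df[col].isin([0, 1, True, False]).all():
            raise ParseError(f"column {col!r} must be boolean/0-1", str(path))
    return df


# --------------------------------------------------------------------------
# Positivity matrices, ground truth, manifests
# --------------------------------------------------------------------------

def write_positivity(P: PositivityMatrix, path: str | Path) -> None:
    P.flags.to_csv(path, sep="\t", index_label="cell_id")


def read_positivity(path: str | Path) -> PositivityMatrix:
    path = Path(path)
    if not path.exists():
        raise ParseError("file missing", str(path))
    flags = pd.read_csv(path, sep="\t", index_col="cell_id")
    return PositivityMatrix(flags=flags, rule={"modality": "file", "source": str(path)})


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "antigens": truth.antigens,
        "weights": truth.weights.tolist(),
        "positivity_probs": truth.probs.tolist(),
        "patients": {
            pid: {
                "subclone": truth.subclone[pid].tolist(),
                "flags": truth.flags[pid].astype(int).to_dict(orient="split"),
                "qc_violators": truth.qc_violators[pid].to_dict(orient="records"),
            }
            for pid in truth.patient_ids
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    truth = GroundTruth(
        antigens=payload["antigens"],
        weights=np.asarray(payload["weights"]),
        probs=np.asarray(payload["positivity_probs"]),
    )
    for pid, p in payload["patients"].items():
        truth.subclone[pid] = np.asarray(p["subclone"])
        f = p["flags"]
        truth.flags[pid] = pd.DataFrame(
            np.asarray(f["data"], dtype=bool), index=f["index"], columns=f["columns"]
        )
        truth.qc_violators[pid] = pd.DataFrame(
            p["qc_violators"], columns=["barcode", "rule"]
        )
    return truth


def build_manifest(root: str | Path, patients: dict[str, dict[str, str]]) -> dict:
    """Manifest of a cohort directory: per-patient file paths + sha256."""
    root = Path(root)
    if len(set(patients)) != len(patients):
        raise InputError("patient ids must be unique")
    manifest: dict = {"patients": {}}
    for pid, files in patients.items():
        entry = {}
        for modality, rel in files.items():
            f = root / rel
            if not f.exists():
                raise InputError(f"manifest references missing file {f}")
            entry[modality] = {
                "path": rel,
                "sha256": hashlib.sha256(f.read_bytes()).hexdigest(),
            }
        manifest["patients"][pid] = entry
    return manifest
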