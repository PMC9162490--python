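"""Readers and writers for the plain-text formats the pipeline exchanges.

Single-cell counts travel as MatrixMarket (matrix.mtx with genes.tsv /
barcodes.tsv sidecars, genes x cells) or as dense TSV; bulk matrices as
TSV/CSV with an orientation flag; signatures and proportions as CSV;
clinical tables as CSV with the documented headers (sample_id, t_stage,
n_stage, grade, os_months, os_event); gene positions as BED-like TSV
(chrom, start, end, gene_id; 0-based half-open).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import InputError

CLINICAL_COLUMNS = ["t_stage", "n_stage", "grade", "os_months", "os_event"]


def _check_unique(index, what: str) -> None:
    idx = pd.Index(index)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise InputError(f"duplicate {what} (e.g. {dups})")


# -- single-cell counts ------------------------------------------------------


def write_counts_mtx(counts: pd.DataFrame, outdir) -> None:
    """Write genes x cells counts as matrix.mtx + genes.tsv + barcodes.tsv."""
    os.makedirs(outdir, exist_ok=True)
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"),
                     scipy.sparse.coo_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(os.path.join(outdir, "genes.tsv"),
                                   sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(os.path.join(outdir, "barcodes.tsv"),
                                     sep="\t", index=False, header=False)


def read_counts_mtx(indir) -> pd.DataFrame:
    """Read matrix.mtx + genes.tsv + barcodes.tsv into a genes x cells DataFrame."""
    mat = scipy.io.mmread(os.path.join(indir, "matrix.mtx")).toarray()
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t", header=None)[0]
    cells = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t", header=None)[0]
    _check_unique(genes, "gene ids")
    _check_unique(cells, "cell ids")
    if mat.shape != (len(genes), len(cells)):
        raise InputError(f"matrix shape {mat.shape} does not match "
                         f"{len(genes)} genes x {len(cells)} cells")
    return pd.DataFrame(mat.astype(np.int64), index=list(genes), columns=list(cells))


def write_dense_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t")


def read_dense_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(frame.index, "row ids")
    _check_unique(frame.columns, "column ids")
    return frame


# -- bulk / signature / proportions ------------------------------------------


def read_bulk(path, samples_in_rows: bool = True) -> pd.DataFrame:
    """Read a bulk matrix (TSV or CSV by extension) as samples x genes."""
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if not samples_in_rows:
        frame = frame.T
    _check_unique(frame.index, "sample ids")
    _check_unique(frame.columns, "gene ids")
    return frame


def write_signature_csv(signature: pd.DataFrame, path) -> None:
    signature.to_csv(path)


def read_signature_csv(path) -> pd.DataFrame:
    sig = pd.read_csv(path, index_col=0)
    _check_unique(sig.index, "signature gene ids")
    return sig


def write_proportions_csv(proportions: pd.DataFrame, path,
                          details: pd.DataFrame | None = None) -> None:
    out = proportions.copy()
    if details is not None:
        out = out.join(details[["n_trimmed", "residual_norm"]])
    out.to_csv(path, index_label="sample_id")


def read_proportions_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col=0)
    return frame.drop(columns=[c for c in ("n_trimmed", "residual_norm")
                               if c in frame.columns])


# -- clinical ----------------------------------------------------------------


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index_label="sample_id")


def read_clinical_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="sample_id")
    missing = [c for c in CLINICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"clinical table missing columns {missing}; "
                         f"expected {CLINICAL_COLUMNS}")
    return frame


# -- labels and positions ----------------------------------------------------


def write_labels_tsv(labels: pd.Series, path) -> None:
    labels.rename("label").rename_axis("cell_id").to_csv(path, sep="\t")


def read_labels_tsv(path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise InputError("labels TSV needs two columns: cell_id, label")
    frame = frame.iloc[:, :2]
    frame.columns = ["cell_id", "label"]
    _check_unique(frame["cell_id"], "cell ids")
    return frame.set_index("cell_id")["label"]


def write_markers_tsv(markers, path) -> None:
    rows = [(c, g) for c in sorted(markers.markers, key=str)
            for g in markers.markers[c]]
    pd.DataFrame(rows, columns=["cluster", "gene"]).to_csv(path, sep="\t", index=False)


def read_positions_bed(path) -> pd.DataFrame:
    """Read BED-like TSV (chrom, start, end, gene_id; 0-based half-open)."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    if frame.shape[1] < 4:
        raise InputError("positions BED needs 4 columns: chrom, start, end, gene_id")
    frame = frame.iloc[:, :4]
    frame.columns = ["chromosome", "start", "end", "gene_id"]
    _check_unique(frame["gene_id"], "gene ids")
    return frame[["gene_id", "chromosome", "start", "end"]]


def write_positions_bed(positions: pd.DataFrame, path) -> None:
    cols = positions.copy()
    if "end" not in cols.columns:
        cols["end"] = cols["start"] + 1
    cols[["chromosome", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", header=False, index=False)
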