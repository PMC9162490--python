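"""Expression-based copy-number inference and per-cell CNV burden scores.

Large chromosomal gains and losses leave a coherent footprint in expression:
many consecutive genes along the chromosome shift up or down together.  The
profile is inferred by (1) centering each gene on its mean over an explicit
reference cell set, (2) clipping each gene's deviation at +/- ``clip_sd``
reference standard deviations so no single gene dominates, (3) smoothing
along the genome with a moving mean over a window of 100 genes surrounding
each position (50 before, 49 after, truncated at chromosome ends), and
(4) median-centering each cell's profile.  The scalar per-cell score is the
mean squared smoothed deviation — symmetric in gains and losses and zero for
a neutral profile (a mean-absolute variant is available).

A cell population whose score distribution does not exceed the reference's
is treated as copy-number neutral; that is the certification used to argue a
cluster is not malignant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

log = logging.getLogger(__name__)

#: Default chromosome order: autosomes, then X, Y, MT.
CHROMOSOME_ORDER = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

MIN_REFERENCE_CELLS = 20


def _norm_chrom(c: str) -> str:
    c = str(c).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return {"M": "MT"}.get(c.upper(), c.upper()) if not c.isdigit() else c


def order_genes(positions: pd.DataFrame, chrom_order=CHROMOSOME_ORDER) -> pd.DataFrame:
    """Sort gene positions by (chromosome order, start); deterministic.

    ``positions`` needs columns ``gene_id``, ``chromosome``, ``start``.
    Genes on chromosomes absent from ``chrom_order`` are dropped with a
    warning; duplicate gene ids are an error.
    """
    pos = positions.copy()
    if pos["gene_id"].duplicated().any():
        dups = pos.loc[pos["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise InputError(f"duplicate gene ids in positions (e.g. {dups})")
    pos["chromosome"] = [_norm_chrom(c) for c in pos["chromosome"]]
    rank = {c: i for i, c in enumerate(chrom_order)}
    known = pos["chromosome"].isin(rank)
    if not known.all():
        dropped = pos.loc[~known, "chromosome"].unique().tolist()
        log.warning("dropping %d gene(s) on unknown chromosome(s) %s",
                    int((~known).sum()), dropped)
        pos = pos.loc[known]
    pos["_rank"] = pos["chromosome"].map(rank)
    pos = pos.sort_values(["_rank", "start", "gene_id"], kind="stable")
    return pos.drop(columns="_rank").reset_index(drop=True)


@dataclass
class CNVProfile:
    """Smoothed, reference-centered expression along the genome (cells x positions)."""

    values: pd.DataFrame          # cells x gene positions, genomic order
    chromosomes: pd.Series        # position (gene id) -> chromosome
    reference_cells: list[str]


def _moving_mean(X: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean over axis 1, truncated at the edges.

    For a window w, position i averages indices [i - w//2, i + (w - w//2 - 1)]
    clipped to the array; both even and odd windows are accepted.
    """
    n = X.shape[1]
    before, after = window // 2, window - window // 2 - 1
    idx = np.arange(n)
    lo = np.clip(idx - before, 0, n)
    hi = np.clip(idx + after + 1, 0, n)
    csum = np.concatenate([np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1)
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


def infer_cnv_profile(expr: pd.DataFrame, reference_cells, positions: pd.DataFrame,
                      window: int = 100, clip_sd: float = 3.0) -> CNVProfile:
    """Infer smoothed relative expression along the genome for every cell.

    ``expr`` is genes x cells (log-scale normalized expression);
    ``reference_cells`` is an explicit list of cells defining the neutral
    baseline (>= 20 required); ``positions`` supplies the genomic ordering.
    Genes without a placed position are dropped with a warning.
    """
    reference_cells = [c for c in reference_cells]
    missing_ref = [c for c in reference_cells if c not in expr.columns]
    if missing_ref:
        raise InputError(f"reference cells absent from expression: {missing_ref[:5]}")
    if len(reference_cells) < MIN_REFERENCE_CELLS:
        raise InputError(
            f"{len(reference_cells)} reference cells; need >= {MIN_REFERENCE_CELLS}")

    ordered = order_genes(positions)
    ordered = ordered.loc[ordered["gene_id"].isin(expr.index)]
    n_unplaced = expr.shape[0] - ordered.shape[0]
    if n_unplaced:
        log.warning("%d expression gene(s) lack positions and are dropped", n_unplaced)
    if ordered.empty:
        raise InputError("no expression genes have genomic positions")

    genes = ordered["gene_id"].tolist()
    X = expr.loc[genes].to_numpy(dtype=float).T      # cells x genes, genomic order
    ref_idx = expr.columns.get_indexer(reference_cells)
    ref = X[ref_idx]
    ref_mean = ref.mean(axis=0)
    ref_sd = ref.std(axis=0, ddof=0)

    rel = X - ref_mean[None, :]
    bound = clip_sd * ref_sd
    rel = np.clip(rel, -bound[None, :], bound[None, :])

    smoothed = np.empty_like(rel)
    chroms = ordered["chromosome"].to_numpy()
    for chrom in pd.unique(chroms):
        block = np.flatnonzero(chroms == chrom)
        smoothed[:, block] = _moving_mean(rel[:, block], window)
    smoothed = smoothed - np.median(smoothed, axis=1, keepdims=True)

    values = pd.DataFrame(smoothed, index=expr.columns, columns=genes)
    return CNVProfile(values=values,
                      chromosomes=pd.Series(chroms, index=genes, name="chromosome"),
                      reference_cells=reference_cells)


def cnv_cell_score(profile: CNVProfile, method: str = "mean_square") -> pd.Series:
    """Scalar CNV burden per cell: mean squared (or mean absolute) smoothed deviation."""
    V = profile.values.to_numpy()
    if method == "mean_square":
        s = (V ** 2).mean(axis=1)
    elif method == "mean_abs":
        s = np.abs(V).mean(axis=1)
    else:
        raise InputError(f"unknown score method {method!r}")
    return pd.Series(s, index=profile.values.index, name="cnv_score")


def cnv_type_summary(scores: pd.Series, labels: pd.Series,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-type CNV score summary with an elevation flag.

    Each type (>= 3 cells; smaller ones excluded with a warning) is compared
    against all other cells pooled by a two-sided rank-sum test; a type is
    flagged CNV-elevated when p < ``alpha`` and its median exceeds the pooled
    median of the other cells.
    """
    labels = labels.reindex(scores.index)
    counts = labels.value_counts()
    usable = counts.index[counts >= 3]
    if len(usable) < 2:
        raise InputError("need >= 2 cell types with >= 3 cells each")
    for small in counts.index[counts < 3]:
        log.warning("type %s has %d cells; excluded from CNV summary", small, counts[small])

    rows = []
    for t in sorted(usable, key=str):
        own = scores[labels == t]
        rest = scores[(labels != t) & labels.isin(usable)]
        if own.nunique() == 1 and rest.nunique() == 1 and own.iloc[0] == rest.iloc[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(own, rest, alternative="two-sided").pvalue)
        elevated = bool(p < alpha and own.median() > rest.median())
        rows.append({"type": t, "n_cells": int(len(own)), "mean": float(own.mean()),
                     "median": float(own.median()), "p": p, "cnv_elevated": elevated})
    return pd.DataFrame(rows).set_index("type")
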