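"""Cell-level quality control and a simple depth normalization.

The QC rule removes cells with unique feature counts over 4000 or below 200
and mitochondrial count fractions above 10%.  Both feature bounds and the
mitochondrial bound are strict inequalities, so boundary cells (exactly 200
or 4000 features, exactly 10% mitochondrial) survive.  Normalization scales
each cell to the cohort median depth and applies log1p; it stands in for
heavier variance-stabilizing transforms, whose clustering stack is out of
scope here (cluster labels are accepted as input).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InputError

log = logging.getLogger(__name__)


def mito_mask(gene_ids, prefix: str = "MT-", gene_list=None) -> np.ndarray:
    """Boolean mask of mitochondrial genes by prefix (case-insensitive) or explicit list."""
    idx = pd.Index(gene_ids)
    if gene_list is not None:
        return idx.isin(set(gene_list))
    return np.asarray([g.upper().startswith(prefix.upper()) for g in idx])


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()[:5]
        raise InputError(
            f"duplicate gene ids in counts (e.g. {dups}); aggregate or rename "
            "them before QC — silent aggregation is not performed")
    if counts.columns.has_duplicates:
        raise InputError("duplicate cell ids in counts")
    if (counts.values < 0).any():
        raise InputError("counts must be non-negative")


def compute_cell_stats(counts: pd.DataFrame, mito_prefix: str = "MT-",
                       mito_genes=None, sample_ids=None) -> pd.DataFrame:
    """Per-cell QC statistics.

    Returns a DataFrame indexed by cell id with columns ``n_features``
    (genes with nonzero count), ``total_counts``, ``mito_fraction`` (share of
    counts on mitochondrial genes; NaN for zero-total cells) and ``valid``
    (False for all-zero cells, which are excluded downstream).
    """
    _validate_counts(counts)
    values = counts.to_numpy()
    mask = mito_mask(counts.index, prefix=mito_prefix, gene_list=mito_genes)
    totals = values.sum(axis=0)
    mito_tot = values[mask, :].sum(axis=0) if mask.any() else np.zeros_like(totals)
    valid = totals > 0
    if not valid.all():
        log.warning("%d all-zero cell(s) flagged invalid", int((~valid).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(valid, mito_tot / np.maximum(totals, 1), np.nan)
    stats = pd.DataFrame(
        {
            "n_features": (values > 0).sum(axis=0),
            "total_counts": totals,
            "mito_fraction": mito_frac,
            "valid": valid,
        },
        index=pd.Index(counts.columns, name="cell_id"),
    )
    if sample_ids is not None:
        stats["sample_id"] = pd.Series(sample_ids).reindex(stats.index).values
    return stats


def qc_filter(counts: pd.DataFrame, stats: pd.DataFrame, min_features: int = 200,
              max_features: int = 4000, max_mito: float = 0.10
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove cells failing the QC rule; returns (filtered counts, report).

    A cell is removed when ``n_features < min_features``,
    ``n_features > max_features`` or ``mito_fraction > max_mito`` — all
    strict, so cells exactly at a threshold are kept.  Invalid (all-zero)
    cells are always removed.  The gene set is unchanged and retained values
    are untouched (pure subsetting).
    """
    stats = stats.reindex(counts.columns)
    if stats["n_features"].isna().any():
        raise InputError("stats missing for some cells; compute them from these counts")
    reasons = pd.Series("", index=stats.index, dtype=object)
    reasons[stats["n_features"] < min_features] = "low_features"
    reasons[stats["n_features"] > max_features] = "high_features"
    high_mito = stats["mito_fraction"] > max_mito  # NaN compares False
    reasons[high_mito & (reasons == "")] = "high_mito"
    reasons[~stats["valid"]] = "invalid_zero_total"
    kept = reasons == ""
    report = pd.DataFrame(
        {
            "n_features": stats["n_features"],
            "mito_fraction": stats["mito_fraction"],
            "kept": kept,
            "reason": reasons,
        },
        index=stats.index,
    )
    if not kept.any():
        raise EmptyResultError("QC removed all cells")
    return counts.loc[:, kept[kept].index], report


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-depth scaling followed by log1p.

    Each cell is scaled so its total equals the cohort median depth, then
    log(1 + x) is applied.  Zeros remain zeros and the map is monotone within
    each cell, so proportional cells normalize identically.
    """
    _validate_counts(counts)
    depths = counts.sum(axis=0).to_numpy(dtype=float)
    if (depths <= 0).any():
        bad = counts.columns[depths <= 0].tolist()[:5]
        raise InputError(f"zero-depth cell(s) {bad}; run qc_filter first")
    target = float(np.median(depths))
    scaled = counts.to_numpy(dtype=float) * (target / depths)[None, :]
    return pd.DataFrame(np.log1p(scaled), index=counts.index, columns=counts.columns)
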