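"""All-pairwise marker selection and signature-matrix construction.

A gene is a marker of a cluster only if it clears BOTH thresholds — FDR
below 0.05 (Benjamini–Hochberg within the comparison) and log2 fold change
above 0.4 — in EVERY pairwise comparison of that cluster against each other
cluster.  With symmetric thresholds this makes marker sets of different
clusters provably disjoint (a gene cannot be >2^0.4-fold up in A vs B and in
B vs A simultaneously), which is asserted on every run.

The per-gene test is the two-sided Wilcoxon rank-sum (Mann–Whitney U) with
tie-corrected normal approximation (no continuity correction, so a gene with
identical values in both clusters gets exactly p = 1); for tiny comparisons
(<= 12 cells total, no ties) the exact null distribution is used instead.  Fold changes are
log2((mean_target + eps) / (mean_background + eps)) with eps = 1e-9 on
normalized expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

log = logging.getLogger(__name__)

#: Pseudocount applied to both means before the log2 ratio.
FC_EPSILON = 1e-9
#: Total-cell bound below which the exact Mann-Whitney null is used.
EXACT_MAX_CELLS = 12


def _cluster_cells(labels: pd.Series, cluster) -> pd.Index:
    cells = labels.index[labels == cluster]
    if len(cells) < 3:
        raise InputError(f"cluster {cluster!r} has {len(cells)} cells; need >= 3")
    return cells


def pairwise_de(expr: pd.DataFrame, labels: pd.Series, target, background) -> pd.DataFrame:
    """Differential expression of ``target`` vs ``background`` cluster.

    ``expr`` is genes x cells (normalized); ``labels`` maps cell id to
    cluster.  Returns one row per gene with ``log2_fc``, ``p_value`` and
    ``fdr`` (BH within this comparison).  Genes constant across both
    clusters get p = 1.
    """
    labels = labels.reindex(expr.columns).dropna()
    xt = expr.loc[:, _cluster_cells(labels, target)].to_numpy()
    xb = expr.loc[:, _cluster_cells(labels, background)].to_numpy()

    mt, mb = xt.mean(axis=1), xb.mean(axis=1)
    log2_fc = np.log2((mt + FC_EPSILON) / (mb + FC_EPSILON))

    n_total = xt.shape[1] + xb.shape[1]
    combined = np.concatenate([xt, xb], axis=1)
    constant = combined.max(axis=1) == combined.min(axis=1)

    if n_total <= EXACT_MAX_CELLS:
        p = np.ones(expr.shape[0])
        for i in range(expr.shape[0]):
            if constant[i]:
                continue
            has_ties = np.unique(combined[i]).size < n_total
            method = "asymptotic" if has_ties else "exact"
            p[i] = stats.mannwhitneyu(xt[i], xb[i], alternative="two-sided",
                                      method=method, use_continuity=False).pvalue
    else:
        res = stats.mannwhitneyu(xt, xb, alternative="two-sided",
                                 method="asymptotic", use_continuity=False, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
        p[constant] = 1.0
    p = np.clip(p, 0.0, 1.0)

    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": expr.index,
            "target_cluster": target,
            "background_cluster": background,
            "log2_fc": log2_fc,
            "p_value": p,
            "fdr": fdr,
        }
    )


@dataclass
class MarkerSet:
    """Per-cluster marker lists under the all-pairwise rule.

    ``markers`` maps cluster to genes ordered by descending minimum pairwise
    log2 fold change (ties broken by gene id); ``min_log2fc`` keeps that
    statistic per marker for reporting.
    """

    markers: dict[str, list[str]]
    min_log2fc: dict[str, pd.Series]
    fdr_max: float = 0.05
    log2fc_min: float = 0.4

    def union(self) -> list[str]:
        out: list[str] = []
        for c in sorted(self.markers, key=str):
            out.extend(self.markers[c])
        return out


def select_markers(expr: pd.DataFrame, labels: pd.Series, fdr_max: float = 0.05,
                   log2fc_min: float = 0.4) -> MarkerSet:
    """Apply the all-pairwise marker rule to every cluster.

    Gene g marks cluster c iff for every other cluster b the (g, c, b)
    comparison has fdr < ``fdr_max`` and log2_fc > ``log2fc_min``.  The
    result is invariant to cell and cluster ordering.
    """
    labels = labels.reindex(expr.columns).dropna()
    clusters = sorted(pd.unique(labels), key=str)
    if len(clusters) < 2:
        raise InputError("marker rule undefined with a single cluster")

    markers: dict[str, list[str]] = {}
    min_lfc: dict[str, pd.Series] = {}
    for c in clusters:
        ok = np.ones(expr.shape[0], dtype=bool)
        lfc_min = np.full(expr.shape[0], np.inf)
        for b in clusters:
            if b == c:
                continue
            de = pairwise_de(expr, labels, c, b)
            ok &= (de["fdr"].to_numpy() < fdr_max) & (de["log2_fc"].to_numpy() > log2fc_min)
            lfc_min = np.minimum(lfc_min, de["log2_fc"].to_numpy())
        genes = expr.index[ok]
        series = pd.Series(lfc_min[ok], index=genes)
        order = sorted(genes, key=lambda g: (-series[g], g))
        markers[str(c)] = list(order)
        min_lfc[str(c)] = series.loc[order]

    _assert_disjoint(markers)
    return MarkerSet(markers=markers, min_log2fc=min_lfc,
                     fdr_max=fdr_max, log2fc_min=log2fc_min)


def _assert_disjoint(markers: dict[str, list[str]]) -> None:
    seen: dict[str, str] = {}
    for c, genes in markers.items():
        for g in genes:
            if g in seen:
                raise AssertionError(
                    f"gene {g} marks both {seen[g]} and {c}; symmetric "
                    "thresholds should make this impossible")
            seen[g] = c


def build_signature(expr: pd.DataFrame, labels: pd.Series, markers: MarkerSet
                    ) -> pd.DataFrame:
    """Signature matrix: marker-gene union x cell types, mean expression per type."""
    labels = labels.reindex(expr.columns).dropna()
    union = markers.union()
    if not union:
        raise InputError("marker set is empty; cannot build a signature")
    missing = [g for g in union if g not in expr.index]
    if missing:
        raise InputError(f"marker genes absent from expression matrix: {missing[:10]}")
    types = sorted(pd.unique(labels), key=str)
    cols = {}
    for t in types:
        cells = labels.index[labels == t]
        cols[str(t)] = expr.loc[union, cells].mean(axis=1)
    return pd.DataFrame(cols, index=pd.Index(union, name="gene_id"))


def marker_report(markers: MarkerSet, top_n: int = 50) -> pd.DataFrame:
    """Per-cluster summary: marker count, top-n genes, mean top-n log2 fold change.

    The fold change summarized is each marker's minimum log2 fold change over
    all pairwise comparisons (the quantity the selection rule bounds).  When a
    cluster has fewer than ``top_n`` markers all of them are used and the
    truncation is noted.
    """
    rows = []
    for c in sorted(markers.markers, key=str):
        genes = markers.markers[c]
        used = genes[:top_n]
        lfc = markers.min_log2fc[c].loc[used]
        rows.append(
            {
                "cluster": c,
                "n_markers": len(genes),
                "n_used": len(used),
                "truncated": len(genes) < top_n,
                "top_genes": ";".join(used),
                "mean_top_log2fc": float(lfc.mean()) if len(used) else np.nan,
            }
        )
        if len(genes) < top_n:
            log.info("cluster %s has %d markers (< top_n=%d)", c, len(genes), top_n)
    return pd.DataFrame(rows).set_index("cluster")
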