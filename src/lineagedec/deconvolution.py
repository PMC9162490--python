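"""Robust estimation of cell-type fractions in bulk expression profiles.

Each bulk sample y (length = shared genes) is modeled as a non-negative
combination of signature columns, y ~ S b with b >= 0, and the coefficient
vector is normalized to proportions p = b / sum(b).  Estimation is by
non-negative least squares wrapped in a least-trimmed-squares loop: genes
whose residuals are extreme relative to a robust (MAD-based) scale are
excluded and the fit repeated until the excluded set stabilizes.  This
protects the proportion estimates from technology-artifact genes that a
plain NNLS fit would be dragged by.

The trimming hyperparameters (``trim_k`` standard-MAD units, ``trim_cap``
maximum trimmed fraction, ``max_iter``) are all exposed; defaults are
trim_k=3.0, trim_cap=0.25, max_iter=20.  Bulk values are expected on a
linear scale — the model is linear mixing — and a heuristic warning fires
when the input looks log-transformed (max < 50).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .errors import DegenerateFitError, InputError

log = logging.getLogger(__name__)

MAD_TO_SD = 1.4826  # consistency factor of the MAD for a normal scale


@dataclass
class DeconvResult:
    """Fit of one bulk sample: coefficients, proportions and trimmed genes."""

    beta: pd.Series                  # >= 0, one per cell type
    proportions: pd.Series           # beta / sum(beta), sums to 1
    trimmed_genes: list[str]
    residual_norm: float             # on retained genes
    n_iterations: int


@dataclass
class CohortDeconvResult:
    """Per-sample proportions for a cohort plus fit metadata and failures."""

    proportions: pd.DataFrame        # samples x types (NaN rows for failures)
    details: pd.DataFrame            # n_trimmed, residual_norm, n_iterations, ok
    trimmed_genes: dict[str, list[str]]
    failures: dict[str, str]         # sample_id -> error message


def align_genes(signature: pd.DataFrame, bulk: pd.DataFrame
                ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Restrict signature (genes x types) and bulk (samples x genes) to shared genes.

    Matching is case-sensitive and exact.  Raises when the intersection is
    smaller than twice the number of cell types (an under-determined basis).
    """
    shared = signature.index.intersection(bulk.columns)
    k = signature.shape[1]
    if len(shared) < 2 * k:
        raise InputError(
            f"only {len(shared)} shared genes for {k} cell types; need >= {2 * k} "
            f"(signature has {signature.shape[0]}, bulk has {bulk.shape[1]})")
    report = {
        "n_shared": int(len(shared)),
        "dropped_signature": [g for g in signature.index if g not in set(shared)],
        "dropped_bulk": [g for g in bulk.columns if g not in set(shared)],
    }
    aligned_sig = signature.loc[shared]
    cond = np.linalg.cond(aligned_sig.to_numpy())
    if cond > 1e8:
        log.warning("signature condition number %.3g > 1e8; estimates may be unstable", cond)
    if bulk.shape[1] and np.nanmax(bulk.to_numpy()) < 50:
        log.warning("bulk maximum < 50: values may be log-transformed; the model "
                    "assumes linear-scale mixing")
    return aligned_sig, bulk.loc[:, shared], report


def nnls_fit(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve min ||y - S b||^2 subject to b >= 0 (Lawson–Hanson active set)."""
    S = np.asarray(S, dtype=float)
    y = np.asarray(y, dtype=float)
    if S.ndim != 2 or S.shape[0] != y.shape[0]:
        raise InputError(f"shape mismatch: S {S.shape} vs y {y.shape}")
    if np.linalg.matrix_rank(S) < S.shape[1]:
        log.warning("rank-deficient signature; NNLS optimum may be non-unique")
    beta, _ = scipy.optimize.nnls(S, y)
    return beta


def lts_deconvolve(S, y, trim_k: float = 3.0, trim_cap: float = 0.25,
                   max_iter: int = 20) -> DeconvResult:
    """Least-trimmed-squares NNLS for one bulk sample.

    Iterates: fit NNLS on currently retained genes; compute residuals
    r = y - S b over all genes; form the robust scale
    s = 1.4826 * median(|r - median(r)|); flag genes with |r| > trim_k * s
    (largest residuals first, never more than ``trim_cap`` of all genes);
    stop when the flagged set stops changing, when the fit is exact (s = 0),
    or after ``max_iter`` rounds.  The final coefficients are refit on the
    retained genes and normalized to proportions.
    """
    if isinstance(S, pd.DataFrame):
        gene_ids, type_ids = list(S.index), list(S.columns)
        S = S.to_numpy(dtype=float)
    else:
        S = np.asarray(S, dtype=float)
        gene_ids = [f"g{i}" for i in range(S.shape[0])]
        type_ids = [f"t{j}" for j in range(S.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != S.shape[0]:
        raise InputError("y length does not match signature rows")

    n_genes = S.shape[0]
    cap = int(np.floor(trim_cap * n_genes))
    # a residual scale at rounding-error level means the fit is exact
    scale_floor = 1e-9 * max(1.0, float(np.median(np.abs(y))))
    flagged = np.zeros(n_genes, dtype=bool)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        retained = ~flagged
        beta = nnls_fit(S[retained], y[retained])
        r = y - S @ beta
        med = np.median(r)
        s = MAD_TO_SD * np.median(np.abs(r - med))
        if s <= scale_floor:
            break
        abs_r = np.abs(r)
        new_flagged = abs_r > trim_k * s
        if new_flagged.sum() > cap:
            order = np.argsort(-abs_r)
            keep_flag = np.zeros(n_genes, dtype=bool)
            keep_flag[order[:cap]] = True
            new_flagged &= keep_flag
        if np.array_equal(new_flagged, flagged):
            break
        flagged = new_flagged

    retained = ~flagged
    beta = nnls_fit(S[retained], y[retained])
    total = beta.sum()
    if total == 0.0:
        raise DegenerateFitError("all coefficients are zero; sample cannot be decomposed")
    residual_norm = float(np.linalg.norm(y[retained] - S[retained] @ beta))
    beta_s = pd.Series(beta, index=type_ids, name="beta")
    return DeconvResult(
        beta=beta_s,
        proportions=beta_s / total,
        trimmed_genes=[gene_ids[i] for i in np.flatnonzero(flagged)],
        residual_norm=residual_norm,
        n_iterations=n_iter,
    )


def deconvolve_cohort(signature: pd.DataFrame, bulk: pd.DataFrame,
                      trim_k: float = 3.0, trim_cap: float = 0.25,
                      max_iter: int = 20) -> CohortDeconvResult:
    """Apply :func:`lts_deconvolve` independently to every bulk sample.

    Degenerate samples are recorded with NaN proportions and the run
    continues; results are independent of sample order.
    """
    sig, blk, _ = align_genes(signature, bulk)
    props = pd.DataFrame(np.nan, index=blk.index, columns=sig.columns)
    details = pd.DataFrame(
        {"n_trimmed": 0, "residual_norm": np.nan, "n_iterations": 0, "ok": False},
        index=blk.index,
    )
    trimmed: dict[str, list[str]] = {}
    failures: dict[str, str] = {}
    for sample in blk.index:
        try:
            res = lts_deconvolve(sig, blk.loc[sample].to_numpy(),
                                 trim_k=trim_k, trim_cap=trim_cap, max_iter=max_iter)
        except DegenerateFitError as exc:
            failures[sample] = str(exc)
            log.warning("sample %s: %s", sample, exc)
            continue
        props.loc[sample] = res.proportions
        details.loc[sample, ["n_trimmed", "residual_norm", "n_iterations", "ok"]] = (
            len(res.trimmed_genes), res.residual_norm, res.n_iterations, True)
        trimmed[sample] = res.trimmed_genes
    if failures:
        log.warning("%d/%d samples degenerate: %s", len(failures), blk.shape[0],
                    sorted(failures))
    return CohortDeconvResult(proportions=props, details=details,
                              trimmed_genes=trimmed, failures=failures)
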