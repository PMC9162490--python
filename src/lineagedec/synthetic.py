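"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the structure of the real inputs — clustered
single-cell counts with planted cluster markers of controlled fold change,
bulk samples that are convex combinations of cell-type profiles plus noise
and planted outlier genes, clinical tables whose hazard depends on lineage
fractions, and cells carrying planted chromosomal gains or losses — so that
marker selection, deconvolution, subtyping, survival testing and CNV scoring
can all be benchmarked against a recorded truth object without any download.

No attempt is made to mimic realistic bladder biology (dropout structure,
doublets, ambient RNA); counts are plain negative-binomial draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

log = logging.getLogger(__name__)

#: Default lineage names, in the order used throughout the package.
LINEAGES = ("basal", "intermediate", "umbrella", "TNNT1+", "EMT-like")

# Fixed offsets expanding one global seed into per-component child seeds.
_SEED_OFFSETS = {"sc": 11, "bulk": 23, "clinical": 37, "cnv": 53}


def child_seed(seed: int, component: str) -> int:
    """Derive the child seed for one generator component from the global seed."""
    s = (int(seed) + _SEED_OFFSETS[component]) % (2**31)
    log.info("component %s uses child seed %d (global seed %d)", component, s, seed)
    return s


def _type_names(n_types: int) -> list[str]:
    if n_types <= len(LINEAGES):
        return list(LINEAGES[:n_types])
    return list(LINEAGES) + [f"type{i}" for i in range(len(LINEAGES), n_types)]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class ScSimConfig:
    """Parameters of the clustered single-cell count simulation.

    Markers are planted per type: their negative-binomial mean is multiplied
    by ``2**marker_log2fc`` in cells of their own type only.  Mitochondrial
    genes are the first ``mito_gene_count`` gene ids, carry an ``MT-`` prefix
    and a ``mito_mean_factor``-fold elevated baseline so the mitochondrial
    QC predicate operates on realistic fractions.  A fraction
    ``qc_fail_fraction`` of cells is engineered to fail each QC predicate
    (relative to the thresholds stated here) so the filter is testable.
    """

    n_types: int = 5
    cells_per_type: int = 200
    n_genes: int = 2000
    markers_per_type: int = 25
    marker_log2fc: float = 2.0
    nb_dispersion: float = 2.0
    baseline_mean: float = 0.5
    mito_gene_count: int = 13
    seed: int = 0
    # QC planting (defaulted extensions; the thresholds mirror qc_filter's)
    qc_fail_fraction: float = 0.03
    qc_min_features: int = 200
    qc_max_features: int = 4000
    qc_max_mito: float = 0.10
    mito_mean_factor: float = 5.0

    def __post_init__(self) -> None:
        for name in ("n_types", "cells_per_type", "n_genes", "markers_per_type",
                     "mito_gene_count"):
            if int(getattr(self, name)) < 1 and name != "mito_gene_count":
                raise ConfigurationError(f"{name} must be >= 1")
        if self.mito_gene_count < 0:
            raise ConfigurationError("mito_gene_count must be >= 0")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ConfigurationError("nb_dispersion and baseline_mean must be > 0")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ConfigurationError(
                "markers_per_type * n_types exceeds n_genes "
                f"({self.markers_per_type} * {self.n_types} > {self.n_genes})")
        if self.mito_gene_count + self.markers_per_type * self.n_types > self.n_genes:
            raise ConfigurationError(
                "mito genes and marker blocks overlap: need "
                f"{self.mito_gene_count + self.markers_per_type * self.n_types} "
                f"genes, have {self.n_genes}")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ConfigurationError("qc_fail_fraction must be in [0, 1)")


@dataclass
class BulkSimConfig:
    """Parameters of the bulk mixture simulation.

    Each sample's expectation is ``signature @ proportions`` with proportions
    drawn from a Dirichlet; multiplicative log-normal noise (sd ``noise_sd``
    on the log scale) and cohort-wide planted outlier genes (multiplied by
    ``outlier_magnitude``) are applied on top.
    """

    n_samples: int = 50
    dirichlet_alpha: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 1.0)
    noise_sd: float = 0.05
    outlier_gene_fraction: float = 0.0
    outlier_magnitude: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        alpha = np.asarray(self.dirichlet_alpha, dtype=float)
        if alpha.ndim != 1 or (alpha <= 0).any():
            raise ConfigurationError("dirichlet_alpha must be positive reals")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.outlier_gene_fraction < 1:
            raise ConfigurationError("outlier_gene_fraction must be in [0, 1)")
        if self.outlier_magnitude <= 1:
            raise ConfigurationError("outlier_magnitude must be > 1")


@dataclass
class ClinicalSimConfig:
    """Parameters of the clinical-table simulation.

    Survival times are exponential with per-sample hazard
    ``baseline_hazard * exp(log_hr_per_lineage . proportions)`` (months^-1);
    censoring is independent: with probability ``censor_rate`` a subject
    receives a uniform censoring time on ``[0, max_followup_months]``, and
    follow-up is administratively truncated at ``max_followup_months``.
    The T_high indicator is Bernoulli with logit
    ``stage_logit_coefs . proportions``; the N+ indicator uses the same
    linear predictor shifted by -1.
    """

    baseline_hazard: float = 0.02
    log_hr_per_lineage: Sequence[float] = (0.0, 0.0, 0.0, 0.0, 0.0)
    censor_rate: float = 0.2
    max_followup_months: float = 120.0
    stage_logit_coefs: Sequence[float] = (0.0, 0.0, 0.0, 0.0, 0.0)
    low_grade_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.baseline_hazard) and self.baseline_hazard > 0):
            raise ConfigurationError("baseline_hazard must be finite and > 0")
        if not all(math.isfinite(x) for x in self.log_hr_per_lineage):
            raise ConfigurationError("log_hr_per_lineage must be finite")
        if self.censor_rate < 0 or self.censor_rate > 1:
            raise ConfigurationError("censor_rate must be in [0, 1]")
        if not self.max_followup_months > 0:
            raise ConfigurationError("max_followup_months must be > 0")
        if self.censor_rate > 0 and not math.isfinite(self.max_followup_months):
            raise ConfigurationError(
                "uniform censoring requires finite max_followup_months")
        if not 0 <= self.low_grade_fraction < 1:
            raise ConfigurationError("low_grade_fraction must be in [0, 1)")


@dataclass
class CnvSimConfig:
    """Planted copy-number events.

    ``segments`` is a list of ``(chromosome, start_index, end_index,
    copy_ratio)`` tuples; indices are 0-based inclusive positions within the
    chromosome's genomic gene ordering.  In a random ``affected_cell_fraction``
    of cells, counts of genes inside each segment are scaled by ``copy_ratio``
    and re-rounded to integers.
    """

    segments: Sequence[tuple] = ()
    affected_cell_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for seg in self.segments:
            chrom, start, end, ratio = seg
            if start > end:
                raise ConfigurationError(f"segment on {chrom}: start {start} > end {end}")
            if not ratio > 0:
                raise ConfigurationError(f"segment on {chrom}: copy_ratio must be > 0")
        if not 0 <= self.affected_cell_fraction <= 1:
            raise ConfigurationError("affected_cell_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators; fields are filled per stage."""

    type_labels: pd.Series | None = None          # cell_id -> type
    marker_sets: dict[str, list[str]] | None = None
    qc_failures: dict[str, str] | None = None     # cell_id -> predicate failed
    proportions: pd.DataFrame | None = None       # samples x types, rows sum to 1
    outlier_genes: list[str] | None = None        # cohort-wide planted outliers
    hazard: dict | None = None                    # hazard parameters used
    cnv_segments: list[dict] | None = None
    cnv_affected_cells: list[str] | None = None

    def to_json(self, path) -> None:
        payload: dict = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if isinstance(v, pd.Series):
                payload[f.name] = {"index": list(v.index), "values": list(v.values)}
            elif isinstance(v, pd.DataFrame):
                payload[f.name] = {
                    "index": list(v.index),
                    "columns": list(v.columns),
                    "values": v.values.tolist(),
                }
            else:
                payload[f.name] = v
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in payload:
                continue
            v = payload[f.name]
            if f.name == "type_labels":
                kwargs[f.name] = pd.Series(v["values"], index=v["index"], name="type")
            elif f.name == "proportions":
                kwargs[f.name] = pd.DataFrame(
                    v["values"], index=v["index"], columns=v["columns"])
            elif f.name == "cnv_segments":
                kwargs[f.name] = [dict(d) for d in v]
            else:
                kwargs[f.name] = v
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance ``mean + mean**2/dispersion``."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_sc(config: ScSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate a clustered genes x cells count matrix with planted markers.

    Returns ``(counts, annotations, truth)`` where ``counts`` is a genes x
    cells integer DataFrame, ``annotations`` carries per-cell ``sample_id``,
    ``n_features``, ``mito_fraction`` and ``cluster_label``, and ``truth``
    records the type labels, the disjoint planted marker sets and the cells
    engineered to fail each QC predicate.
    """
    rng = np.random.default_rng(child_seed(config.seed, "sc"))
    n_cells = config.n_types * config.cells_per_type
    types = _type_names(config.n_types)

    gene_ids = [f"MT-G{i + 1}" for i in range(config.mito_gene_count)]
    gene_ids += [f"G{i:05d}" for i in range(config.n_genes - config.mito_gene_count)]
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    labels = np.repeat(types, config.cells_per_type)

    mean = np.full((config.n_genes, n_cells), config.baseline_mean)
    mean[: config.mito_gene_count, :] *= config.mito_mean_factor

    marker_sets: dict[str, list[str]] = {}
    for t, name in enumerate(types):
        lo = config.mito_gene_count + t * config.markers_per_type
        hi = lo + config.markers_per_type
        marker_sets[name] = gene_ids[lo:hi]
        mean[lo:hi, labels == name] *= 2.0 ** config.marker_log2fc

    counts = _nb_draw(rng, mean, config.nb_dispersion).astype(np.int64)

    qc_failures = _plant_qc_failures(rng, counts, config)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=cell_ids)
    totals = counts.sum(axis=0)
    mito_counts = counts[: config.mito_gene_count, :].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), np.nan)
    annotations = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": rng.choice(["donor1", "donor2", "donor3"], size=n_cells),
            "n_features": (counts > 0).sum(axis=0),
            "mito_fraction": mito_frac,
            "cluster_label": labels,
        }
    ).set_index("cell_id", drop=False)

    truth = SyntheticTruth(
        type_labels=pd.Series(labels, index=cell_ids, name="type"),
        marker_sets=marker_sets,
        qc_failures=qc_failures,
    )
    return counts_df, annotations, truth


def _plant_qc_failures(rng: np.random.Generator, counts: np.ndarray,
                       config: ScSimConfig) -> dict[str, str]:
    """Corrupt a disjoint subset of cells so each QC predicate fires; in place."""
    n_genes, n_cells = counts.shape
    n_fail = int(round(config.qc_fail_fraction * n_cells))
    if n_fail == 0:
        return {}
    predicates = ["low_features", "high_mito"]
    if n_genes > config.qc_max_features:
        predicates.append("high_features")
    else:
        log.info("n_genes <= qc_max_features; high-feature failures not plantable")
    need = n_fail * len(predicates)
    if need > n_cells:
        raise ConfigurationError("qc_fail_fraction too large for cell count")
    chosen = rng.choice(n_cells, size=need, replace=False)
    failures: dict[str, str] = {}
    for p_idx, predicate in enumerate(predicates):
        for j in chosen[p_idx * n_fail:(p_idx + 1) * n_fail]:
            col = counts[:, j]
            if predicate == "low_features":
                keep = int(rng.integers(1, max(config.qc_min_features, 2)))
                nz = np.flatnonzero(col)
                if nz.size == 0:
                    col[rng.integers(config.mito_gene_count, n_genes)] = 1
                elif nz.size > keep:
                    drop = rng.choice(nz, size=nz.size - keep, replace=False)
                    col[drop] = 0
            elif predicate == "high_mito":
                if config.mito_gene_count == 0:
                    continue
                nonmito = int(col[config.mito_gene_count:].sum())
                target = min(0.95, 1.5 * config.qc_max_mito)
                needed = int(math.ceil(target / (1 - target) * max(nonmito, 1))) + 1
                col[: config.mito_gene_count] = 0
                col[0] = needed
            else:  # high_features
                target = min(n_genes, config.qc_max_features + 1 +
                             int(rng.integers(0, max(n_genes - config.qc_max_features, 2))))
                zeros = np.flatnonzero(col == 0)
                add = target - (n_genes - zeros.size)
                if add > 0:
                    col[rng.choice(zeros, size=min(add, zeros.size), replace=False)] = 1
            failures[f"cell{j:05d}"] = predicate
    return failures


def simulate_bulk(signature: pd.DataFrame, config: BulkSimConfig
                  ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate bulk samples as noisy convex combinations of signature columns.

    ``signature`` is genes x types.  Returns ``(bulk, truth)`` with ``bulk``
    samples x genes and ``truth.proportions`` the Dirichlet mixing weights
    (rows sum to 1) plus the cohort-wide planted outlier genes.
    """
    sig = np.asarray(signature.values, dtype=float)
    if (sig < 0).any():
        raise InputError("signature must be non-negative")
    n_types = signature.shape[1]
    alpha = np.asarray(config.dirichlet_alpha, dtype=float)
    if alpha.size != n_types:
        raise ConfigurationError(
            f"dirichlet_alpha length {alpha.size} != {n_types} signature columns")

    rng = np.random.default_rng(child_seed(config.seed, "bulk"))
    props = rng.dirichlet(alpha, size=config.n_samples)
    props = props / props.sum(axis=1, keepdims=True)  # exact row sums

    values = props @ sig.T  # samples x genes
    if config.noise_sd > 0:
        values = values * np.exp(rng.normal(0.0, config.noise_sd, size=values.shape))

    n_genes = signature.shape[0]
    n_out = int(round(config.outlier_gene_fraction * n_genes))
    outlier_idx = np.sort(rng.choice(n_genes, size=n_out, replace=False)) if n_out else []
    outliers = [signature.index[i] for i in outlier_idx]
    if n_out:
        values[:, outlier_idx] *= config.outlier_magnitude

    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    bulk = pd.DataFrame(values, index=sample_ids, columns=signature.index)
    truth = SyntheticTruth(
        proportions=pd.DataFrame(props, index=sample_ids, columns=signature.columns),
        outlier_genes=list(outliers),
    )
    return bulk, truth


def simulate_clinical(true_proportions: pd.DataFrame, config: ClinicalSimConfig
                      ) -> pd.DataFrame:
    """Simulate a clinical table whose hazard depends on lineage fractions.

    Returns a DataFrame indexed by sample_id with columns ``t_stage``,
    ``n_stage``, ``grade``, ``os_months``, ``os_event``.
    """
    P = np.asarray(true_proportions.values, dtype=float)
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise InputError("true_proportions rows must sum to 1")
    log_hr = np.asarray(config.log_hr_per_lineage, dtype=float)
    if log_hr.size != P.shape[1]:
        raise ConfigurationError(
            f"log_hr_per_lineage length {log_hr.size} != {P.shape[1]} lineages")
    stage_coefs = np.asarray(config.stage_logit_coefs, dtype=float)
    if stage_coefs.size != P.shape[1]:
        raise ConfigurationError("stage_logit_coefs length mismatch")

    hazard = config.baseline_hazard * np.exp(P @ log_hr)
    if not np.isfinite(hazard).all():
        raise ConfigurationError("non-finite hazard")

    rng = np.random.default_rng(child_seed(config.seed, "clinical"))
    n = P.shape[0]
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.full(n, np.inf)
    censored = rng.random(n) < config.censor_rate
    if censored.any():
        censor_time[censored] = rng.uniform(0, config.max_followup_months,
                                            size=int(censored.sum()))
    limit = min(np.inf, config.max_followup_months)
    horizon = np.minimum(censor_time, limit)
    os_months = np.minimum(event_time, horizon)
    os_event = (event_time <= horizon).astype(int)

    t_logit = P @ stage_coefs
    t_high = rng.random(n) < 1.0 / (1.0 + np.exp(-t_logit))
    n_plus = rng.random(n) < 1.0 / (1.0 + np.exp(-(t_logit - 1.0)))
    t_stage = np.where(t_high, rng.choice(["T3", "T4"], size=n),
                       rng.choice(["T1", "T2"], size=n))
    n_stage = np.where(n_plus, rng.choice(["N1", "N2"], size=n), "N0")
    grade = np.where(rng.random(n) < config.low_grade_fraction, "low", "high")

    return pd.DataFrame(
        {
            "t_stage": t_stage,
            "n_stage": n_stage,
            "grade": grade,
            "os_months": os_months,
            "os_event": os_event,
        },
        index=pd.Index(true_proportions.index, name="sample_id"),
    )


def emt_survival_scenario(n_samples: int, seed: int, hazard_ratio: float = 2.0,
                          null: bool = False
                          ) -> tuple[pd.DataFrame, pd.DataFrame, ClinicalSimConfig]:
    """Two-arm prognostic benchmark cohort with a planted EMT-like hazard ratio.

    Half the samples are drawn EMT-rich (Dirichlet alpha ``(1,1,1,1,8)``) and
    half EMT-poor (``(2,2,2,2,0.5)``), mimicking dominant-lineage versus
    mixture-like tumors.  The per-unit-fraction log hazard ratio on the
    EMT-like lineage is calibrated so the planted hazard ratio between the
    two designed arms equals ``hazard_ratio``:
    ``log_hr = log(hazard_ratio) / (E[f_EMT | rich] - E[f_EMT | poor])``
    with the Dirichlet means 8/12 and 0.5/8.5.  Under ``null=True`` all log
    hazard ratios are zero and the same cohort tests the type-I error of the
    downstream pipeline.  Returns (proportions, clinical table, the clinical
    config used).
    """
    rng = np.random.default_rng(int(seed) % (2**31))
    alpha_rich = np.array([1.0, 1.0, 1.0, 1.0, 8.0])
    alpha_poor = np.array([2.0, 2.0, 2.0, 2.0, 0.5])
    n_rich = n_samples // 2
    props = np.vstack([rng.dirichlet(alpha_rich, size=n_rich),
                       rng.dirichlet(alpha_poor, size=n_samples - n_rich)])
    props = props / props.sum(axis=1, keepdims=True)
    proportions = pd.DataFrame(
        props, index=[f"S{i:04d}" for i in range(n_samples)], columns=list(LINEAGES))
    gap = alpha_rich[-1] / alpha_rich.sum() - alpha_poor[-1] / alpha_poor.sum()
    log_hr_emt = 0.0 if null else math.log(hazard_ratio) / gap
    config = ClinicalSimConfig(
        baseline_hazard=0.02,
        log_hr_per_lineage=(0.0, 0.0, 0.0, 0.0, log_hr_emt),
        censor_rate=0.2,
        max_followup_months=120.0,
        stage_logit_coefs=(0.0, 0.0, 0.0, 0.0, 0.0),
        seed=int(rng.integers(0, 2**31 - 64)),
    )
    return proportions, simulate_clinical(proportions, config), config


def simulate_cnv(base: pd.DataFrame, positions: pd.DataFrame, config: CnvSimConfig
                 ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Plant copy-number events into a genes x cells count matrix.

    ``positions`` must carry columns ``gene_id``, ``chromosome``, ``start``.
    In a random ``affected_cell_fraction`` of cells, counts of genes inside
    each segment are scaled by its copy_ratio and re-rounded.
    """
    pos = positions.set_index("gene_id") if "gene_id" in positions.columns else positions
    by_chrom: dict[str, list[str]] = {}
    present = pos.loc[pos.index.isin(base.index)]
    for chrom, sub in present.groupby("chromosome", sort=False):
        by_chrom[str(chrom)] = list(sub.sort_values("start").index)

    rng = np.random.default_rng(child_seed(config.seed, "cnv"))
    n_cells = base.shape[1]
    n_aff = int(round(config.affected_cell_fraction * n_cells))
    affected = sorted(rng.choice(base.columns, size=n_aff, replace=False).tolist())

    out = base.copy()
    seg_records = []
    for chrom, start, end, ratio in config.segments:
        chrom = str(chrom)
        if chrom not in by_chrom:
            raise InputError(f"unknown chromosome in segment: {chrom!r}")
        genes = by_chrom[chrom]
        if end >= len(genes):
            raise InputError(
                f"segment [{start}, {end}] exceeds {len(genes)} genes on {chrom}")
        seg_genes = genes[start:end + 1]
        if n_aff and ratio != 1.0:
            block = out.loc[seg_genes, affected].to_numpy(dtype=float)
            out.loc[seg_genes, affected] = np.rint(block * ratio).astype(np.int64)
        seg_records.append({"chromosome": chrom, "start_index": int(start),
                            "end_index": int(end), "copy_ratio": float(ratio),
                            "genes": seg_genes})

    truth = SyntheticTruth(cnv_segments=seg_records, cnv_affected_cells=affected)
    return out, truth
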