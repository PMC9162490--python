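"""Tumor subtyping from lineage fractions and stage / survival association.

The analysis graph mirrors the deconvolution-to-prognosis workflow: merge
closely related lineages (basal + intermediate), call a dominant-lineage
subtype when any fraction exceeds 0.4 (otherwise "mixture"), compare
fractions between dichotomized T (T1-2 vs T3-4) and N (N0 vs N+) stages by
rank-sum tests, then — after cohort filters (low-grade / not-available
removal, optional strict OS > 100-month exclusion) — dichotomize each
lineage fraction at the cohort median and compare overall survival by
Kaplan-Meier curves and log-rank tests, including each dominant subtype
against the mixture reference group.

Conventions that matter and are easy to get wrong:

* the subtype threshold is strict (a fraction of exactly 0.4 is "mixture");
* ties at the dichotomization median go to "low" (high means strictly above);
* the OS cap drops months > 100 strictly (exactly 100 is kept);
* the median is computed after all cohort filters, per dataset;
* no multiple-testing correction across lineages by default (a Bonferroni
  column is available but off).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import EmptyResultError, InputError

log = logging.getLogger(__name__)

DEFAULT_MERGE_MAP = {"basal/intermediate": ("basal", "intermediate")}
SUBTYPE_THRESHOLD = 0.4
MIXTURE_LABEL = "mixture"


# ---------------------------------------------------------------------------
# subtyping
# ---------------------------------------------------------------------------


def merge_lineages(proportions: pd.DataFrame,
                   merge_map: dict | None = None) -> pd.DataFrame:
    """Sum groups of lineage columns into merged columns.

    ``merge_map`` maps new column name -> iterable of existing columns; an
    empty or None map is the identity.  Row sums are preserved exactly.
    """
    if not merge_map:
        return proportions.copy()
    out = proportions.copy()
    for new, sources in merge_map.items():
        sources = list(sources)
        missing = [s for s in sources if s not in out.columns]
        if missing:
            raise InputError(f"merge_lineages: unknown columns {missing}")
        pos = min(out.columns.get_loc(s) for s in sources)
        merged = out[sources].sum(axis=1)
        out = out.drop(columns=sources)
        out.insert(min(pos, out.shape[1]), new, merged)
    return out


def assign_subtype(proportions: pd.DataFrame,
                   threshold: float = SUBTYPE_THRESHOLD) -> pd.DataFrame:
    """Dominant-lineage subtype call per sample.

    A sample is labeled by its argmax lineage when that fraction strictly
    exceeds ``threshold``; otherwise it is "mixture".  Ties at the maximum
    are broken by lexicographic lineage name (logged).  Rows must sum to 1
    within 1e-6.
    """
    vals = proportions.to_numpy(dtype=float)
    sums = vals.sum(axis=1)
    bad = ~np.isclose(sums, 1.0, atol=1e-6)
    if bad.any():
        raise InputError(
            f"proportion rows do not sum to 1 (e.g. {proportions.index[bad][:3].tolist()})")
    cols = np.asarray([str(c) for c in proportions.columns])
    order = np.argsort(cols, kind="stable")  # lexicographic tie-break
    dominant = vals.max(axis=1)
    labels = []
    for i in range(vals.shape[0]):
        if dominant[i] > threshold:
            tied = cols[np.isclose(vals[i], dominant[i], rtol=0, atol=0)]
            if tied.size > 1:
                log.warning("sample %s: tie between %s; taking %s",
                            proportions.index[i], list(tied), sorted(tied)[0])
            labels.append(sorted(tied)[0])
        else:
            labels.append(MIXTURE_LABEL)
    return pd.DataFrame(
        {"label": labels, "dominant_fraction": dominant},
        index=pd.Index(proportions.index, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# staging
# ---------------------------------------------------------------------------

_T_RE = re.compile(r"^T([0-4]|IS|A|X)([ABC])?$", re.IGNORECASE)
_N_RE = re.compile(r"^N([0-3]|X)([ABC])?$", re.IGNORECASE)


def t_group(stage) -> str:
    """Map a T-stage string to 'T_low' (T1-2), 'T_high' (T3-4) or 'missing'."""
    if stage is None or (isinstance(stage, float) and np.isnan(stage)):
        return "missing"
    m = _T_RE.match(str(stage).strip())
    if not m:
        log.warning("unparseable T stage %r -> missing", stage)
        return "missing"
    code = m.group(1).upper()
    if code in {"1", "2"}:
        return "T_low"
    if code in {"3", "4"}:
        return "T_high"
    return "missing"  # T0 / Tis / Ta / TX are outside the dichotomy


def n_group(stage) -> str:
    """Map an N-stage string to 'N0', 'N_plus' (N1-3) or 'missing'."""
    if stage is None or (isinstance(stage, float) and np.isnan(stage)):
        return "missing"
    m = _N_RE.match(str(stage).strip())
    if not m:
        log.warning("unparseable N stage %r -> missing", stage)
        return "missing"
    code = m.group(1).upper()
    if code == "0":
        return "N0"
    if code in {"1", "2", "3"}:
        return "N_plus"
    return "missing"


def stage_dichotomize(clinical: pd.DataFrame) -> pd.DataFrame:
    """Add ``t_group`` / ``n_group`` columns per the T1-2 vs T3-4 and N0 vs N+ split."""
    out = clinical.copy()
    out["t_group"] = [t_group(s) for s in clinical["t_stage"]]
    out["n_group"] = [n_group(s) for s in clinical["n_stage"]]
    return out


def ranksum_stage_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two groups of lineage fractions.

    Exact null enumeration when both groups have <= 8 samples, tie-corrected
    normal approximation otherwise.  Returns (U, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("both groups need >= 2 samples")
    method = "exact" if max(a.size, b.size) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# cohort filters and survival
# ---------------------------------------------------------------------------


def filter_cohort(clinical: pd.DataFrame, drop_low_grade: bool = True,
                  drop_missing: bool = True, max_os_months: float | None = None
                  ) -> tuple[pd.DataFrame, dict]:
    """Apply the cohort filters; returns (filtered table, per-reason counts).

    ``drop_low_grade`` removes grade == "low"; ``drop_missing`` removes
    records with missing grade or missing OS fields; ``max_os_months`` (when
    set) strictly drops os_months > cap, so a record at exactly the cap is
    kept.  An empty result is allowed with a warning.
    """
    report = {"low_grade": 0, "missing": 0, "os_cap": 0, "kept": 0}
    keep = pd.Series(True, index=clinical.index)
    grade = clinical["grade"].astype(object)
    missing = clinical["os_months"].isna() | clinical["os_event"].isna() | grade.isna()
    if drop_missing:
        report["missing"] = int((keep & missing).sum())
        keep &= ~missing
    if drop_low_grade:
        low = (grade == "low") & keep
        report["low_grade"] = int(low.sum())
        keep &= ~(grade == "low")
    if max_os_months is not None:
        over = (clinical["os_months"] > max_os_months) & keep
        report["os_cap"] = int(over.sum())
        keep &= ~(clinical["os_months"] > max_os_months)
    report["kept"] = int(keep.sum())
    if report["kept"] == 0:
        log.warning("cohort filters removed every record")
    return clinical.loc[keep], report


def median_dichotomize(scores: pd.Series) -> pd.Series:
    """Label scores 'high' (strictly above the median) or 'low' (at or below).

    The median is that of the scores passed in — i.e. of the current,
    already-filtered dataset.  Raises when all scores are identical (no split).
    """
    s = pd.Series(scores, dtype=float)
    if s.size < 4:
        raise InputError(f"need >= 4 samples to dichotomize, got {s.size}")
    if s.nunique() == 1:
        raise InputError("all scores identical; median split impossible")
    med = float(s.median())
    return pd.Series(np.where(s > med, "high", "low"), index=s.index, name="group")


@dataclass
class SurvivalCurve:
    """Product-limit estimate evaluated at the event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Censored subjects leave the risk set without a survival drop; at tied
    times events are counted before censorings.  The curve is reported at
    the distinct event times.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise InputError("empty survival input")
    if (t < 0).any():
        raise InputError("negative survival times")
    if not np.isin(e, [0, 1]).all():
        raise InputError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    surv = np.asarray([float(kmf.predict(x)) for x in event_times])
    return SurvivalCurve(event_times=event_times, survival_prob=surv,
                         n_at_risk=ev["at_risk"].to_numpy(dtype=int))


def logrank_test(times, events, groups) -> tuple[float, float, int]:
    """k-group log-rank test; returns (chi-square statistic, p, df)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if t.size != e.size or t.size != g.size:
        raise InputError("times, events and groups must have equal length")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise InputError("log-rank needs >= 2 groups")
    if (counts == 0).any():
        raise InputError("log-rank group with zero subjects")
    if e.sum() < 1:
        raise InputError("log-rank needs at least one event")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value), int(labels.size - 1)


# ---------------------------------------------------------------------------
# end-to-end report
# ---------------------------------------------------------------------------


@dataclass
class PrognosisConfig:
    threshold: float = SUBTYPE_THRESHOLD
    merge_map: dict | None = None          # None -> DEFAULT_MERGE_MAP when applicable
    drop_low_grade: bool = True
    drop_missing: bool = True
    max_os_months: float | None = None     # the strict OS cap; default off
    bonferroni: bool = False


@dataclass
class PrognosisReport:
    proportions: pd.DataFrame      # after lineage merging, aligned to clinical
    subtypes: pd.DataFrame
    stage_tests: pd.DataFrame      # lineage x comparison: U, p, group sizes
    filter_report: dict
    survival_by_lineage: pd.DataFrame   # median high/low log-rank per lineage
    survival_by_subtype: pd.DataFrame   # each subtype vs the mixture reference


def _resolve_merge_map(config: PrognosisConfig, columns) -> dict:
    if config.merge_map is not None:
        return config.merge_map
    if all(c in columns for srcs in DEFAULT_MERGE_MAP.values() for c in srcs):
        return DEFAULT_MERGE_MAP
    return {}


def run_prognosis(proportions: pd.DataFrame, clinical: pd.DataFrame,
                  config: PrognosisConfig | None = None) -> PrognosisReport:
    """End-to-end subtype / stage / survival analysis of one cohort.

    Deterministic and invariant to sample order: merge lineages, call
    subtypes, test each lineage fraction across the T and N dichotomies,
    apply the cohort filters, and compare survival (a) between median-split
    high/low groups of each lineage fraction and (b) between each dominant
    subtype and the mixture reference group.
    """
    config = config or PrognosisConfig()
    shared = proportions.index.intersection(clinical.index).sort_values()
    if shared.empty:
        raise InputError("no shared sample ids between proportions and clinical table")
    props = proportions.loc[shared]
    clin = clinical.loc[shared]

    merged = merge_lineages(props, _resolve_merge_map(config, props.columns))
    subtypes = assign_subtype(merged, threshold=config.threshold)
    staged = stage_dichotomize(clin)

    stage_rows = []
    for lineage in merged.columns:
        for comparison, col, lo, hi in (("T_low_vs_T_high", "t_group", "T_low", "T_high"),
                                        ("N0_vs_N_plus", "n_group", "N0", "N_plus")):
            a = merged.loc[staged[col] == lo, lineage]
            b = merged.loc[staged[col] == hi, lineage]
            if len(a) >= 2 and len(b) >= 2:
                u, p = ranksum_stage_test(a, b)
            else:
                u, p = np.nan, np.nan
            stage_rows.append({"lineage": lineage, "comparison": comparison,
                               "n_a": len(a), "n_b": len(b), "U": u, "p": p})
    stage_tests = pd.DataFrame(stage_rows)

    filtered, filter_report = filter_cohort(
        clin, drop_low_grade=config.drop_low_grade,
        drop_missing=config.drop_missing, max_os_months=config.max_os_months)
    surv_props = merged.loc[filtered.index]
    times = filtered["os_months"].to_numpy(dtype=float)
    events = filtered["os_event"].to_numpy(dtype=int)

    lineage_rows = []
    for lineage in merged.columns:
        row = {"lineage": lineage, "n_low": 0, "n_high": 0,
               "chi2": np.nan, "p": np.nan}
        try:
            groups = median_dichotomize(surv_props[lineage])
            chi2, p, _ = logrank_test(times, events, groups.to_numpy())
            row.update(n_low=int((groups == "low").sum()),
                       n_high=int((groups == "high").sum()), chi2=chi2, p=p)
        except (InputError, EmptyResultError) as exc:
            log.warning("lineage %s survival comparison skipped: %s", lineage, exc)
        lineage_rows.append(row)
    survival_by_lineage = pd.DataFrame(lineage_rows)

    sub_filtered = subtypes.loc[filtered.index, "label"]
    mixture_idx = sub_filtered.index[sub_filtered == MIXTURE_LABEL]
    subtype_rows = []
    for label in sorted(set(sub_filtered) - {MIXTURE_LABEL}):
        idx = sub_filtered.index[sub_filtered == label]
        row = {"subtype": label, "n_subtype": len(idx), "n_mixture": len(mixture_idx),
               "chi2": np.nan, "p": np.nan}
        if len(idx) >= 2 and len(mixture_idx) >= 2:
            sel = idx.union(mixture_idx)
            pos = filtered.index.get_indexer(sel)
            try:
                chi2, p, _ = logrank_test(
                    times[pos], events[pos],
                    np.where(sub_filtered.loc[sel] == label, label, MIXTURE_LABEL))
                row.update(chi2=chi2, p=p)
            except InputError as exc:
                log.warning("subtype %s vs mixture skipped: %s", label, exc)
        subtype_rows.append(row)
    survival_by_subtype = pd.DataFrame(
        subtype_rows, columns=["subtype", "n_subtype", "n_mixture", "chi2", "p"])

    if config.bonferroni:
        m = survival_by_lineage["p"].notna().sum()
        survival_by_lineage["p_bonferroni"] = (survival_by_lineage["p"] * m).clip(upper=1.0)

    return PrognosisReport(
        proportions=merged, subtypes=subtypes, stage_tests=stage_tests,
        filter_report=filter_report, survival_by_lineage=survival_by_lineage,
        survival_by_subtype=survival_by_subtype)
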