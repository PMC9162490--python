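"""Subtype calls, stage dichotomies, cohort filters, KM and log-rank tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lineagedec as ld
from lineagedec.clinical import km_estimate, logrank_test, t_group, n_group
from lineagedec.synthetic import emt_survival_scenario


def _props(rows, columns):
    return pd.DataFrame(rows, columns=columns,
                        index=[f"S{i}" for i in range(len(rows))])


class TestMergeLineages:
    def test_additivity(self):
        props = _props([[0.2, 0.3, 0.5]], ["basal", "intermediate", "umbrella"])
        merged = ld.merge_lineages(props, {"basal/intermediate": ("basal", "intermediate")})
        assert merged.loc["S0", "basal/intermediate"] == pytest.approx(0.5)
        assert merged.loc["S0", "umbrella"] == pytest.approx(0.5)
        assert list(merged.columns) == ["basal/intermediate", "umbrella"]

    def test_empty_map_is_identity(self):
        props = _props([[0.4, 0.6]], ["a", "b"])
        pd.testing.assert_frame_equal(ld.merge_lineages(props, {}), props)

    def test_unknown_column_rejected(self):
        props = _props([[1.0]], ["a"])
        with pytest.raises(ld.InputError):
            ld.merge_lineages(props, {"x": ("a", "missing")})

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=500))
    def test_row_sums_preserved(self, seed):
        r = np.random.default_rng(seed)
        props = _props(r.dirichlet(np.ones(4), size=6), ["a", "b", "c", "d"])
        merged = ld.merge_lineages(props, {"ab": ("a", "b")})
        np.testing.assert_allclose(merged.sum(axis=1), props.sum(axis=1), atol=1e-12)


class TestAssignSubtype:
    def test_dominant_lineage_called(self):
        calls = ld.assign_subtype(_props([[0.5, 0.3, 0.1, 0.1]], list("abcd")))
        assert calls.loc["S0", "label"] == "a"
        assert calls.loc["S0", "dominant_fraction"] == pytest.approx(0.5)

    def test_threshold_is_strict(self):
        calls = ld.assign_subtype(_props([[0.4, 0.3, 0.2, 0.1]], list("abcd")))
        assert calls.loc["S0", "label"] == "mixture"

    def test_tie_broken_lexicographically(self):
        calls = ld.assign_subtype(_props([[0.45, 0.45, 0.05, 0.05]],
                                         ["zeta", "alpha", "c", "d"]))
        assert calls.loc["S0", "label"] == "alpha"

    def test_row_sum_violation_rejected(self):
        with pytest.raises(ld.InputError):
            ld.assign_subtype(_props([[0.5, 0.2]], ["a", "b"]))


class TestStageDichotomize:
    @pytest.mark.parametrize("stage,expected", [
        ("T1", "T_low"), ("T2a", "T_low"), ("T2", "T_low"),
        ("T3", "T_high"), ("T4b", "T_high"), ("t3", "T_high"),
        ("TX", "missing"), ("Ta", "missing"), ("Tis", "missing"),
        (None, "missing"), ("garbled", "missing"),
    ])
    def test_t_groups(self, stage, expected):
        assert t_group(stage) == expected

    @pytest.mark.parametrize("stage,expected", [
        ("N0", "N0"), ("N1", "N_plus"), ("N2", "N_plus"), ("N3", "N_plus"),
        ("NX", "missing"), (None, "missing"), ("??", "missing"),
    ])
    def test_n_groups(self, stage, expected):
        assert n_group(stage) == expected

    def test_table_level_columns(self):
        clin = pd.DataFrame({"t_stage": ["T1", "T4"], "n_stage": ["N0", "N2"]},
                            index=["a", "b"])
        out = ld.stage_dichotomize(clin)
        assert list(out["t_group"]) == ["T_low", "T_high"]
        assert list(out["n_group"]) == ["N0", "N_plus"]


class TestRanksumStageTest:
    def test_identical_groups_p_one(self):
        _, p = ld.ranksum_stage_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_enumeration_value(self):
        """{1,2,3} vs {4,5,6}: 2 of the 20 assignments are as extreme."""
        _, p = ld.ranksum_stage_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_large_shift_is_significant(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(3, 1, 200)
        _, p = ld.ranksum_stage_test(a, b)
        assert p < 1e-6

    def test_small_group_rejected(self):
        with pytest.raises(ld.InputError):
            ld.ranksum_stage_test([1], [2, 3])


class TestFilterCohort:
    def _table(self):
        return pd.DataFrame(
            {
                "t_stage": ["T1"] * 6,
                "n_stage": ["N0"] * 6,
                "grade": ["high", "low", "high", None, "high", "high"],
                "os_months": [10.0, 20.0, np.nan, 40.0, 100.0, 130.0],
                "os_event": [1, 0, 1, 1, 0, 1],
            },
            index=[f"P{i}" for i in range(6)],
        )

    def test_reason_counts_match_brute_force(self):
        kept, report = ld.filter_cohort(self._table(), max_os_months=100)
        assert report == {"low_grade": 1, "missing": 2, "os_cap": 1, "kept": 2}
        assert list(kept.index) == ["P0", "P4"]

    def test_os_cap_boundary_kept(self):
        kept, _ = ld.filter_cohort(self._table(), max_os_months=100)
        assert "P4" in kept.index  # os_months == 100 exactly

    def test_flags_off_keep_everything(self):
        kept, report = ld.filter_cohort(self._table(), drop_low_grade=False,
                                        drop_missing=False)
        assert report["kept"] == 6


class TestMedianDichotomize:
    def test_even_split(self):
        groups = ld.median_dichotomize(pd.Series([1, 2, 3, 4]))
        assert list(groups) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        groups = ld.median_dichotomize(pd.Series([1, 2, 2, 3]))
        assert list(groups) == ["low", "low", "low", "high"]

    def test_all_identical_rejected(self):
        with pytest.raises(ld.InputError):
            ld.median_dichotomize(pd.Series([2.0, 2.0, 2.0, 2.0]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=500))
    def test_group_sizes_match_brute_force(self, seed):
        r = np.random.default_rng(seed)
        scores = pd.Series(r.normal(size=11))
        groups = ld.median_dichotomize(scores)
        med = float(np.median(scores))
        assert (groups == "high").sum() == int((scores > med).sum())


def independent_km(times, events):
    """Closed-form product-limit oracle, independent of the implementation."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1 - d / at_risk
        out[t] = s
    return out


class TestKmEstimate:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([3, 5, 7], [0, 0, 0])
        assert curve.event_times.size == 0  # no drops anywhere

    def test_three_events_closed_form(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival_prob, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.n_at_risk, [3, 2, 1])

    def test_censoring_shrinks_risk_set_without_drop(self):
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(curve.survival_prob, [2 / 3, 0.0])
        np.testing.assert_array_equal(curve.event_times, [1, 3])

    def test_matches_independent_oracle_on_small_fixtures(self):
        fixtures = [
            ([1, 1, 2, 3], [1, 1, 0, 1]),
            ([2, 2, 2], [1, 1, 1]),
            ([1, 2, 3, 4, 5, 6, 7, 8], [1, 0, 1, 0, 1, 0, 1, 0]),
            ([5, 1, 3, 1, 4], [0, 1, 1, 1, 1]),
            ([1.5, 1.5, 2.5, 2.5, 9], [1, 0, 1, 0, 0]),
        ]
        for times, events in fixtures:
            curve = km_estimate(times, events)
            oracle = independent_km(times, events)
            assert list(curve.event_times) == sorted(oracle)
            for t, s in zip(curve.event_times, curve.survival_prob):
                assert s == pytest.approx(oracle[t], abs=1e-12), (times, events)

    def test_empty_input_rejected(self):
        with pytest.raises(ld.InputError):
            km_estimate([], [])


def independent_logrank(times, events, groups):
    """Two-group observed-minus-expected chi-square, evaluated directly."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = int(at_risk.sum())
        n0 = int((at_risk & (groups == g0)).sum())
        d = int(((times == t) & (events == 1)).sum())
        d0 = int(((times == t) & (events == 1) & (groups == g0)).sum())
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 0, 1, 1, 1, 0, 1, 1]
        groups = ["a"] * 4 + ["b"] * 4
        chi2, p, df = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_worked_instance_matches_direct_formula(self):
        times = [1, 3, 4, 6, 7, 9, 10, 12, 2, 5]
        events = [1, 1, 0, 1, 1, 0, 1, 1, 1, 1]
        groups = ["a"] * 5 + ["b"] * 5
        chi2, p, df = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(independent_logrank(times, events, groups),
                                     rel=1e-10)

    def test_group_label_swap_invariance(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 0, 1, 1, 1]
        g1 = ["a", "a", "a", "b", "b", "b"]
        g2 = ["b", "b", "b", "a", "a", "a"]
        assert logrank_test(times, events, g1)[0] == pytest.approx(
            logrank_test(times, events, g2)[0])

    def test_no_events_rejected(self):
        with pytest.raises(ld.InputError):
            logrank_test([1, 2], [0, 0], ["a", "b"])

    def test_power_at_hazard_ratio_two(self):
        """Two designed arms with hazard ratio 2, 200 subjects each:
        log-rank rejects at 0.05 in >= 80 of 100 seeded replicates."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(30_000 + seed)
            t1 = r.exponential(1 / 0.02, 200)
            t2 = r.exponential(1 / 0.04, 200)
            times = np.concatenate([t1, t2])
            cens = r.uniform(0, 120, 400)
            keep_event = times <= np.minimum(cens, 120)
            obs = np.minimum(times, np.minimum(cens, 120))
            _, p, _ = logrank_test(obs, keep_event.astype(int),
                                   ["a"] * 200 + ["b"] * 200)
            hits += p < 0.05
        assert hits >= 80


class TestRunPrognosis:
    def test_end_to_end_recovers_planted_hazard(self):
        props, clin, _ = emt_survival_scenario(300, seed=0)
        report = ld.run_prognosis(props, clin)
        row = report.survival_by_lineage.set_index("lineage")
        assert row.loc["EMT-like", "p"] < 0.05

    def test_sample_order_invariance(self):
        props, clin, _ = emt_survival_scenario(120, seed=1)
        r1 = ld.run_prognosis(props, clin)
        perm = np.random.default_rng(0).permutation(len(props))
        r2 = ld.run_prognosis(props.iloc[perm], clin.iloc[perm])
        pd.testing.assert_frame_equal(r1.survival_by_lineage, r2.survival_by_lineage)
        pd.testing.assert_frame_equal(r1.subtypes, r2.subtypes)
        pd.testing.assert_frame_equal(r1.stage_tests, r2.stage_tests)

    def test_default_merge_applied_and_rows_sum(self):
        props, clin, _ = emt_survival_scenario(80, seed=2)
        report = ld.run_prognosis(props, clin)
        assert "basal/intermediate" in report.proportions.columns
        np.testing.assert_allclose(report.proportions.sum(axis=1), 1.0, atol=1e-9)

    def test_planted_hazards_dominate_lineage_ranking(self):
        """A hazardous and a protective planted lineage occupy the two top
        log-rank statistics, ahead of the two null lineages, in >= 90% of seeds."""
        top = 0
        for seed in range(20):
            r = np.random.default_rng(40_000 + seed)
            p = r.dirichlet(np.ones(4) * 0.4, size=300)
            props = pd.DataFrame(p / p.sum(1, keepdims=True),
                                 index=[f"S{i}" for i in range(300)],
                                 columns=["w", "x", "y", "z"])
            clin = ld.simulate_clinical(props, ld.ClinicalSimConfig(
                log_hr_per_lineage=(2.5, 0.0, 0.0, -2.5),
                stage_logit_coefs=(0, 0, 0, 0), censor_rate=0.1, seed=seed))
            report = ld.run_prognosis(props, clin, ld.PrognosisConfig(merge_map={}))
            ranked = report.survival_by_lineage.sort_values("chi2", ascending=False)
            if set(ranked["lineage"].iloc[:2]) == {"w", "z"}:
                top += 1
        assert top >= 18

    def test_empty_id_intersection_rejected(self):
        props, clin, _ = emt_survival_scenario(20, seed=3)
        clin2 = clin.copy()
        clin2.index = [f"other{i}" for i in range(len(clin2))]
        with pytest.raises(ld.InputError):
            ld.run_prognosis(props, clin2)
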