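"""Per-code significance testing, Storey q-values and DD construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from ddri.differential import (
    MANN_WHITNEY,
    T_TEST,
    build_diagnosis_table,
    choose_test,
    differential_distribution,
    group_by_code,
    mann_whitney_exact_p,
    storey_qvalues,
)
from ddri.differential import test_group as group_p_value

from util import benjamini_hochberg, brute_force_mwu_p, make_stratum


class TestGroupByCode:
    def test_result_with_k_codes_contributes_to_k_groups(self):
        s = make_stratum([4.4, 3.9], [("N18", "I10"), ()])
        groups = group_by_code(s)
        assert set(groups) == {"N18", "I10"}
        assert groups["N18"].tolist() == [4.4] and groups["I10"].tolist() == [4.4]

    def test_uncoded_stratum_yields_empty_mapping(self):
        assert group_by_code(make_stratum([1.0, 2.0])) == {}

    def test_single_code_group_collects_all_carriers(self):
        s = make_stratum(range(10), [("E11",)] * 10)
        assert group_by_code(s)["E11"].size == 10


class TestChooseTest:
    def test_gaussian_samples_select_t_test(self, rng):
        g = rng.normal(0, 1, 5000)
        gd = rng.normal(0, 1, 5000)
        assert choose_test(g, gd, rng=np.random.default_rng(0)) == T_TEST

    def test_t_test_rate_matches_normality_alpha(self):
        # both samples Gaussian: each Shapiro test rejects with prob ~alpha
        hits = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            if choose_test(r.normal(size=400), r.normal(size=2000),
                           rng=np.random.default_rng(seed)) == T_TEST:
                hits += 1
        assert hits >= 30 * 0.75

    def test_degenerate_group_falls_back_to_mann_whitney(self, rng):
        assert choose_test(np.full(6, 4.0), rng.normal(size=100)) == MANN_WHITNEY

    def test_bimodal_group_fails_normality(self, rng):
        g = np.concatenate([rng.normal(-4, 0.3, 150), rng.normal(4, 0.3, 150)])
        assert choose_test(g, rng.normal(size=2000)) == MANN_WHITNEY


class TestTestGroup:
    def test_identical_multisets_not_significant(self, rng):
        x = rng.normal(size=200)
        assert group_p_value(x, x, T_TEST) > 0.999
        assert group_p_value(x, x, MANN_WHITNEY) > 0.999

    def test_exact_mwu_on_separated_triples(self):
        # all 20 rank assignments enumerable by hand: only the two fully
        # separated ones are as extreme, p = 2/20
        assert group_p_value([1, 2, 3], [4, 5, 6], MANN_WHITNEY) == pytest.approx(0.1)

    def test_constant_samples_give_p_one(self):
        assert group_p_value(np.zeros(6), np.zeros(50), T_TEST) == 1.0
        assert group_p_value(np.zeros(6), np.zeros(50), MANN_WHITNEY) == 1.0

    @pytest.mark.parametrize("n1,n2", [(1, 9), (2, 8), (3, 7), (4, 6), (5, 5), (3, 3)])
    def test_exact_mwu_matches_brute_force_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(12):
            x = rng.integers(0, 6, n1)  # integer values: ties are common
            y = rng.integers(0, 6, n2)
            assert mann_whitney_exact_p(x, y) == pytest.approx(
                brute_force_mwu_p(list(x), list(y))
            )

    def test_large_samples_use_tie_corrected_normal_approximation(self, rng):
        x = rng.integers(0, 10, 50).astype(float)
        y = rng.integers(2, 12, 300).astype(float)
        from scipy.stats import mannwhitneyu

        expected = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert group_p_value(x, y, MANN_WHITNEY) == pytest.approx(expected)


class TestStoreyQvalues:
    def test_bh_reduction_hand_example(self):
        q, pi0 = storey_qvalues([0.01, 0.02, 0.03, 0.9], pi0=1.0)
        assert pi0 == 1.0
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.9])

    def test_single_maximal_p(self):
        q, _ = storey_qvalues([1.0])
        assert q.tolist() == [1.0]

    def test_pi0_near_one_under_uniform_nulls(self, rng):
        p = rng.uniform(size=1000)
        _, pi0 = storey_qvalues(p)
        assert 0.85 <= pi0 <= 1.0

    def test_pi0_detects_signal(self, rng):
        # half the p-values tiny: pi0 should drop well below 1
        p = np.concatenate([rng.uniform(0, 1e-4, 500), rng.uniform(size=500)])
        _, pi0 = storey_qvalues(p)
        assert pi0 < 0.75

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=80)
    def test_pi0_one_equals_benjamini_hochberg(self, p):
        q, _ = storey_qvalues(p, pi0=1.0)
        assert np.allclose(q, benjamini_hochberg(p))
        assert np.allclose(
            q, multipletests(p, method="fdr_bh")[1]
        )  # independent library oracle

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        q, _ = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([])
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])


def _planted_stratum(seed, n_gd=5000, n_sig=500):
    """GD draws N(4, 0.35^2); code N18 marks a shifted N(4.4, 0.7^2) subgroup."""
    r = np.random.default_rng(seed)
    healthy = r.normal(4.0, 0.35, n_gd - n_sig)
    sick = r.normal(4.4, 0.7, n_sig)
    base = [()] * (n_gd - n_sig) + [("N18",)] * n_sig
    # a null code spread over ALL results, mirroring the GD's composition
    null_mask = r.random(n_gd) < 0.1
    codes = [c + ("Z01",) if z else c for c, z in zip(base, null_mask)]
    return make_stratum(np.concatenate([healthy, sick]), codes)


class TestDiagnosisTable:
    def test_groups_of_five_or_fewer_are_excluded(self):
        values = list(np.linspace(3.5, 4.5, 30))
        codes = [("A01",)] * 5 + [("B02",)] * 6 + [()] * 19
        table = build_diagnosis_table(make_stratum(values, codes))
        assert [r.code_or_cluster for r in table.rows] == ["B02"]
        assert table.rows[0].n == 6

    def test_shifted_subgroup_is_detected(self):
        table = build_diagnosis_table(_planted_stratum(0), seed=0)
        rows = {r.code_or_cluster: r for r in table.rows}
        assert rows["N18"].significant and rows["N18"].q_value < 0.05
        assert not rows["Z01"].significant
        assert rows["N18"].mean == pytest.approx(4.4, abs=0.1)

    def test_row_statistics_are_sample_moments(self):
        s = make_stratum([1.0, 2, 3, 4, 5, 6, 10.0], [("X10",)] * 6 + [()])
        row = build_diagnosis_table(s).rows[0]
        assert row.mean == pytest.approx(3.5)
        assert row.sd == pytest.approx(np.std([1, 2, 3, 4, 5, 6], ddof=1))

    def test_q_monotone_within_table(self):
        table = build_diagnosis_table(_planted_stratum(3), seed=3)
        ordered = sorted(table.rows, key=lambda r: r.p_value)
        qs = [r.q_value for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_null_stratum_rarely_flags_codes(self, rng):
        # 30 random subsamples of one Gaussian: expect ~no q < 0.05 rows
        values = rng.normal(4, 0.35, 3000)
        all_codes = np.array([f"Z{j:02d}" for j in range(30)])
        codes = [
            tuple(all_codes[rng.uniform(size=30) < 0.02][:5]) for _ in range(3000)
        ]
        table = build_diagnosis_table(make_stratum(values, codes), seed=1)
        assert len(table.rows) >= 25
        assert sum(r.significant for r in table.rows) <= 2

    def test_empty_table_when_no_eligible_codes(self):
        table = build_diagnosis_table(make_stratum([1.0, 2.0, 3.0]))
        assert table.rows == []


class TestDifferentialDistribution:
    def test_no_significant_rows_leaves_gd_unchanged(self):
        s = make_stratum([1.0, 2.0, 3.0])
        dd = differential_distribution(s, build_diagnosis_table(s))
        assert np.array_equal(np.sort(dd.dd_values), np.sort(s.gd_values))
        assert dd.removal_fraction == 0

    def test_any_code_rule_removes_mixed_coded_results(self):
        from ddri.io import TestResult

        s = _planted_stratum(0)
        # a result carrying one significant and one insignificant code
        s.results.append(TestResult(4.0, 25, "female", "mix", ("N18", "Z01")))
        dd = differential_distribution(s, build_diagnosis_table(s, seed=0))
        assert "N18" in dd.removed_codes and "Z01" not in dd.removed_codes
        assert any(r.case_id == "mix" for r in dd.removed_results)

    def test_counting_and_conservation(self):
        s = _planted_stratum(2)
        dd = differential_distribution(s, build_diagnosis_table(s, seed=2))
        assert dd.dd_values.size + dd.removed_count == s.gd_values.size
        # every removed result carries a significant code; no survivor does
        removed_ids = {r.case_id for r in dd.removed_results}
        for r in s.results:
            has_sig = any(c in dd.removed_codes for c in r.codes)
            assert has_sig == (r.case_id in removed_ids)

    def test_removal_monotone_in_alpha(self):
        s = _planted_stratum(4)
        table = build_diagnosis_table(s, seed=4)
        removed_small = {r.case_id for r in differential_distribution(s, table, alpha=0.001).removed_results}
        removed_large = {r.case_id for r in differential_distribution(s, table, alpha=0.1).removed_results}
        assert removed_small <= removed_large

    def test_manifest_lists_triggering_codes(self):
        s = _planted_stratum(5)
        dd = differential_distribution(s, build_diagnosis_table(s, seed=5))
        mf = dd.manifest_frame()
        assert len(mf) == dd.removed_count
        assert (mf["triggering_codes"].str.len() > 0).all()
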