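"""Box statistics, Wilcoxon rank-sum tests and Bonferroni adjustment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import mannwhitneyu

from wolfram_gp import (
    GroupedPatient,
    Grouping,
    Manifestation,
    PatientRecord,
    Sex,
    bonferroni_adjust,
    compare_dose_groups,
    five_number_summary,
    parse_protein_descriptor,
    sex_stratified_comparison,
    wilcoxon_rank_sum,
)


def make_patient(onset, nsfs_dose=0, tm_dose=0, sex=Sex.FEMALE, pid=None):
    """Assemble a GroupedPatient directly for statistics-level tests."""
    descriptors = {0: "p.Arg558Cys", 1: "p.Trp613*", 2: "p.Trp613*"}
    a1 = parse_protein_descriptor(descriptors[min(nsfs_dose, 1)])
    a2 = parse_protein_descriptor("p.Trp613*" if nsfs_dose == 2 else "p.Arg558Cys")
    record = PatientRecord(
        patient_id=pid or f"P{id(object()) % 10_000_000}",
        sex=sex,
        allele1_text=a1.raw_text,
        allele2_text=a2.raw_text,
        onset={Manifestation.DM: onset},
    )
    return GroupedPatient(
        record=record, allele1=a1, allele2=a2,
        nsfs_dose=nsfs_dose,
        tm_dose=None if nsfs_dose == 2 else tm_dose,
        onset_age=onset,
    )


class TestFiveNumberSummary:
    def test_singleton(self):
        s = five_number_summary([5])
        assert (s.median, s.q1, s.q3) == (5, 5, 5)
        assert s.outliers == ()

    def test_far_point_is_outlier(self):
        s = five_number_summary([1, 2, 3, 100])
        assert s.outliers == (100.0,)
        assert s.whisker_high == 3.0

    def test_odd_n_median_is_method_independent(self):
        for method in ("linear", "lower", "midpoint"):
            assert five_number_summary([4, 5, 6, 7, 8], method=method).median == 6

    def test_quartile_methods_differ_on_fractional_positions(self):
        data = [1, 2, 3, 4]
        assert five_number_summary(data, method="linear").q1 == 1.75
        assert five_number_summary(data, method="lower").q1 == 1.0
        assert five_number_summary(data, method="midpoint").q1 == 1.5

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            five_number_summary([])

    @given(
        ages=st.lists(st.floats(0, 80, allow_nan=False), min_size=2, max_size=40),
        shift=st.floats(-10, 10, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_permutation_invariant_and_shift_equivariant(self, ages, shift, seed):
        rng = np.random.default_rng(seed)
        s = five_number_summary(ages)
        permuted = five_number_summary(rng.permutation(ages))
        assert permuted == s
        shifted = five_number_summary([a + shift for a in ages])
        assert shifted.median == pytest.approx(s.median + shift, abs=1e-9)
        assert shifted.q1 == pytest.approx(s.q1 + shift, abs=1e-9)
        assert len(shifted.outliers) == len(s.outliers)


def bruteforce_exact_p(x, y):
    """Enumeration oracle: every C(n, nx) rank assignment is equally likely."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes untied data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n, nx = len(pooled), len(x)
    lo = hi = total = 0
    for combo in itertools.combinations(range(1, n + 1), nx):
        w = sum(combo)
        total += 1
        lo += w <= w_obs
        hi += w >= w_obs
    return min(1.0, 2.0 * min(lo, hi) / total)


class TestWilcoxonRankSum:
    def test_worked_example(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        x = [3.0, 5.0, 7.0, 9.0]
        _, p = wilcoxon_rank_sum(x, list(x))
        assert p == pytest.approx(1.0)

    def test_symmetry_under_sample_swap(self, rng):
        x, y = rng.normal(5, 2, 12).tolist(), rng.normal(6, 2, 9).tolist()
        for mode in ("exact", "normal_approx"):
            _, p_xy = wilcoxon_rank_sum(x, y, mode=mode)
            _, p_yx = wilcoxon_rank_sum(y, x, mode=mode)
            assert p_xy == pytest.approx(p_yx)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_agrees_with_scipy_and_bruteforce(self, rng):
        for _ in range(25):
            nx, ny = rng.integers(2, 7, size=2)
            x = rng.permutation(40)[: nx + ny].astype(float)
            x, y = x[:nx].tolist(), x[nx:].tolist()
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            p_scipy = mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
            assert p == pytest.approx(p_scipy, abs=1e-12)
            assert p == pytest.approx(bruteforce_exact_p(x, y), abs=1e-12)

    def test_normal_approx_agrees_with_scipy_under_ties(self, rng):
        x = rng.integers(0, 12, size=35).astype(float).tolist()
        y = (rng.integers(0, 12, size=28) + 2).astype(float).tolist()
        u, p = wilcoxon_rank_sum(x, y, mode="normal_approx")
        res = mannwhitneyu(x, y, method="asymptotic", use_continuity=False,
                           alternative="two-sided")
        assert u == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue, rel=1e-9)

    def test_fully_tied_data_degenerates_to_p_one(self, caplog):
        _, p = wilcoxon_rank_sum([4.0, 4.0], [4.0, 4.0, 4.0])
        assert p == 1.0

    def test_normal_approximation_converges_to_exact(self, rng):
        """|p_approx - p_exact| shrinks as the sample size grows."""
        deltas = []
        for n in (15, 30, 60):
            x = rng.permutation(10_000)[: 2 * n].astype(float)
            x, y = x[:n].tolist(), x[n:].tolist()
            _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
            _, p_approx = wilcoxon_rank_sum(x, y, mode="normal_approx")
            deltas.append(abs(p_exact - p_approx) / max(p_exact, 1e-12))
        assert deltas[2] < deltas[0]

    def test_auto_uses_exact_for_small_untied_samples(self):
        _, p_auto = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="auto")
        assert p_auto == pytest.approx(0.1)


class TestBonferroni:
    def test_worked_examples(self):
        assert bonferroni_adjust([0.01, 0.02, 0.5]) == pytest.approx([0.03, 0.06, 1.0])
        assert bonferroni_adjust([0.2]) == [0.2]

    def test_invalid_p_raises(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                bonferroni_adjust([0.5, bad])

    @given(st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=12))
    def test_never_decreases_and_never_exceeds_one(self, ps):
        out = bonferroni_adjust(ps)
        assert all(a >= p for a, p in zip(out, ps))
        assert all(a <= 1.0 for a in out)


class TestCompareDoseGroups:
    def test_empty_group_omitted_and_m_counts_only_tested_pairs(self, rng):
        patients = [make_patient(a, nsfs_dose=0) for a in rng.normal(10, 2, 20)]
        patients += [make_patient(a, nsfs_dose=2) for a in rng.normal(6, 2, 20)]
        comp = compare_dose_groups(patients, Manifestation.DM, Grouping.NSFS_DOSE)
        assert set(comp.per_group) == {"NSFS0", "NSFS2"}
        assert any("NSFS1" in note for note in comp.notes)
        [test] = comp.pairwise
        assert test.p_adjusted == pytest.approx(test.p_raw)  # m = 1

    def test_adjustment_multiplies_by_family_size(self, rng):
        patients = [
            make_patient(a, nsfs_dose=d)
            for d in (0, 1, 2)
            for a in rng.normal(10 - 2 * d, 2, 15)
        ]
        comp = compare_dose_groups(patients, Manifestation.DM, Grouping.NSFS_DOSE)
        assert len(comp.pairwise) == 3
        for t in comp.pairwise:
            assert t.p_adjusted == pytest.approx(min(1.0, 3 * t.p_raw))

    def test_single_group_reports_not_testable(self, rng):
        patients = [make_patient(a, nsfs_dose=2) for a in rng.normal(6, 2, 10)]
        comp = compare_dose_groups(patients, Manifestation.DM, Grouping.NSFS_DOSE)
        assert not comp.testable
        assert any("not testable" in note for note in comp.notes)

    def test_tm_groupings_use_only_their_subset(self, rng):
        patients = [make_patient(a, nsfs_dose=0, tm_dose=2) for a in rng.normal(6, 1, 8)]
        patients += [make_patient(a, nsfs_dose=0, tm_dose=0) for a in rng.normal(11, 2, 8)]
        patients += [make_patient(a, nsfs_dose=1, tm_dose=1) for a in rng.normal(5, 1, 8)]
        patients += [make_patient(a, nsfs_dose=1, tm_dose=0) for a in rng.normal(8, 1, 8)]
        two = compare_dose_groups(patients, Manifestation.DM, Grouping.TM_DOSE_TWO_INFRAME)
        assert {lab: s.n for lab, s in two.per_group.items()} == {"NTM0": 8, "NTM2": 8}
        one = compare_dose_groups(patients, Manifestation.DM, Grouping.TM_DOSE_ONE_INFRAME)
        assert {lab: s.n for lab, s in one.per_group.items()} == {"NTM0": 8, "NTM1": 8}

    def test_group_sizes_partition_the_input(self, rng):
        patients = [
            make_patient(a, nsfs_dose=int(d))
            for d, a in zip(rng.integers(0, 3, 60), rng.normal(9, 3, 60))
        ]
        comp = compare_dose_groups(patients, Manifestation.DM, Grouping.NSFS_DOSE)
        assert sum(s.n for s in comp.per_group.values()) == len(patients)


class TestSexStratified:
    def test_detects_simulated_male_shift(self, rng):
        patients = [make_patient(a, sex=Sex.MALE) for a in rng.normal(6.5, 1.5, 60)]
        patients += [make_patient(a, sex=Sex.FEMALE) for a in rng.normal(8.0, 1.5, 60)]
        comp = sex_stratified_comparison(patients, Manifestation.DM)
        [test] = comp.pairwise
        assert test.p_adjusted < 0.05

    def test_all_unknown_sex_is_not_testable(self, rng):
        patients = [make_patient(a, sex=Sex.UNKNOWN) for a in rng.normal(8, 2, 10)]
        comp = sex_stratified_comparison(patients, Manifestation.DM)
        assert not comp.testable

    def test_within_dose_stratum_restricts_patients(self, rng):
        patients = [
            make_patient(a, nsfs_dose=0, sex=Sex.MALE) for a in rng.normal(8, 2, 12)
        ] + [
            make_patient(a, nsfs_dose=0, sex=Sex.FEMALE) for a in rng.normal(8, 2, 12)
        ] + [
            make_patient(a, nsfs_dose=2, sex=Sex.MALE) for a in rng.normal(5, 2, 12)
        ]
        comp = sex_stratified_comparison(patients, Manifestation.DM, within_dose=0)
        assert sum(s.n for s in comp.per_group.values()) == 24
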