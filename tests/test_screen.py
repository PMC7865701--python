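import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scinfer import (
    DataError,
    DisruptionMatrix,
    ParameterError,
    ScreenParams,
    evaluate_pair,
    partition_by_pair,
    rank_sum_test,
    scan_pairs,
)
from _oracles import ranksum_exact_oracle


class TestPartition:
    def test_exhaustive_routing(self, tiny_matrix):
        part = partition_by_pair(tiny_matrix, "gA", "gB")
        assert part.both == ("s1",)
        assert part.a_only == ("s2",)
        assert part.b_only == ("s3",)
        assert part.neither == ("s4",)

    def test_all_wild_type(self):
        data = pd.DataFrame(np.zeros((3, 2), dtype=int), index=["a", "b", "c"], columns=["gA", "gB"])
        part = partition_by_pair(DisruptionMatrix(data), "gA", "gB")
        assert part.neither == ("a", "b", "c") and part.sizes() == (0, 0, 0, 3)

    def test_partition_is_disjoint_cover(self, tiny_matrix):
        part = partition_by_pair(tiny_matrix, "gA", "gB")
        groups = [set(part.both), set(part.a_only), set(part.b_only), set(part.neither)]
        assert set().union(*groups) == set(tiny_matrix.sample_ids)
        assert sum(len(g) for g in groups) == tiny_matrix.n_samples

    def test_column_permutation_invariance(self, tiny_matrix):
        shuffled = DisruptionMatrix(tiny_matrix.data[["gB", "gA"]])
        assert partition_by_pair(shuffled, "gA", "gB") == partition_by_pair(tiny_matrix, "gA", "gB")

    def test_errors(self, tiny_matrix):
        with pytest.raises(KeyError):
            partition_by_pair(tiny_matrix, "gA", "nope")
        with pytest.raises(ParameterError):
            partition_by_pair(tiny_matrix, "gA", "gA")


class TestRankSum:
    def test_fully_separated_small_groups(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 20)
        assert res.u_statistic == 0.0

    def test_reversed_direction_gives_p_one(self):
        res = rank_sum_test([4, 5, 6], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_identical_singletons_no_evidence(self):
        res = rank_sum_test([5.0], [5.0])
        assert res.p_value >= 0.5

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            nx_, ny_ = rng.integers(1, 9, size=2)
            pooled = rng.normal(size=nx_ + ny_)
            x, y = pooled[:nx_], pooled[nx_:]
            res = rank_sum_test(x, y)
            u_oracle, p_oracle = ranksum_exact_oracle(x, y)
            assert res.method == "exact"
            assert res.u_statistic == pytest.approx(u_oracle)
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_ties_fall_back_to_approximation(self):
        res = rank_sum_test([1, 1, 2], [2, 3, 4])
        assert res.method == "normal_approx"

    def test_large_groups_use_approximation(self):
        rng = np.random.default_rng(0)
        res = rank_sum_test(rng.normal(size=40), rng.normal(size=40))
        assert res.method == "normal_approx"
        assert 0 < res.p_value <= 1

    @given(
        st.lists(st.integers(0, 10_000), min_size=2, max_size=8, unique=True),
        st.lists(st.integers(10_001, 20_000), min_size=2, max_size=8, unique=True),
        st.integers(1, 5_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shift_monotonicity(self, xs, ys, shift):
        """Subtracting a positive constant from x never increases the one-sided p."""
        x = np.array(xs, dtype=float) / 3.0
        y = np.array(ys, dtype=float) / 3.0
        p0 = rank_sum_test(x, y).p_value
        p1 = rank_sum_test(x - shift, y).p_value
        assert p1 <= p0 + 1e-12

    def test_input_contracts(self):
        with pytest.raises(ParameterError):
            rank_sum_test([], [1.0])
        with pytest.raises(DataError):
            rank_sum_test([np.nan], [1.0])


def _matrix_with_group_sizes(n_both, n_a, n_b, n_neither):
    rows = (
        [[1, 1]] * n_both + [[1, 0]] * n_a + [[0, 1]] * n_b + [[0, 0]] * n_neither
    )
    n = len(rows)
    data = pd.DataFrame(rows, index=[f"s{i}" for i in range(n)], columns=["gA", "gB"])
    return DisruptionMatrix(data)


class TestEvaluatePair:
    def test_undersized_group_marks_untested(self):
        # n = 407 -> every group needs ceil(0.025 * 407) = 11 samples
        m = _matrix_with_group_sizes(10, 130, 130, 137)
        rng = np.random.default_rng(1)
        resp = pd.Series(rng.normal(size=407), index=m.sample_ids)
        res = evaluate_pair(m, resp, "gA", "gB")
        assert not res.tested and res.p_values is None and res.is_sc == 0
        assert res.group_sizes == (10, 130, 130, 137)

    def test_planted_shift_is_declared_sc(self):
        m = _matrix_with_group_sizes(15, 60, 60, 65)
        rng = np.random.default_rng(2)
        resp = pd.Series(rng.normal(size=200), index=m.sample_ids)
        resp.iloc[:15] -= 3.0  # both-disrupted group sensitised
        res = evaluate_pair(m, resp, "gA", "gB")
        assert res.tested and res.is_sc == 1
        assert all(p < 0.05 for p in res.p_values)
        assert res.group_medians[0] == min(res.group_medians)

    def test_median_direction_vetoes(self):
        m = _matrix_with_group_sizes(15, 60, 60, 65)
        rng = np.random.default_rng(3)
        resp = pd.Series(rng.normal(size=200), index=m.sample_ids)
        resp.iloc[:15] += 3.0  # both-group is WORSE: must not be SC
        res = evaluate_pair(m, resp, "gA", "gB")
        assert res.is_sc == 0

    def test_samples_without_response_are_excluded(self):
        m = _matrix_with_group_sizes(15, 60, 60, 65)
        rng = np.random.default_rng(4)
        resp = pd.Series(rng.normal(size=100), index=m.sample_ids[:100])
        res = evaluate_pair(m, resp, "gA", "gB")
        assert sum(res.group_sizes) == 100


class TestScanPairs:
    def _cohort_matrix(self, seed=0, n=120, freqs=(0.3, 0.3, 0.3, 0.02)):
        rng = np.random.default_rng(seed)
        cells = (rng.random((n, len(freqs))) < np.array(freqs)).astype(int)
        data = pd.DataFrame(cells, index=[f"s{i}" for i in range(n)], columns=["g1", "g2", "g3", "g4"])
        return DisruptionMatrix(data), rng

    def test_three_passing_genes_give_three_pairs(self):
        m, rng = self._cohort_matrix()
        resp = pd.Series(rng.normal(size=120), index=m.sample_ids)
        results = scan_pairs(m, resp)
        # g4 at 2% fails the >5% gene filter
        assert len(results) == 3
        assert [(r.gene_a, r.gene_b) for r in results] == [("g1", "g2"), ("g1", "g3"), ("g2", "g3")]

    def test_order_invariance(self):
        m, rng = self._cohort_matrix()
        resp = pd.Series(rng.normal(size=120), index=m.sample_ids)
        r1 = scan_pairs(m, resp)
        perm = list(np.random.default_rng(9).permutation(m.sample_ids))
        m_shuf = DisruptionMatrix(m.data.loc[perm, ["g3", "g1", "g4", "g2"]])
        r2 = scan_pairs(m_shuf, resp)
        assert [(r.gene_a, r.gene_b, r.group_sizes, r.p_values) for r in r1] == [
            (r.gene_a, r.gene_b, r.group_sizes, r.p_values) for r in r2
        ]

    def test_no_passing_genes_warns_and_returns_empty(self):
        data = pd.DataFrame(np.zeros((50, 3), dtype=int), index=[f"s{i}" for i in range(50)], columns=list("abc"))
        m = DisruptionMatrix(data)
        resp = pd.Series(np.arange(50.0), index=m.sample_ids)
        with pytest.warns(UserWarning):
            assert scan_pairs(m, resp) == []

    def test_recovers_planted_pair_from_cohort(self, small_planted_cohort):
        from scinfer import build_disruption_matrix, filter_population_variants, sc_pairs

        c = small_planted_cohort
        var, _ = filter_population_variants(c.variants)
        samples = sorted(set(c.response["sample_id"]))
        m = build_disruption_matrix(var, c.copy_number, samples)
        results = scan_pairs(m, c.response, drug="paclitaxel")
        hits = {r.as_pair() for r in sc_pairs(results)}
        assert frozenset({"G001", "G002"}) in hits
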