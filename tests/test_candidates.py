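import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clinepool.candidates import (
    compare_candidate_sets,
    fdr_qvalues,
    fisher_exact_2x2,
    fisher_exact_many,
    gene_based_candidates,
    overlap_fraction,
    select_outliers,
)
from clinepool.genes import genes_for_positions
from clinepool.io_formats import GeneModel


class TestFisherExact:
    def test_diagonal_table_by_full_enumeration(self):
        # [[10,0],[0,10]]: only the two extreme tables are as improbable
        assert fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(2 / 184756)

    def test_central_table_is_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == 1.0

    def test_transposition_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, 4)
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher_exact_2x2(a, c, b, d), rel=1e-9
            )

    def test_zero_margin_gives_one(self):
        assert fisher_exact_2x2(0, 0, 5, 7) == 1.0
        assert fisher_exact_2x2(0, 3, 0, 7) == 1.0

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        a, b, c, d = (rng.integers(0, 60, 300) for _ in range(4))
        ours = fisher_exact_many(a, b, c, d)
        for i in range(300):
            ref = stats.fisher_exact([[a[i], b[i]], [c[i], d[i]]])[1]
            assert ours[i] == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_negative_entries_raise(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestFdr:
    def test_hand_computed_bh_example(self):
        q = fdr_qvalues(np.array([0.001, 0.02, 0.03, 0.5]))
        assert np.allclose(q, [0.004, 0.04, 0.04, 0.5])

    def test_degenerate_inputs(self):
        assert np.allclose(fdr_qvalues(np.array([1.0, 1.0, 1.0])), 1.0)
        assert fdr_qvalues(np.array([0.123]))[0] == pytest.approx(0.123)

    def test_q_at_least_p_and_monotone_in_sorted_order(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=500)
        q = fdr_qvalues(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestOutlierSelection:
    def test_flags_exactly_floor_of_tail(self):
        rng = np.random.default_rng(3)
        fst = rng.uniform(size=10_000)
        flags = select_outliers(fst, 0.005)
        assert flags.sum() == 50
        assert fst[flags].min() >= np.sort(fst)[-50]

    def test_small_set_flags_nothing(self):
        assert select_outliers(np.arange(100.0), 0.005).sum() == 0

    def test_ties_at_cutoff_resolved_by_fet_p_then_position(self):
        fst = np.array([0.9, 0.5, 0.5, 0.5, 0.1] + [0.0] * 995)
        fet = np.array([0.5, 0.2, 0.01, 0.2, 0.9] + [1.0] * 995)
        pos = np.arange(len(fst))
        arms = np.array(["2L"] * len(fst))
        flags = select_outliers(fst, 0.003, fet_p=fet, arms=arms, positions=pos)
        assert flags.sum() == 3
        # 0.9 first; among the 0.5-tie the smaller p wins, then position
        assert set(np.flatnonzero(flags)) == {0, 2, 1}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            select_outliers(np.array([]), 0.005)


class TestGeneAssignment:
    @pytest.fixture
    def genes(self):
        return [
            GeneModel("g1", "2L", "+", 10_000, 12_000),
            GeneModel("g2", "2L", "+", 11_500, 13_000),
        ]

    def test_flank_boundary_inclusive_at_1000(self, genes):
        arms = np.array(["2L"] * 3)
        pos = np.array([9000, 8999, 11_800])
        out = genes_for_positions(arms, pos, genes, flank=1000)
        assert out[0] == ["g1"]      # exactly start - 1000
        assert out[1] == []          # one bp further out
        assert out[2] == ["g1", "g2"]  # inside the overlap


class TestGeneCandidatesAndOverlap:
    def test_top_tail_selection_and_overlap_fraction(self):
        gene_fst = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(100)],
             "mean_fst": np.linspace(0, 1, 100), "n_snps": 1}
        )
        top = gene_based_candidates(gene_fst, tail=0.05)
        assert top == {"g99", "g98", "g97", "g96", "g95"}
        assert overlap_fraction({"g99", "g98", "x"}, top) == pytest.approx(0.4)
        assert overlap_fraction(top, top) == 1.0
        assert overlap_fraction(set(), top) == 0.0
        with pytest.raises(ValueError):
            overlap_fraction(top, set())


class TestSetComparison:
    def test_identical_full_sets_give_p_one(self):
        uni = {f"g{i}" for i in range(50)}
        obs, p = compare_candidate_sets(uni, uni, uni, n_perm=200, seed=0)
        assert obs == 1.0 and p == 1.0

    def test_disjoint_small_sets_are_unsurprising(self):
        uni = {f"g{i}" for i in range(1000)}
        s1 = {f"g{i}" for i in range(10)}
        s2 = {f"g{i}" for i in range(10, 20)}
        _, p = compare_candidate_sets(s1, s2, uni, n_perm=200, seed=0)
        assert p > 0.5

    def test_planted_overlap_is_maximally_significant(self):
        uni = {f"g{i}" for i in range(1000)}
        s2 = {f"g{i}" for i in range(100)}
        s1 = {f"g{i}" for i in range(50)} | {f"g{i}" for i in range(900, 950)}
        obs, p = compare_candidate_sets(s1, s2, uni, n_perm=999, seed=0)
        assert obs == pytest.approx(0.5)
        assert p == pytest.approx(1 / 1000)

    def test_invalid_inputs_raise(self):
        uni = {"a", "b"}
        with pytest.raises(ValueError):
            compare_candidate_sets({"z"}, {"a"}, uni, n_perm=10)
        with pytest.raises(ValueError):
            compare_candidate_sets({"a"}, {"b"}, uni, n_perm=0)
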