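import itertools

import numpy as np
import pytest

from tfcoev.coevolution import (
    candidate_pairs,
    combine_scores,
    compute_coevolution,
    define_crps,
    filter_columns,
    method_agreement,
    min_max_rescale,
    quantile_normalize,
    run_coevolution,
)
from tfcoev.msa import AlignedFamily

from conftest import random_msa
from oracles import mi_oracle, mip_oracle, omes_oracle, sca_oracle


def _msa_from_columns(columns: list[str]) -> AlignedFamily:
    n = len(columns[0])
    seqs = ["".join(col[i] for col in columns) for i in range(n)]
    return AlignedFamily.from_sequences([f"s{i}" for i in range(n)], seqs)


FULL3 = np.ones(3, dtype=bool)


class TestWorkedExamples:
    def test_mi_one_bit_for_perfect_covariation(self):
        msa = _msa_from_columns(["AACC", "AACC", "ACAC"])
        mi = compute_coevolution(msa, "MI", column_mask=FULL3)
        assert mi[0, 1] == pytest.approx(1.0)

    def test_mi_and_omes_zero_for_exact_independence(self):
        msa = _msa_from_columns(["AACC", "ACAC", "AAAC"])
        mi = compute_coevolution(msa, "MI", column_mask=FULL3)
        omes = compute_coevolution(msa, "OMES", column_mask=FULL3)
        assert mi[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert omes[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_mip_apc_arithmetic(self):
        # MI: (A,B)=1, (A,C)=0, (B,C)=0 -> APC(A,B)=0.75, MIp(A,B)=0.25
        msa = _msa_from_columns(["AACC", "AACC", "ACAC"])
        mip = compute_coevolution(msa, "MIp", column_mask=FULL3)
        assert mip[0, 1] == pytest.approx(0.25)
        assert mip[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_omes_one_for_perfect_covariation(self):
        msa = _msa_from_columns(["AACC", "AACC", "ACAC"])
        omes = compute_coevolution(msa, "OMES", column_mask=FULL3)
        assert omes[0, 1] == pytest.approx(1.0)

    def test_sca_zero_for_exact_independence(self):
        msa = _msa_from_columns(["AACC", "ACAC", "AAAC"])
        sca = compute_coevolution(msa, "SCA", column_mask=FULL3)
        assert sca[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_all_methods_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        msa = random_msa(
            rng,
            n_seq=int(rng.integers(4, 11)),
            n_col=int(rng.integers(3, 9)),
            gap_prob=0.1 if seed % 2 else 0.0,
        )
        rows = ["".join(r) for r in msa.seqs]
        mask = np.ones(msa.n_col, dtype=bool)
        mats = {
            m: compute_coevolution(msa, m, column_mask=mask)
            for m in ("MI", "OMES", "SCA")
        }
        oracles = {"MI": mi_oracle, "OMES": omes_oracle, "SCA": sca_oracle}
        for i, j in itertools.combinations(range(msa.n_col), 2):
            for m in mats:
                expected = oracles[m](rows, i, j)
                got = mats[m][i, j]
                if expected is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-10)
        mip = compute_coevolution(msa, "MIp", column_mask=mask)
        expected_mip = mip_oracle(rows, list(range(msa.n_col)))
        for (i, j), v in expected_mip.items():
            assert mip[i, j] == pytest.approx(v, abs=1e-10)

    def test_invariance_to_row_order_and_relabeling(self):
        rng = np.random.default_rng(99)
        msa = random_msa(rng, 8, 6)
        mask = np.ones(6, dtype=bool)
        base = compute_coevolution(msa, "MI", column_mask=mask)

        perm = rng.permutation(8)
        reordered = AlignedFamily(
            [msa.ids[i] for i in perm], msa.seqs[perm], msa.seed_id
        )
        relabel = dict(zip("ACDEFG", "MNPQRS"))
        remapped = AlignedFamily(
            msa.ids,
            np.vectorize(relabel.get)(msa.seqs).astype("<U1"),
            msa.seed_id,
        )
        for other in (reordered, remapped):
            alt = compute_coevolution(other, "MI", column_mask=mask)
            np.testing.assert_allclose(base, alt, atol=1e-12)


class TestFilterColumns:
    def test_gap_and_invariant_filtering(self):
        cols = [
            "AC-DEF-A--",  # 4/10 gaps -> excluded at 0.25
            "AAAAAAAAAA",  # invariant -> excluded
            "ACDEFGHIKL",  # retained
            "AC-DEFGHIK",  # 1/10 gaps -> retained
        ]
        msa = _msa_from_columns(cols)
        mask = filter_columns(msa, max_gap_frac=0.25)
        np.testing.assert_array_equal(mask, [False, False, True, True])

    def test_all_filtered_errors(self):
        msa = _msa_from_columns(["AAAA"])
        with pytest.raises(ValueError):
            filter_columns(msa)


def _matrix_from_scores(scores):
    """Symmetric NaN matrix holding the given upper-triangle scores."""
    m = len(scores)
    n = int(np.ceil((1 + np.sqrt(1 + 8 * m)) / 2))
    mat = np.full((n, n), np.nan)
    for (i, j), s in zip(itertools.combinations(range(n), 2), scores):
        mat[i, j] = mat[j, i] = s
    return mat


class TestCandidatePairs:
    def test_twenty_distinct_scores_give_two_pairs(self):
        mat = _matrix_from_scores(np.random.default_rng(0).permutation(20.0 + np.arange(20)))
        assert len(candidate_pairs(mat)) == 2

    def test_hundred_distinct_scores_threshold_91(self):
        scores = np.random.default_rng(1).permutation(np.arange(1.0, 101.0))
        mat = _matrix_from_scores(scores)
        pairs = candidate_pairs(mat)
        assert len(pairs) == 10
        assert all(mat[p] >= 91 for p in pairs)

    def test_all_tied_returns_everything_with_warning(self):
        mat = _matrix_from_scores(np.ones(15))
        with pytest.warns(UserWarning):
            assert len(candidate_pairs(mat)) == 15


class TestCrpsAndAgreement:
    def test_define_crps_two_method_rule(self):
        cands = {
            "MI": {(0, 1), (0, 2)},
            "MIp": {(0, 1), (0, 3)},
            "OMES": {(0, 4)},
            "SCA": {(0, 5)},
        }
        assert define_crps(cands) == {(0, 1)}

    def test_identical_sets_all_crps(self):
        s = {(0, 1), (2, 3)}
        assert define_crps({m: set(s) for m in "abcd"}) == s

    def test_disjoint_sets_warn_empty(self):
        cands = {"a": {(0, 1)}, "b": {(2, 3)}}
        with pytest.warns(UserWarning):
            assert define_crps(cands) == set()

    def test_jaccard_values(self):
        j = method_agreement({"a": {1, 2, 3}, "b": {2, 3, 4}, "c": {9}})
        assert j.loc["a", "b"] == pytest.approx(0.5)
        assert j.loc["a", "c"] == pytest.approx(0.0)
        assert j.loc["a", "a"] == pytest.approx(1.0)


class TestScoreCombination:
    def test_min_max_rescale_example(self):
        np.testing.assert_allclose(
            min_max_rescale(np.array([2.0, 4.0, 6.0])), [0.0, 0.5, 1.0]
        )

    def test_quantile_normalize_example(self):
        v = np.column_stack([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]])
        out = quantile_normalize(v)
        np.testing.assert_allclose(out[:, 0], [5.5, 11.0, 16.5])
        np.testing.assert_allclose(out[:, 1], [5.5, 11.0, 16.5])

    def test_quantile_normalize_tie_handling(self):
        v = np.column_stack([[1.0, 1.0, 3.0], [10.0, 20.0, 30.0]])
        out = quantile_normalize(v)
        ref = np.sort(v, axis=0).mean(axis=1)
        np.testing.assert_allclose(out[:2, 0], (ref[0] + ref[1]) / 2)

    def test_identical_matrices_combination_idempotent(self):
        rng = np.random.default_rng(5)
        mat = _matrix_from_scores(rng.uniform(size=10))
        combined = combine_scores({m: mat for m in "abcd"})
        iu = np.isfinite(mat)
        np.testing.assert_allclose(
            combined[iu], min_max_rescale(mat[iu]), atol=1e-12
        )

    def test_combined_scores_rank_monotone(self):
        rng = np.random.default_rng(6)
        mats = {m: _matrix_from_scores(rng.uniform(size=45)) for m in "abcd"}
        combined = combine_scores(mats)
        iu = np.triu_indices(10, k=1)
        pairs = list(zip(*iu))
        for p, q in itertools.combinations(pairs, 2):
            dominates = all(mats[m][p] > mats[m][q] for m in mats)
            if dominates:
                assert combined[p] > combined[q]


class TestPlantedRecovery:
    def test_strongly_coupled_pair_is_crp(self, small_family):
        _, msa, _, truth = small_family
        result = run_coevolution(msa)
        assert truth.true_pairs <= result.crps
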