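import itertools
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from clonalscape import clonal_assignment as ca

from conftest import make_table


def brute_force_compatible(profile, resolved, mlg_profiles):
    """Oracle: MLGs agreeing with `profile` at every mutually resolved locus."""
    hits = []
    for mlg, prof in mlg_profiles.items():
        both = resolved & (prof[:, 0] != 0)
        if both.any() and all(tuple(prof[j]) == tuple(profile[j])
                              for j in np.flatnonzero(both)):
            hits.append(mlg)
    return hits


class TestAssignMlgs:
    def test_identical_samples_one_mlg(self):
        gt = make_table([[(1, 2), (3, 3)], [(1, 2), (3, 3)]])
        a = ca.assign_mlgs(gt)
        assert len(a.mlg_ids) == 1

    def test_one_locus_difference_two_mlgs(self):
        gt = make_table([[(1, 2), (3, 3)], [(1, 2), (3, 4)]])
        a = ca.assign_mlgs(gt)
        assert len(a.mlg_ids) == 2

    def test_missing_sample_merged_into_unique_match(self):
        gt = make_table([
            [(1, 2), (3, 3), (5, 6)],
            [(1, 2), (4, 4), (5, 6)],
            [(1, 2), (0, 0), (5, 6)],   # matches both -> ambiguous
            [(1, 1), (0, 0), (5, 6)],   # matches none -> new MLG
        ])
        a = ca.assign_mlgs(gt)
        assert a.sample_ids[2] not in a.mlg_of_sample
        assert "s03" in a.ambiguous_samples
        assert len(a.mlg_ids) == 3  # two complete + one founded by s04
        # oracle agreement
        resolved = ~gt.missing_mask[2]
        hits = brute_force_compatible(gt.calls[2], resolved,
                                      {g: p for g, p in a.mlg_profiles.items()
                                       if (p[:, 0] != 0).all()})
        assert len(hits) == 2

    def test_unique_partial_match_merges(self):
        gt = make_table([
            [(1, 2), (3, 3), (5, 6)],
            [(1, 2), (4, 4), (7, 8)],
            [(1, 2), (3, 3), (0, 0)],
        ])
        a = ca.assign_mlgs(gt)
        assert a.mlg_of_sample["s03"] == a.mlg_of_sample["s01"]
        assert "s03" in a.missing_flagged

    def test_all_missing_excluded(self):
        gt = make_table([[(1, 2)], [(0, 0)]])
        a = ca.assign_mlgs(gt)
        assert a.empty_samples == ["s02"]
        assert "s02" not in a.mlg_of_sample


class TestMlgDistance:
    def test_identical_zero(self):
        p = np.array([[148, 150], [100, 102]])
        assert ca.mlg_distance(p, p) == 0

    @pytest.mark.parametrize("other,expected", [
        ([[148, 152], [100, 102]], 1),
        ([[152, 154], [100, 102]], 2),
        ([[148, 148], [100, 102]], 1),
        ([[152, 154], [104, 106]], 4),
    ])
    def test_multiset_difference(self, other, expected):
        a = np.array([[148, 150], [100, 102]])
        b = np.array(other)
        # independent multiset oracle
        oracle = sum(
            2 - sum((Counter(x) & Counter(y)).values())
            for x, y in zip(map(tuple, a), map(tuple, b)))
        assert ca.mlg_distance(a, b) == expected == oracle

    def test_missing_locus_skipped(self):
        a = np.array([[148, 150], [0, 0]])
        b = np.array([[148, 150], [100, 102]])
        assert ca.mlg_distance(a, b) == 0

    def test_no_comparable_loci_error(self):
        a = np.array([[0, 0]])
        b = np.array([[148, 150]])
        with pytest.raises(ValueError):
            ca.mlg_distance(a, b)


class TestCollapse:
    def _assign(self, rows):
        return ca.assign_mlgs(make_table(rows))

    def test_singleton_merged_into_abundant(self):
        rows = [[(1, 2), (3, 4)]] * 5 + [[(1, 2), (3, 5)]]
        a = ca.collapse_to_mlls(self._assign(rows))
        assert len(a.mll_ids) == 1
        assert len(a.mll_members()[a.mll_ids[0]]) == 6

    def test_both_multisample_not_merged(self):
        rows = [[(1, 2), (3, 4)]] * 3 + [[(1, 2), (3, 5)]] * 2
        a = ca.collapse_to_mlls(self._assign(rows))
        assert len(a.mll_ids) == 2

    def test_chain_collapses_to_single_mll(self):
        # A(3) - B(1) - C(1) with d(A,B)=d(B,C)=1 but d(A,C)=2: C joins only
        # through the fixed-point iteration via B
        rows = ([[(1, 2), (3, 4)]] * 3
                + [[(1, 2), (4, 5)]]
                + [[(1, 2), (5, 6)]])
        a = ca.collapse_to_mlls(self._assign(rows))
        assert len(a.mll_ids) == 1
        assert len(a.mll_members()[a.mll_ids[0]]) == 5

    def test_order_independence(self, rng):
        rows = ([[(1, 2), (3, 4), (9, 9)]] * 3
                + [[(1, 2), (3, 5), (9, 9)]]
                + [[(1, 2), (3, 6), (9, 9)]]
                + [[(7, 7), (3, 4), (9, 9)]] * 2)
        gt = make_table(rows)
        base = ca.collapse_to_mlls(ca.assign_mlgs(gt))
        base_parts = sorted(sorted(v) for v in base.mll_members().values())
        for _ in range(5):
            perm = rng.permutation(len(rows))
            gtp = gt.subset(perm)
            ap = ca.collapse_to_mlls(ca.assign_mlgs(gtp))
            parts = sorted(sorted(v) for v in ap.mll_members().values())
            assert parts == base_parts

    def test_mll_count_never_exceeds_mlg_count(self):
        rows = [[(1, 2), (3, 4)], [(1, 2), (3, 5)], [(5, 6), (7, 8)]]
        a = ca.collapse_to_mlls(self._assign(rows))
        assert len(a.mll_ids) <= len(a.mlg_ids) <= 3


class TestPgenPsex:
    def test_homozygote_fixed_allele(self):
        assert ca.pgen(np.array([[5, 5]]), [{5: 1.0}]) == 1.0

    def test_heterozygote_2pq(self):
        val = ca.pgen(np.array([[1, 2]]), [{1: 0.5, 2: 0.5}])
        assert val == pytest.approx(0.5)

    def test_product_over_loci_matches_log_sum(self):
        prof = np.array([[1, 2], [3, 3], [0, 0]])
        freqs = [{1: 0.3, 2: 0.7}, {3: 0.25, 4: 0.75}, {9: 1.0}]
        expected = np.exp(np.log(2 * 0.3 * 0.7) + np.log(0.25 ** 2))
        assert ca.pgen(prof, freqs) == pytest.approx(expected, abs=1e-12)

    def test_unknown_allele_error(self):
        with pytest.raises(KeyError):
            ca.pgen(np.array([[1, 3]]), [{1: 1.0}])

    def test_psex_pgen_one(self):
        series, flag = ca.psex(1.0, 4, 100)
        np.testing.assert_allclose(series, 1.0)
        assert not flag

    def test_psex_binomial_tail(self):
        series, _ = ca.psex(0.1, 2, 10)
        assert series[0] == pytest.approx(1 - 0.9 ** 9)
        # enumeration oracle
        oracle = sum(stats.binom.pmf(k, 9, 0.1) for k in range(1, 10))
        assert series[0] == pytest.approx(oracle)

    def test_psex_small_pgen_limit(self):
        series, flag = ca.psex(1e-9, 2, 1000)
        assert series[0] < 1e-5
        assert flag

    def test_psex_invalid_pgen(self):
        with pytest.raises(ValueError):
            ca.psex(0.0, 2, 10)

    def test_psex_shrinks_with_more_loci(self):
        freqs = [{1: 0.5, 2: 0.5}] * 6
        prof = np.array([[1, 2]] * 6)
        p3 = ca.pgen(prof[:3], freqs[:3])
        p6 = ca.pgen(prof, freqs)
        s3, _ = ca.psex(p3, 3, 50)
        s6, _ = ca.psex(p6, 3, 50)
        assert (s6 <= s3 + 1e-15).all()


class TestAccumulation:
    def test_separating_locus_constant_curve(self, rng):
        # one locus distinguishes all samples -> curve constant at G
        rows = [[(i, i), (1, 2)] for i in range(1, 7)]
        gt = make_table(rows)
        # with subsets of size 1, only one of two loci separates; use all
        # loci identical except the separating one at every position
        rows = [[(i, i), (i, i + 10)] for i in range(1, 7)]
        gt = make_table(rows)
        curve = ca.genotype_accumulation(gt, n_reps=20, rng=rng)
        np.testing.assert_allclose(curve.mean, 6)

    def test_final_point_equals_mlg_count(self, rng):
        calls = rng.integers(1, 4, size=(12, 4, 2))
        gt = make_table(np.sort(calls, axis=2))
        a = ca.assign_mlgs(gt)
        curve = ca.genotype_accumulation(gt, n_reps=30, rng=rng)
        assert curve.mean[-1] == len(a.mlg_ids)

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        calls = np.sort(rng.integers(1, 3, size=(10, 4, 2)), axis=2)
        gt = make_table(calls)
        curve = ca.genotype_accumulation(gt, n_reps=5, rng=rng,
                                         exhaustive=True)
        for m in range(1, 5):
            vals = []
            for comb in itertools.combinations(range(4), m):
                keys = {tuple(map(tuple, calls[i][list(comb)]))
                        for i in range(10)}
                vals.append(len(keys))
            assert curve.mean[m - 1] == pytest.approx(np.mean(vals))

    def test_mean_monotone_in_loci(self, rng):
        calls = np.sort(rng.integers(1, 5, size=(20, 5, 2)), axis=2)
        gt = make_table(calls)
        curve = ca.genotype_accumulation(gt, n_reps=5, rng=rng,
                                         exhaustive=True)
        assert (np.diff(curve.mean) >= -1e-12).all()
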