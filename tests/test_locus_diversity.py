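import itertools

import numpy as np
import pytest

from clonalscape import locus_diversity as ld
from clonalscape import synthetic_data as sd
from clonalscape.clonal_assignment import assign_mlgs, collapse_to_mlls

from conftest import make_table


class TestAlleleStats:
    def test_monomorphic(self):
        gt = make_table([[(1, 1), (2, 2)], [(1, 1), (2, 2)]])
        p, a = ld.allele_stats(gt)
        assert p == 0.0 and a == 1.0

    def test_partial_polymorphism(self, rng):
        # 10 loci, 8 polymorphic
        calls = np.ones((6, 10, 2), dtype=np.int64)
        for j in range(8):
            calls[0, j, 1] = 2
        gt = make_table(np.sort(calls, axis=2))
        p, a = ld.allele_stats(gt)
        assert p == pytest.approx(0.8)

    def test_counts_match_set_cardinality(self, rng):
        calls = np.sort(rng.integers(1, 6, size=(15, 4, 2)), axis=2)
        calls[0, 2] = 0
        gt = make_table(calls)
        _, a = ld.allele_stats(gt)
        brute = []
        for j in range(4):
            vals = set(calls[:, j, :].ravel()) - {0}
            brute.append(len(vals))
        assert a == pytest.approx(np.mean(brute))


class TestRarefiedRichness:
    def test_g_one_gives_one(self):
        assert ld.rarefied_richness_locus([10, 5, 3], 1) == pytest.approx(1.0)

    def test_g_equals_total_gives_allele_count(self):
        assert ld.rarefied_richness_locus([10, 5, 1], 16) == pytest.approx(3.0)

    def test_worked_example(self):
        # counts (10, 5, 1), g = 2
        val = ld.rarefied_richness_locus([10, 5, 1], 2)
        assert val == pytest.approx(0.875 + 0.5416667 + 0.125, abs=1e-6)

    def test_matches_exhaustive_enumeration(self):
        counts = [7, 5, 3, 1]  # 16 gene copies
        pool = sum(([i] * c for i, c in enumerate(counts)), [])
        for g in (2, 3, 5):
            exhaustive = np.mean([
                len(set(sub)) for sub in itertools.combinations(pool, g)])
            assert ld.rarefied_richness_locus(counts, g) == pytest.approx(
                exhaustive, abs=1e-12)

    def test_monotone_in_g_and_bounded_by_a(self):
        counts = [9, 4, 2, 1]
        vals = [ld.rarefied_richness_locus(counts, g) for g in range(1, 17)]
        assert (np.diff(vals) >= -1e-12).all()
        assert vals[-1] <= len(counts) + 1e-12

    def test_invalid_g(self):
        with pytest.raises(ValueError):
            ld.rarefied_richness_locus([5, 5], 0)


class TestHeterozygosity:
    def test_all_heterozygotes_excess(self):
        gt = make_table([[(1, 2)]] * 10)
        het = ld.heterozygosity_stats(gt)
        assert het.mean_ho == 1.0
        assert het.mean_fis < 0

    def test_all_homozygotes_deficit(self):
        gt = make_table([[(1, 1)]] * 5 + [[(2, 2)]] * 5)
        het = ld.heterozygosity_stats(gt)
        assert het.mean_ho == 0.0
        assert het.mean_fis > 0

    def test_unbiased_hs_worked_example(self):
        calls = [[(1, 2)], [(1, 1)], [(2, 3)], [(3, 3)], [(1, 2)], [(2, 2)]]
        gt = make_table(calls)
        het = ld.heterozygosity_stats(gt)
        # direct formula: n=6, Ho=3/6, freqs 1:4/12, 2:5/12, 3:3/12
        n = 6
        ho = 0.5
        s2 = (4 / 12) ** 2 + (5 / 12) ** 2 + (3 / 12) ** 2
        hs = (n / (n - 1)) * (1 - s2 - ho / (2 * n))
        assert het.hs[0] == pytest.approx(hs, abs=1e-12)
        assert het.fis[0] == pytest.approx(1 - ho / hs, abs=1e-12)

    def test_monomorphic_locus_fis_excluded(self):
        gt = make_table([[(1, 1), (1, 2)], [(1, 1), (2, 2)]])
        het = ld.heterozygosity_stats(gt)
        assert np.isnan(het.fis[0])
        assert np.isfinite(het.mean_fis)


class TestFisBootstrap:
    def test_identical_loci_zero_width(self, rng):
        gt = make_table([[(1, 2)] * 4] * 8)
        het = ld.heterozygosity_stats(gt)
        lo, hi = ld.fis_bootstrap_ci(het, 200, rng)
        assert lo == pytest.approx(hi)
        assert lo == pytest.approx(het.mean_fis)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(3)
        calls = np.sort(rng.integers(1, 5, size=(20, 6, 2)), axis=2)
        gt = make_table(calls)
        het = ld.heterozygosity_stats(gt)
        ci1 = ld.fis_bootstrap_ci(het, 500, np.random.default_rng(9))
        ci2 = ld.fis_bootstrap_ci(het, 500, np.random.default_rng(9))
        assert ci1 == ci2

    def test_ci_contains_point_estimate(self):
        covered = 0
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            calls = np.sort(rng.integers(1, 6, size=(30, 8, 2)), axis=2)
            gt = make_table(calls)
            het = ld.heterozygosity_stats(gt)
            lo, hi = ld.fis_bootstrap_ci(het, 500, rng)
            if lo - 1e-12 <= het.mean_fis <= hi + 1e-12:
                covered += 1
        assert covered >= 19

    def test_small_n_boot_warns(self, rng, caplog):
        import logging
        gt = make_table([[(1, 2), (1, 1)]] * 6)
        het = ld.heterozygosity_stats(gt)
        with caplog.at_level(logging.WARNING,
                             logger="clonalscape.locus_diversity"):
            ld.fis_bootstrap_ci(het, 50, rng)
        assert any("n_boot" in r.message for r in caplog.records)


class TestCloneCorrect:
    def test_all_unique_unchanged(self, rng):
        calls = np.sort(rng.integers(1, 30, size=(8, 5, 2)), axis=2)
        gt = make_table(calls)
        mll = {s: f"m{i}" for i, s in enumerate(gt.sample_ids)}
        cc = ld.clone_correct(gt, mll)
        assert cc.sample_ids == gt.sample_ids

    def test_monoclonal_site_keeps_one(self):
        gt = make_table([[(1, 2)]] * 20)
        mll = {s: "m1" for s in gt.sample_ids}
        cc = ld.clone_correct(gt, mll)
        assert cc.n_samples == 1
        assert cc.sample_ids == ["s01"]  # lexicographic tie-break

    def test_prefers_fewest_missing(self):
        calls = [[(1, 2), (0, 0)], [(1, 2), (3, 4)]]
        gt = make_table(calls)
        mll = {"s01": "m1", "s02": "m1"}
        cc = ld.clone_correct(gt, mll)
        assert cc.sample_ids == ["s02"]

    def test_one_per_mll_per_site(self):
        gt = make_table([[(1, 2)]] * 4, site_ids=["a", "a", "b", "b"])
        mll = {s: "m1" for s in gt.sample_ids}
        cc = ld.clone_correct(gt, mll)
        assert cc.n_samples == 2
        assert sorted(cc.site_ids) == ["a", "b"]


def test_clone_corrected_hs_not_higher_in_clonal_sites():
    """Clonal replication inflates H_s; one-per-MLL correction lowers it."""
    cfg = sd.SimulationConfig(seed=11, n_sites_nontidal=6, n_sites_tidal=2,
                              samples_per_site=30, n_widespread_clones=0,
                              clonal_fraction={"nontidal": 0.8, "tidal": 0.0},
                              missing_rate={"nontidal": 0.0, "tidal": 0.0})
    sites, _ = sd.simulate_riverscape(cfg)
    gt, truth = sd.simulate_genotypes(cfg, sites)
    a = collapse_to_mlls(assign_mlgs(gt))
    mll = a.mll_of_sample()
    cc = ld.clone_correct(gt, mll)
    by_site = gt.by_site()
    cc_by_site = cc.by_site()
    regime_of = sites.regime_of()
    checked = 0
    for site, idx in by_site.items():
        if regime_of[site] != "nontidal":
            continue
        cc_idx = cc_by_site.get(site)
        # restrict to sites where the comparison is meaningful: enough
        # clone-corrected genets that Nei's n/(n-1) factor is not dominant
        if cc_idx is None or cc_idx.size < 5 or cc_idx.size == idx.size:
            continue
        full = ld.heterozygosity_stats(gt, idx)
        corr = ld.heterozygosity_stats(cc, cc_idx)
        assert corr.mean_hs <= full.mean_hs + 1e-9
        checked += 1
    assert checked >= 2
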