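"""Relatedness estimator checks: an independent straight-from-the-equations
implementation, pedigree recovery, and the group/site summaries."""

from collections import Counter

import numpy as np
import pytest

from clonalscape import relatedness as rel
from clonalscape import synthetic_data as sd
from clonalscape.genotype_io import GenotypeTable

from conftest import make_table


# ---------------------------------------------------------------------------
# independent scalar implementation (explicit loops, lstsq solver)

def _power_sums_ref(freqs, n_genes):
    s2 = sum(p ** 2 for p in freqs.values())
    s3 = sum(p ** 3 for p in freqs.values())
    s4 = sum(p ** 4 for p in freqs.values())
    if n_genes is None or n_genes < 4:
        return s2, s3, s4
    n = n_genes
    a2 = (n * s2 - 1) / (n - 1)
    a3 = (n * n * s3 - 3 * (n - 1) * a2 - 1) / ((n - 1) * (n - 2))
    a4 = ((n ** 3 * s4 - 6 * (n - 1) * (n - 2) * a3 - 7 * (n - 1) * a2 - 1)
          / ((n - 1) * (n - 2) * (n - 3)))
    return a2, a3, a4


def wang_r_reference(geno_a, geno_b, freq_list, n_genes_list=None):
    """Scalar re-implementation: per-locus categories via multisets, loci
    combined by 1/(2 a2 - a3) weights, solved with numpy lstsq."""
    P = np.zeros(3)
    coefs = np.zeros(6)  # b, c, d, e, f, g
    wsum = 0.0
    for j, (ga, gb) in enumerate(zip(geno_a, geno_b)):
        ga, gb = tuple(ga), tuple(gb)
        if 0 in ga or 0 in gb:
            continue
        freqs = freq_list[j]
        ng = None if n_genes_list is None else n_genes_list[j]
        a2, a3, a4 = _power_sums_ref(freqs, ng)
        b = 2 * a2 ** 2 - a4
        c = a2 - 2 * a2 ** 2 + a4
        d = 4 * (a3 - a4)
        e = 2 * (a2 - 3 * a3 + 2 * a4)
        f = 4 * (a2 - a2 ** 2 - 2 * a3 + 2 * a4)
        g = 1 - 7 * a2 + 4 * a2 ** 2 + 10 * a3 - 8 * a4
        w = 1.0 / (2 * a2 - a3)
        shared = sum((Counter(ga) & Counter(gb)).values())
        if Counter(ga) == Counter(gb):
            cat = 0
        elif shared >= 1 and (ga[0] == ga[1] or gb[0] == gb[1]):
            cat = 1
        elif shared >= 1:
            cat = 2
        else:
            cat = None
        if cat is not None:
            P[cat] += w
        coefs += w * np.array([b, c, d, e, f, g])
        wsum += w
    if wsum == 0:
        raise ValueError("no comparable loci")
    P /= wsum
    b, c, d, e, f, g = coefs / wsum
    A = np.array([[c, 1 - b], [e, -d], [g, -f]])
    y = np.array([P[0] - b, P[1] - d, P[2] - f])
    k1, k2 = np.linalg.lstsq(A, y, rcond=None)[0]
    return k2 + 0.5 * k1


EQUI_FREQS = [{a: 1 / 8 for a in range(1, 9)} for _ in range(10)]


class TestDualImplementation:
    def test_agrees_with_reference_on_random_pairs(self, rng):
        params = rel.locus_params(EQUI_FREQS)
        for _ in range(100):
            a = np.sort(rng.integers(1, 9, size=(10, 2)), axis=1)
            b = np.sort(rng.integers(1, 9, size=(10, 2)), axis=1)
            got = rel.wang_r_pair(a, b, params)
            want = wang_r_reference(a, b, EQUI_FREQS)
            assert got == pytest.approx(want, abs=1e-10)

    def test_agrees_with_reference_uneven_freqs_and_missing(self, rng):
        freqs = []
        for _ in range(8):
            p = rng.dirichlet(np.ones(5))
            freqs.append({a + 1: p[a] for a in range(5)})
        params = rel.locus_params(freqs, n_genes=[40] * 8)
        for _ in range(50):
            a = np.sort(rng.integers(1, 6, size=(8, 2)), axis=1)
            b = np.sort(rng.integers(1, 6, size=(8, 2)), axis=1)
            a[rng.integers(0, 8)] = 0
            got = rel.wang_r_pair(a, b, params)
            want = wang_r_reference(a, b, freqs, [40] * 8)
            assert got == pytest.approx(want, abs=1e-10)

    def test_matrix_matches_scalar(self, rng):
        calls = np.sort(rng.integers(1, 9, size=(12, 10, 2)), axis=2)
        calls[3, 2] = 0
        gt = make_table(calls)
        rmat, lowconf = rel.wang_r_matrix(gt, small_sample_correction=False)
        from clonalscape.clonal_assignment import allele_frequencies
        params = rel.locus_params(allele_frequencies(gt))
        for i in range(12):
            for j in range(i + 1, 12):
                want = rel.wang_r_pair(gt.calls[i], gt.calls[j], params)
                assert rmat[i, j] == pytest.approx(want, abs=1e-10)
                assert rmat[j, i] == rmat[i, j]
        assert np.isnan(np.diag(rmat)).all()


class TestPedigreeRecovery:
    @pytest.mark.parametrize("relationship,expected", [
        ("unrelated", 0.0), ("half-sib", 0.25), ("full-sib", 0.5),
        ("parent-offspring", 0.5), ("clone", 1.0)])
    def test_mean_r_recovers_kinship(self, relationship, expected):
        rng = np.random.default_rng(hash(relationship) % 2 ** 31)
        params = rel.locus_params(EQUI_FREQS)
        a, b = sd.simulate_pedigree_pairs(1000, relationship, rng=rng)
        vals = np.array([rel.wang_r_pair(a[i], b[i], params)
                         for i in range(1000)])
        assert vals.mean() == pytest.approx(expected, abs=0.03)

    def test_category_mean_ordering(self):
        rng = np.random.default_rng(77)
        params = rel.locus_params(EQUI_FREQS)
        means = {}
        for relationship in ("unrelated", "half-sib", "full-sib", "clone"):
            a, b = sd.simulate_pedigree_pairs(500, relationship, rng=rng)
            means[relationship] = np.mean(
                [rel.wang_r_pair(a[i], b[i], params) for i in range(500)])
        assert (means["unrelated"] < means["half-sib"] < means["full-sib"]
                < means["clone"])

    def test_symmetry_in_pair_order(self, rng):
        params = rel.locus_params(EQUI_FREQS)
        a = np.sort(rng.integers(1, 9, size=(10, 2)), axis=1)
        b = np.sort(rng.integers(1, 9, size=(10, 2)), axis=1)
        assert rel.wang_r_pair(a, b, params) == pytest.approx(
            rel.wang_r_pair(b, a, params), abs=1e-12)


class TestGroupTest:
    def test_clone_group_maximal_statistic(self, rng):
        n = 20
        r = rng.normal(0, 0.1, size=(n, n))
        r = (r + r.T) / 2
        # group 'c' entirely clone-mates: within-pair r = 1
        labels = np.array(["c"] * 6 + ["o"] * 14)
        r[:6, :6] = 1.0
        np.fill_diagonal(r, np.nan)
        res = rel.group_relatedness_test(r, labels, n_shuffles=200, rng=rng)
        assert res.p_high["c"] == pytest.approx(1 / 201)

    def test_null_groups_not_significant(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            n = 20
            r = rng.normal(0, 0.2, size=(n, n))
            r = (r + r.T) / 2
            np.fill_diagonal(r, np.nan)
            labels = np.array(["a"] * 10 + ["b"] * 10)
            res = rel.group_relatedness_test(r, labels, n_shuffles=199,
                                             rng=rng)
            if min(res.p_high["a"], res.p_low["a"]) < 0.025:
                hits += 1
        assert hits <= 4  # ~5% expected false positives, tolerance for 20 runs

    def test_degenerate_groups_rejected(self, rng):
        r = np.zeros((3, 3))
        with pytest.raises(ValueError):
            rel.group_relatedness_test(r, ["a", "a", "b"], 10, rng)


class TestWithinAmongSummaries:
    def test_block_toy(self):
        # two sites of 3; within-site pairs r=1, between r=0
        n = 6
        r = np.zeros((n, n))
        r[:3, :3] = 1.0
        r[3:, 3:] = 1.0
        np.fill_diagonal(r, np.nan)
        sites = ["x"] * 3 + ["y"] * 3
        regimes = ["t"] * 6
        out = rel.within_among_summaries(r, sites, regimes)
        assert out["r_w"].tolist() == [1.0, 1.0]
        assert out["r_a"].tolist() == [0.0, 0.0]

    def test_matches_pairwise_brute_force(self, rng):
        n = 10
        r = rng.normal(size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, np.nan)
        sites = np.array(["x", "x", "x", "y", "y", "y", "y", "z", "z", "z"])
        regimes = np.array(["t"] * 7 + ["n"] * 3)
        out = rel.within_among_summaries(r, sites, regimes).set_index("site_id")
        # brute force for site x
        per_sample = []
        for i in range(3):
            vals = [r[i, j] for j in range(3) if j != i]
            per_sample.append(np.mean(vals))
        assert out.loc["x", "r_w"] == pytest.approx(np.mean(per_sample))
        per_sample_a = [np.mean([r[i, j] for j in range(3, 7)])
                        for i in range(3)]
        assert out.loc["x", "r_a"] == pytest.approx(np.mean(per_sample_a))

    def test_single_sample_site_nan(self):
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, np.nan)
        out = rel.within_among_summaries(
            r, ["x", "y", "y"], ["t", "t", "t"]).set_index("site_id")
        assert np.isnan(out.loc["x", "r_w"])

    def test_invariant_to_sample_order(self, rng):
        n = 8
        r = rng.normal(size=(n, n)); r = (r + r.T) / 2
        np.fill_diagonal(r, np.nan)
        sites = np.array(["x"] * 4 + ["y"] * 4)
        regimes = np.array(["t"] * 8)
        base = rel.within_among_summaries(r, sites, regimes)
        perm = rng.permutation(n)
        shuffled = rel.within_among_summaries(
            r[np.ix_(perm, perm)], sites[perm], regimes[perm])
        for site in ("x", "y"):
            a = base.set_index("site_id").loc[site]
            b = shuffled.set_index("site_id").loc[site]
            assert a["r_w"] == pytest.approx(b["r_w"])
            assert a["r_a"] == pytest.approx(b["r_a"])


def test_clonal_sites_have_higher_rw_than_clone_corrected():
    """With heavy clonality, within-site relatedness from all shoots exceeds
    the clone-corrected (one per MLL) version."""
    cfg = sd.SimulationConfig(seed=5, n_sites_nontidal=3, n_sites_tidal=2,
                              samples_per_site=15, n_widespread_clones=0,
                              missing_rate={"nontidal": 0.0, "tidal": 0.0})
    sites, _ = sd.simulate_riverscape(cfg)
    gt, truth = sd.simulate_genotypes(cfg, sites)
    regime_of = sites.regime_of()
    regimes = np.array([regime_of[s] for s in gt.site_ids])
    rmat, _ = rel.wang_r_matrix(gt)
    full = rel.within_among_summaries(rmat, gt.site_ids, regimes)
    # clone-correct by truth labels: one shoot per genet per site
    seen, keep = set(), []
    for i, s in enumerate(gt.sample_ids):
        key = (gt.site_ids[i], truth[s])
        if key not in seen:
            seen.add(key)
            keep.append(i)
    cc = gt.subset(keep)
    cc_r, _ = rel.wang_r_matrix(cc)
    cc_sum = rel.within_among_summaries(
        cc_r, cc.site_ids, [regime_of[s] for s in cc.site_ids])
    merged = full.merge(cc_sum, on="site_id", suffixes=("", "_cc"))
    clonal = merged[merged["regime"] == "nontidal"].dropna(subset=["r_w", "r_w_cc"])
    assert (clonal["r_w"] >= clonal["r_w_cc"] - 1e-9).all()
    assert clonal["r_w"].mean() > clonal["r_w_cc"].mean()
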