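"""Among-population differentiation: Weir-Cockerham theta, Hedrick's G''ST
and Jost's D_est, with bootstrap confidence intervals.

theta follows the 1984 variance-component estimator (components a, b, c per
allele per locus, combined as sum(a)/sum(a+b+c)); G''ST and D_est are built
on Nei & Chesser (1983) unbiased H_S and H_T.  Negative estimates are
reported as-is -- truncation at zero would bias the bootstrap CIs used for
significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING_ALLELE, GenotypeTable


@dataclass
class VarianceComponents:
    """Per-locus summed W-C components (a, b, c) over alleles."""

    locus_names: list[str]
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def theta(self) -> float:
        tot = (self.a + self.b + self.c).sum()
        return float(self.a.sum() / tot) if tot != 0 else float("nan")


@dataclass
class HSHTComponents:
    """Per-locus Nei-Chesser unbiased H_S / H_T (and mean H_o)."""

    locus_names: list[str]
    hs: np.ndarray
    ht: np.ndarray
    ho: np.ndarray
    k: int

    @property
    def mean_hs(self) -> float:
        return float(np.nanmean(self.hs))

    @property
    def mean_ht(self) -> float:
        return float(np.nanmean(self.ht))


def _pop_allele_counts(gt: GenotypeTable, pops: np.ndarray, j: int):
    """Per-pop diploid sample sizes, allele counts and het counts at locus j."""
    labels = sorted(set(pops))
    alleles = np.unique(gt.calls[:, j, :][gt.calls[:, j, :] != MISSING_ALLELE])
    n_i = np.zeros(len(labels))
    counts = np.zeros((len(labels), alleles.size))
    het = np.zeros((len(labels), alleles.size))
    aidx = {a: k for k, a in enumerate(alleles)}
    for pi, lab in enumerate(labels):
        calls = gt.calls[pops == lab, j, :]
        ok = calls[:, 0] != MISSING_ALLELE
        calls = calls[ok]
        n_i[pi] = calls.shape[0]
        for a1, a2 in calls:
            counts[pi, aidx[a1]] += 1
            counts[pi, aidx[a2]] += 1
            if a1 != a2:
                het[pi, aidx[a1]] += 1
                het[pi, aidx[a2]] += 1
    return labels, alleles, n_i, counts, het


def wc_components(gt: GenotypeTable, pops) -> VarianceComponents:
    """Weir-Cockerham (1984) variance components per locus.

    Populations with no calls at a locus are dropped for that locus; loci
    monomorphic overall contribute zero components.
    """
    pops = np.asarray(pops)
    if len(set(pops)) < 2:
        raise ValueError("need at least two populations")
    L = gt.n_loci
    a_l = np.zeros(L); b_l = np.zeros(L); c_l = np.zeros(L)
    for j in range(L):
        _, alleles, n_i, counts, het = _pop_allele_counts(gt, pops, j)
        keep = n_i > 0
        n_i, counts, het = n_i[keep], counts[keep], het[keep]
        r = n_i.size
        if r < 2 or alleles.size < 2:
            continue
        nbar = n_i.mean()
        nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1.0)
        p_i = counts / (2.0 * n_i[:, None])
        h_i = het / n_i[:, None]
        pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
        s2 = ((n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0)
              / ((r - 1.0) * nbar))
        hbar = (n_i[:, None] * h_i).sum(axis=0) / (r * nbar)
        inner = (pbar * (1 - pbar) - (r - 1.0) / r * s2)
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner
                                     - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
        a_l[j], b_l[j], c_l[j] = a.sum(), b.sum(), c.sum()
    return VarianceComponents(list(gt.locus_names), a_l, b_l, c_l)


def wc_fst(gt: GenotypeTable, pops) -> float:
    """Multi-locus Weir-Cockerham theta."""
    return wc_components(gt, pops).theta


def nei_chesser_components(gt: GenotypeTable, pops) -> HSHTComponents:
    """Unbiased H_S and H_T per locus (Nei & Chesser 1983).

    H_S = (ntilde/(ntilde-1)) (1 - mean_pops sum p^2 - H_o/(2 ntilde)) with
    ntilde the harmonic mean sample size; H_T = 1 - sum pbar^2 + H_S/(k
    ntilde) - H_o/(2 k ntilde).  Populations with a single sample at a locus
    are excluded for that locus.
    """
    pops = np.asarray(pops)
    k_global = len(set(pops))
    if k_global < 2:
        raise ValueError("need at least two populations")
    L = gt.n_loci
    hs = np.full(L, np.nan); ht = np.full(L, np.nan); ho_l = np.full(L, np.nan)
    for j in range(L):
        _, alleles, n_i, counts, het = _pop_allele_counts(gt, pops, j)
        keep = n_i > 1
        n_i, counts = n_i[keep], counts[keep]
        k = n_i.size
        if k < 2:
            continue
        p_i = counts / (2.0 * n_i[:, None])
        # observed heterozygosity per pop from diploid calls
        calls_het = het[keep]
        ho_i = calls_het.sum(axis=1) / (2.0 * n_i)   # each het call counted twice
        ntilde = k / (1.0 / n_i).sum()
        ho = ho_i.mean()
        sum_p2 = (p_i ** 2).sum(axis=1).mean()
        hs_j = (ntilde / (ntilde - 1.0)) * (1.0 - sum_p2 - ho / (2.0 * ntilde))
        pbar = p_i.mean(axis=0)
        ht_j = (1.0 - (pbar ** 2).sum() + hs_j / (k * ntilde)
                - ho / (2.0 * k * ntilde))
        hs[j], ht[j], ho_l[j] = hs_j, ht_j, ho
    return HSHTComponents(list(gt.locus_names), hs, ht, ho_l, k_global)


def hedrick_gst(hs: float, ht: float, k: int) -> float:
    """G''ST = k (H_T - H_S) / ((k H_T - H_S)(1 - H_S))."""
    if ht <= 0:
        raise ValueError("H_T must be positive")
    if hs >= 1:
        raise ValueError("G''ST undefined for H_S = 1")
    return float(k * (ht - hs) / ((k * ht - hs) * (1.0 - hs)))


def jost_d(hs: float, ht: float, k: int) -> float:
    """D_est = (k/(k-1)) (H_T - H_S)/(1 - H_S)."""
    if hs >= 1:
        raise ValueError("D_est undefined for H_S = 1")
    return float((k / (k - 1.0)) * (ht - hs) / (1.0 - hs))


def jost_d_multilocus(comp: HSHTComponents, how: str = "harmonic") -> float:
    """Combine per-locus D_est across loci.

    ``harmonic`` uses the harmonic mean of per-locus values (with the
    standard 1/(1 + D) transform to accommodate non-positive loci);
    ``arithmetic`` applies the formula to across-locus mean H_S/H_T.
    """
    valid = ~np.isnan(comp.hs)
    if how == "arithmetic":
        return jost_d(float(np.mean(comp.hs[valid])),
                      float(np.mean(comp.ht[valid])), comp.k)
    d_l = np.array([jost_d(h, t, comp.k)
                    for h, t in zip(comp.hs[valid], comp.ht[valid])])
    # harmonic mean via mean of 1/(1/D ...): use the positive-shifted form
    # 1/D_harm = mean(1/D_l); non-positive loci make the plain harmonic mean
    # ill-defined, so fall back to the arithmetic combination then
    if (d_l <= 0).any():
        return float(d_l.mean())
    return float(d_l.size / (1.0 / d_l).sum())


def global_differentiation(gt: GenotypeTable, pops,
                           d_how: str = "harmonic") -> dict[str, float]:
    comp = nei_chesser_components(gt, pops)
    return {
        "fst": wc_fst(gt, pops),
        "gst_hedrick": hedrick_gst(comp.mean_hs, comp.mean_ht, comp.k),
        "d_est": jost_d_multilocus(comp, d_how),
        "hs": comp.mean_hs,
        "ht": comp.mean_ht,
        "k": comp.k,
    }


def pairwise_matrices(gt: GenotypeTable, pops,
                      ) -> dict[str, "pd.DataFrame"]:
    """Pairwise F_ST / G''ST / D_est between all population pairs.

    Components are re-estimated per pair (not extracted from the global
    fit).
    """
    import pandas as pd

    pops = np.asarray(pops)
    labels = sorted(set(pops))
    k = len(labels)
    mats = {m: np.full((k, k), 0.0) for m in ("fst", "gst_hedrick", "d_est")}
    for i in range(k):
        for j in range(i + 1, k):
            sel = np.isin(pops, [labels[i], labels[j]])
            sub = gt.subset(sel)
            res = global_differentiation(sub, pops[sel])
            for m in mats:
                mats[m][i, j] = mats[m][j, i] = res[m]
    return {m: pd.DataFrame(v, index=labels, columns=labels)
            for m, v in mats.items()}


# ---------------------------------------------------------------------------
# bootstrap

def differentiation_bootstrap(gt: GenotypeTable, pops, measure: str = "fst",
                              unit: str = "loci", n_boot: int = 1000,
                              rng: np.random.Generator | None = None,
                              ) -> tuple[float, float]:
    """Percentile 95% CI for a differentiation measure.

    ``unit='loci'`` resamples loci with replacement (the convention for
    theta); ``unit='individuals'`` resamples individuals with replacement
    within each population (the convention for G''ST / D_est).
    """
    rng = np.random.default_rng() if rng is None else rng
    pops = np.asarray(pops)
    if unit == "loci":
        L = gt.n_loci
        if L < 2:
            raise ValueError("loci bootstrap needs >= 2 loci")
        if measure == "fst":
            comp = wc_components(gt, pops)
            picks = rng.integers(0, L, size=(n_boot, L))
            a = comp.a[picks].sum(axis=1)
            tot = (comp.a + comp.b + comp.c)[picks].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                boots = a / tot
        else:
            nc = nei_chesser_components(gt, pops)
            valid = np.flatnonzero(~np.isnan(nc.hs))
            picks = valid[rng.integers(0, valid.size, size=(n_boot, valid.size))]
            mh = nc.hs[picks].mean(axis=1)
            mt = nc.ht[picks].mean(axis=1)
            if measure == "gst_hedrick":
                boots = np.array([hedrick_gst(h, t, nc.k)
                                  for h, t in zip(mh, mt)])
            elif measure == "d_est":
                boots = np.array([jost_d(h, t, nc.k) for h, t in zip(mh, mt)])
            else:
                raise ValueError(f"unknown measure {measure!r}")
    elif unit == "individuals":
        labels = sorted(set(pops))
        group_idx = {lab: np.flatnonzero(pops == lab) for lab in labels}
        if any(v.size < 2 for v in group_idx.values()):
            raise ValueError("individual bootstrap needs >= 2 samples per pop")
        boots = np.empty(n_boot)
        for t in range(n_boot):
            idx = np.concatenate([
                rng.choice(v, size=v.size, replace=True)
                for v in group_idx.values()])
            # resampling duplicates samples, so rebuild with unique ids
            sub = GenotypeTable(
                [f"b{q}" for q in range(idx.size)],
                [pops[q] for q in idx],
                list(gt.locus_names), gt.calls[idx].copy())
            res = global_differentiation(sub, pops[idx])
            boots[t] = res[measure]
    else:
        raise ValueError(f"unknown unit {unit!r}")
    boots = boots[np.isfinite(boots)]
    return (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
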