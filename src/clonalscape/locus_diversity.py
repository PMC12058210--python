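"""Within-population allelic and heterozygosity statistics.

Per site (or regime, or river): proportion of polymorphic loci P, mean
alleles per locus A, allelic richness rarefied to a fixed number of gene
copies (hypergeometric expectation), observed and Nei-unbiased expected
heterozygosity, and F_IS = 1 - H_o/H_s with a loci-bootstrap confidence
interval.  Clone correction (one sample per MLL per site) and the deltas it
induces are also provided, since H_s inflation by clonal replicates is a
standard clonality signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .genotype_io import MISSING_ALLELE, GenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class HetStats:
    """Per-locus and summary heterozygosity statistics for one population."""

    locus_names: list[str]
    n: np.ndarray            # diploid calls per locus
    ho: np.ndarray
    hs: np.ndarray           # Nei (1987) unbiased gene diversity
    fis: np.ndarray          # per locus; NaN where H_s = 0
    mean_ho: float
    mean_hs: float
    mean_fis: float          # ratio-of-means 1 - mean(Ho)/mean(Hs)
    fis_variance: float      # across-locus variance of per-locus F_IS


def _locus_allele_counts(gt: GenotypeTable, idx, j: int,
                         ) -> tuple[np.ndarray, np.ndarray]:
    flat = gt.calls[idx, j, :].ravel()
    flat = flat[flat != MISSING_ALLELE]
    return np.unique(flat, return_counts=True)


def allele_stats(gt: GenotypeTable, idx=None) -> tuple[float, float]:
    """(P, A): fraction of polymorphic loci and mean alleles per locus.

    Loci with zero calls in the scope are excluded from both denominators.
    """
    idx = np.arange(gt.n_samples) if idx is None else np.asarray(idx)
    n_alleles = []
    for j in range(gt.n_loci):
        vals, _ = _locus_allele_counts(gt, idx, j)
        if vals.size == 0:
            logger.info("locus %s has no calls in scope; excluded",
                        gt.locus_names[j])
            continue
        n_alleles.append(vals.size)
    if not n_alleles:
        raise ValueError("no genotyped loci in scope")
    n_alleles = np.array(n_alleles)
    return float((n_alleles >= 2).mean()), float(n_alleles.mean())


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness_locus(counts, g: int) -> float:
    """Expected allele count in a sample of g gene copies (hypergeometric)."""
    if g < 1:
        raise ValueError("g must be >= 1")
    counts = np.asarray(list(counts), dtype=float)
    total = counts.sum()
    if total < g:
        raise ValueError("fewer gene copies than rarefaction size")
    keep = total - counts >= g
    expected = np.ones_like(counts)
    if keep.any():
        expected[keep] = 1.0 - np.exp(
            _log_comb(total - counts[keep], g) - _log_comb(total, g))
    return float(expected.sum())


def rarefied_richness(gt: GenotypeTable, idx=None, g: int = 15) -> float:
    """Mean rarefied allelic richness across loci with >= g gene copies."""
    idx = np.arange(gt.n_samples) if idx is None else np.asarray(idx)
    vals = []
    for j in range(gt.n_loci):
        _, cnt = _locus_allele_counts(gt, idx, j)
        if cnt.sum() >= g:
            vals.append(rarefied_richness_locus(cnt, g))
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def heterozygosity_stats(gt: GenotypeTable, idx=None) -> HetStats:
    """H_o, Nei-unbiased H_s and F_IS per locus plus across-locus summaries.

    H_s = (n/(n-1)) * (1 - sum p_hat^2 - H_o/(2n)); F_IS = 1 - H_o/H_s with
    the summary F_IS computed as a ratio of means across loci (per-locus
    values are also returned; loci with H_s = 0 are excluded from the mean
    and variance).
    """
    idx = np.arange(gt.n_samples) if idx is None else np.asarray(idx)
    L = gt.n_loci
    n = np.zeros(L); ho = np.full(L, np.nan); hs = np.full(L, np.nan)
    for j in range(L):
        calls = gt.calls[idx, j, :]
        ok = calls[:, 0] != MISSING_ALLELE
        nj = int(ok.sum())
        n[j] = nj
        if nj < 2:
            continue
        het = calls[ok, 0] != calls[ok, 1]
        ho[j] = het.mean()
        flat = calls[ok].ravel()
        _, cnt = np.unique(flat, return_counts=True)
        p = cnt / cnt.sum()
        hs[j] = (nj / (nj - 1.0)) * (1.0 - (p ** 2).sum() - ho[j] / (2.0 * nj))
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = 1.0 - ho / hs
    fis[np.isclose(hs, 0.0)] = np.nan
    valid = ~np.isnan(hs)
    mean_ho = float(np.nanmean(ho[valid]))
    mean_hs = float(np.nanmean(hs[valid]))
    mean_fis = 1.0 - mean_ho / mean_hs if mean_hs > 0 else float("nan")
    good_fis = fis[~np.isnan(fis)]
    fis_var = float(np.var(good_fis, ddof=1)) if good_fis.size >= 2 else float("nan")
    return HetStats(list(gt.locus_names), n, ho, hs, fis,
                    mean_ho, mean_hs, mean_fis, fis_var)


def fis_bootstrap_ci(het: HetStats, n_boot: int = 1000,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[float, float]:
    """Percentile 95% CI of the ratio-of-means F_IS, resampling loci."""
    if n_boot < 100:
        logger.warning("fis_bootstrap_ci with n_boot=%d < 100", n_boot)
    rng = np.random.default_rng() if rng is None else rng
    valid = ~np.isnan(het.hs) & ~np.isnan(het.ho)
    ho, hs = het.ho[valid], het.hs[valid]
    L = ho.size
    if L < 2:
        raise ValueError("bootstrap needs at least two loci")
    picks = rng.integers(0, L, size=(n_boot, L))
    mh = ho[picks].mean(axis=1)
    ms = hs[picks].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = 1.0 - mh / ms
    boots = boots[np.isfinite(boots)]
    return (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))


def clone_correct(gt: GenotypeTable, mll_of_sample: dict[str, str],
                  ) -> GenotypeTable:
    """One sample per MLL per site: fewest missing loci, then lexicographic id.

    Samples without an MLL assignment (ambiguous/empty) are dropped.
    """
    miss = gt.missing_mask.sum(axis=1)
    best: dict[tuple[str, str], int] = {}
    for i, sid in enumerate(gt.sample_ids):
        mll = mll_of_sample.get(sid)
        if mll is None:
            continue
        key = (gt.site_ids[i], mll)
        j = best.get(key)
        if j is None or (miss[i], sid) < (miss[j], gt.sample_ids[j]):
            best[key] = i
    keep = sorted(best.values())
    return gt.subset(keep)
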