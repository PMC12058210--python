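"""Spatial genetic structure: chord distance, Mantel IBD tests,
correspondence analysis, and rank correlations with river position.

The genetic distance is the angular (Edwards) chord distance on per-locus
allele-frequency simplices; isolation by distance is assessed with a
one-sided Mantel permutation test (positive association, the convention for
IBD); ordination uses classical correspondence analysis of the site x allele
count table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING_ALLELE, GenotypeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# allele frequency tables

def site_allele_counts(gt: GenotypeTable) -> pd.DataFrame:
    """Site x (locus, allele) contingency table of allele copy counts."""
    sites = sorted(set(gt.site_ids))
    site_idx = {s: i for i, s in enumerate(sites)}
    cols = []
    blocks = []
    for j, locus in enumerate(gt.locus_names):
        calls = gt.calls[:, j, :]
        ok = calls[:, 0] != MISSING_ALLELE
        alleles = np.unique(calls[ok])
        block = np.zeros((len(sites), alleles.size))
        aidx = {a: k for k, a in enumerate(alleles)}
        for i in np.flatnonzero(ok):
            si = site_idx[gt.site_ids[i]]
            block[si, aidx[calls[i, 0]]] += 1
            block[si, aidx[calls[i, 1]]] += 1
        blocks.append(block)
        cols.extend([(locus, int(a)) for a in alleles])
    table = np.hstack(blocks)
    return pd.DataFrame(table, index=sites,
                        columns=pd.MultiIndex.from_tuples(cols,
                                                          names=["locus", "allele"]))


def site_allele_freqs(counts: pd.DataFrame) -> pd.DataFrame:
    """Normalise a site x (locus, allele) count table per locus."""
    out = counts.astype(float).copy()
    for locus in counts.columns.get_level_values("locus").unique():
        block = out[locus]
        totals = block.sum(axis=1)
        out.loc[:, pd.IndexSlice[locus, :]] = block.div(
            totals.replace(0, np.nan), axis=0).to_numpy()
    return out


# ---------------------------------------------------------------------------
# Edwards chord distance

def edwards_chord_pair(freq_a: pd.Series | np.ndarray,
                       freq_b: pd.Series | np.ndarray,
                       locus_index: np.ndarray) -> float:
    """D = sqrt(1 - (1/L) sum_l sum_a sqrt(p_A p_B)).

    ``locus_index`` labels each frequency entry with its locus; loci with
    undefined frequencies in either profile are excluded with L renormalised.
    """
    fa = np.asarray(freq_a, dtype=float)
    fb = np.asarray(freq_b, dtype=float)
    locus_index = np.asarray(locus_index)
    affinity = 0.0
    n_loci = 0
    for locus in pd.unique(locus_index):
        sel = locus_index == locus
        pa, pb = fa[sel], fb[sel]
        if np.isnan(pa).any() or np.isnan(pb).any():
            logger.info("locus %s dropped from chord distance", locus)
            continue
        affinity += float(np.sqrt(pa * pb).sum())
        n_loci += 1
    if n_loci == 0:
        raise ValueError("no comparable loci for chord distance")
    val = 1.0 - affinity / n_loci
    return float(np.sqrt(max(val, 0.0)))


def edwards_chord_matrix(gt: GenotypeTable) -> pd.DataFrame:
    counts = site_allele_counts(gt)
    freqs = site_allele_freqs(counts)
    loci = freqs.columns.get_level_values("locus").to_numpy()
    sites = list(freqs.index)
    k = len(sites)
    mat = np.zeros((k, k))
    arr = freqs.to_numpy()
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = edwards_chord_pair(arr[i], arr[j], loci)
    return pd.DataFrame(mat, index=sites, columns=sites)


# ---------------------------------------------------------------------------
# Mantel test

@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    scope: str = ""


def mantel_test(genetic: np.ndarray, geographic: np.ndarray,
                n_perm: int = 999, rng: np.random.Generator | None = None,
                scope: str = "") -> MantelResult:
    """One-sided Mantel test (positive association).

    r is the Pearson correlation over the n(n-1)/2 off-diagonal pairs;
    row/column labels of one matrix are permuted jointly and
    p = (#{r_perm >= r_obs} + 1)/(n_perm + 1).
    """
    rng = np.random.default_rng() if rng is None else rng
    a = np.asarray(genetic, dtype=float)
    b = np.asarray(geographic, dtype=float)
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 entities")
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    if np.std(va) == 0 or np.std(b[iu]) == 0:
        raise ValueError("constant distance matrix")

    def corr_with(bm):
        vb = bm[iu]
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = corr_with(b)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(b[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    return MantelResult(r_obs, (count + 1) / (n_perm + 1), n_perm, scope)


# ---------------------------------------------------------------------------
# correspondence analysis

@dataclass
class CAResult:
    row_coords: pd.DataFrame       # site principal coordinates
    inertia_pct: np.ndarray        # per retained axis, non-increasing
    total_inertia: float


def correspondence_analysis(table: pd.DataFrame, n_axes: int | None = None,
                            ) -> CAResult:
    """Classical CA of a contingency table (rows mass-weighted).

    Centered standardised residuals S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}
    are decomposed by SVD; row principal coordinates are D_r^{-1/2} U Sigma
    and axis inertias sigma_i^2 / total.  All-zero rows/columns are dropped
    with a warning.
    """
    X = np.asarray(table, dtype=float)
    row_keep = X.sum(axis=1) > 0
    col_keep = X.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        logger.warning("CA: dropping %d all-zero rows, %d all-zero columns",
                       (~row_keep).sum(), (~col_keep).sum())
    X = X[np.ix_(row_keep, col_keep)]
    if X.sum() == 0:
        raise ValueError("contingency table has zero total")
    P = X / X.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > 1e-12 * sv.max() if sv.max() > 0 else np.zeros_like(sv, bool)
    if not keep.any():
        raise ValueError("contingency table has rank 0 after centering")
    U, sv = U[:, keep], sv[keep]
    total = float((sv ** 2).sum())
    if n_axes is not None:
        U, sv = U[:, :n_axes], sv[:n_axes]
    coords = (U * sv) / np.sqrt(r)[:, None]
    index = np.asarray(table.index)[row_keep]
    axes = [f"axis{i+1}" for i in range(coords.shape[1])]
    return CAResult(pd.DataFrame(coords, index=index, columns=axes),
                    100.0 * sv ** 2 / total, total)


# ---------------------------------------------------------------------------
# rank correlation with river km

def spearman_vs_riverkm(values, river_km) -> tuple[float, float]:
    """Spearman rho (midrank ties) of a site statistic against river km.

    p via the t approximation; NaN sites are dropped pairwise; a constant
    vector yields (nan, nan).
    """
    v = np.asarray(values, dtype=float)
    k = np.asarray(river_km, dtype=float)
    ok = ~(np.isnan(v) | np.isnan(k))
    v, k = v[ok], k[ok]
    if v.size < 4:
        raise ValueError("need at least 4 paired sites")
    if np.std(v) == 0 or np.std(k) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(v, k)
    return float(rho), float(p)
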