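"""Pairwise relatedness (Wang's moment estimator) and group permutation tests.

The estimator works from the four observable allele-sharing categories of a
dyad at a locus -- identical genotypes; one homozygote sharing its allele
with a heterozygote; two heterozygotes sharing one allele; nothing shared --
whose expected frequencies are linear in the probabilities k1 (one pair of
genes identical by descent) and k2 (both pairs IBD):

    E[P1] = b + c*k1 + (1 - b)*k2
    E[P2] = d + e*k1 - d*k2
    E[P3] = f + g*k1 - f*k2

with locus constants built from the allele-frequency power sums
a_m = sum_i p_i^m (bias-corrected for the reference sample size):

    b = 2*a2^2 - a4            c = a2 - 2*a2^2 + a4
    d = 4*(a3 - a4)            e = 2*(a2 - 3*a3 + 2*a4)
    f = 4*(a2 - a2^2 - 2*a3 + 2*a4)
    g = 1 - 7*a2 + 4*a2^2 + 10*a3 - 8*a4

Loci are combined by weighted averages of the observed category indicators
and of the constants, with locus weight w = 1/u, u = 2*a2 - a3 (more
polymorphic loci are more informative and get larger weight); weights are
renormalised over the loci resolved in both members of a pair.  The
overdetermined 3x2 linear system is then solved by least squares, and
r = k2 + k1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING_ALLELE, GenotypeTable
from .clonal_assignment import allele_frequencies

LOW_CONFIDENCE_MIN_LOCI = 5


@dataclass
class LocusParams:
    """Per-locus constants for the category-moment estimator."""

    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    e: np.ndarray
    f: np.ndarray
    g: np.ndarray
    w: np.ndarray  # informativeness weight 1/u


def unbiased_power_sums(freqs: dict[int, float], n_genes: int,
                        ) -> tuple[float, float, float]:
    """Bias-corrected a2, a3, a4 from plug-in frequencies of n_genes copies.

    Inverts the multinomial moment identities, e.g.
    E[sum p_hat^2] = ((n-1) a2 + 1)/n.  For n_genes < 4 the plug-in sums are
    returned unchanged.
    """
    p = np.array(list(freqs.values()))
    s2, s3, s4 = float((p ** 2).sum()), float((p ** 3).sum()), float((p ** 4).sum())
    n = n_genes
    if n < 4:
        return s2, s3, s4
    a2 = (n * s2 - 1.0) / (n - 1.0)
    a3 = (n ** 2 * s3 - 3.0 * (n - 1.0) * a2 - 1.0) / ((n - 1.0) * (n - 2.0))
    a4 = (n ** 3 * s4 - 6.0 * (n - 1.0) * (n - 2.0) * a3
          - 7.0 * (n - 1.0) * a2 - 1.0) / ((n - 1.0) * (n - 2.0) * (n - 3.0))
    return a2, a3, a4


def locus_params(freq_list: list[dict[int, float]],
                 n_genes: list[int] | np.ndarray | None = None) -> LocusParams:
    """Estimator constants for each locus.

    ``n_genes`` gives the number of gene copies behind each frequency
    estimate (for the small-sample correction); None skips the correction.
    """
    L = len(freq_list)
    b = np.zeros(L); c = np.zeros(L); d = np.zeros(L)
    e = np.zeros(L); f = np.zeros(L); g = np.zeros(L); w = np.zeros(L)
    for j, freqs in enumerate(freq_list):
        if not freqs:
            w[j] = 0.0
            continue
        if n_genes is None:
            p = np.array(list(freqs.values()))
            a2, a3, a4 = float((p**2).sum()), float((p**3).sum()), float((p**4).sum())
        else:
            a2, a3, a4 = unbiased_power_sums(freqs, int(n_genes[j]))
        b[j] = 2 * a2 ** 2 - a4
        c[j] = a2 - 2 * a2 ** 2 + a4
        d[j] = 4 * (a3 - a4)
        e[j] = 2 * (a2 - 3 * a3 + 2 * a4)
        f[j] = 4 * (a2 - a2 ** 2 - 2 * a3 + 2 * a4)
        g[j] = 1 - 7 * a2 + 4 * a2 ** 2 + 10 * a3 - 8 * a4
        u = 2 * a2 - a3
        w[j] = 1.0 / u if u > 0 else 0.0
    return LocusParams(b, c, d, e, f, g, w)


def _categories(calls_a: np.ndarray, calls_b: np.ndarray,
                ) -> tuple[np.ndarray, ...]:
    """Boolean (.., L) arrays: shared-resolution mask and categories 1-3.

    ``calls_a`` is (L, 2) and ``calls_b`` (L, 2) or (n, L, 2); calls must be
    order-normalised so multiset comparisons reduce to positionwise tests.
    """
    a1, a2_ = calls_a[..., 0], calls_a[..., 1]
    b1, b2 = calls_b[..., 0], calls_b[..., 1]
    ok = (a1 != MISSING_ALLELE) & (b1 != MISSING_ALLELE)
    identical = (b1 == a1) & (b2 == a2_)
    anymatch = (b1 == a1) | (b1 == a2_) | (b2 == a1) | (b2 == a2_)
    homo_a = a1 == a2_
    homo_b = b1 == b2
    cat1 = ok & identical
    cat2 = ok & ~identical & anymatch & (homo_a | homo_b)
    cat3 = ok & ~identical & anymatch & ~homo_a & ~homo_b
    return ok, cat1, cat2, cat3


def _solve(P1, P2, P3, b, c, d, e, f, g):
    """Least-squares (k1, k2) from the three category moment equations."""
    # design matrix rows: (c, 1-b), (e, -d), (g, -f)
    y1, y2, y3 = P1 - b, P2 - d, P3 - f
    m11 = c * c + e * e + g * g
    m12 = c * (1 - b) + e * (-d) + g * (-f)
    m22 = (1 - b) ** 2 + d * d + f * f
    v1 = c * y1 + e * y2 + g * y3
    v2 = (1 - b) * y1 - d * y2 - f * y3
    det = m11 * m22 - m12 * m12
    with np.errstate(divide="ignore", invalid="ignore"):
        k1 = (m22 * v1 - m12 * v2) / det
        k2 = (m11 * v2 - m12 * v1) / det
        r = np.where(np.abs(det) > 1e-12, k2 + 0.5 * k1, np.nan)
    return r


def wang_r_pair(calls_a: np.ndarray, calls_b: np.ndarray,
                params: LocusParams) -> float:
    """Wang's r for one dyad; loci missing in either member are excluded."""
    ok, c1, c2, c3 = _categories(np.asarray(calls_a), np.asarray(calls_b))
    wsum = float((params.w * ok).sum())
    if wsum == 0:
        raise ValueError("no comparable loci for this pair")
    wm = params.w * ok / wsum
    P1, P2, P3 = float((wm * c1).sum()), float((wm * c2).sum()), float((wm * c3).sum())
    b = float((wm * params.b).sum()); c = float((wm * params.c).sum())
    d = float((wm * params.d).sum()); e = float((wm * params.e).sum())
    f = float((wm * params.f).sum()); g = float((wm * params.g).sum())
    return float(_solve(P1, P2, P3, b, c, d, e, f, g))


def wang_r_matrix(gt: GenotypeTable, ref_idx=None,
                  freq_list: list[dict[int, float]] | None = None,
                  small_sample_correction: bool = True,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Wang r.

    Reference allele frequencies default to the full analysed sample set
    (``ref_idx`` restricts, e.g. to clone-corrected representatives).
    Returns the symmetric matrix (nan diagonal, nan for incomparable pairs)
    and a boolean low-confidence mask for pairs sharing fewer than
    ``LOW_CONFIDENCE_MIN_LOCI`` resolved loci.
    """
    if freq_list is None:
        freq_list = allele_frequencies(gt, ref_idx)
    if small_sample_correction:
        if ref_idx is None:
            nm = (~gt.missing_mask).sum(axis=0) * 2
        else:
            nm = (~gt.missing_mask[np.asarray(ref_idx)]).sum(axis=0) * 2
        params = locus_params(freq_list, nm)
    else:
        params = locus_params(freq_list)
    n = gt.n_samples
    r = np.full((n, n), np.nan)
    lowconf = np.zeros((n, n), dtype=bool)
    calls = gt.calls
    for i in range(n - 1):
        rows = calls[i + 1:]
        ok, c1, c2, c3 = _categories(calls[i], rows)
        wsum = (params.w * ok).sum(axis=1)
        good = wsum > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            wm = params.w * ok / wsum[:, None]
        P1 = (wm * c1).sum(axis=1); P2 = (wm * c2).sum(axis=1)
        P3 = (wm * c3).sum(axis=1)
        b = wm @ params.b; c = wm @ params.c; d = wm @ params.d
        e = wm @ params.e; f = wm @ params.f; g = wm @ params.g
        vals = _solve(P1, P2, P3, b, c, d, e, f, g)
        vals[~good] = np.nan
        r[i, i + 1:] = vals
        r[i + 1:, i] = vals
        lc = ok.sum(axis=1) < LOW_CONFIDENCE_MIN_LOCI
        lowconf[i, i + 1:] = lc
        lowconf[i + 1:, i] = lc
    return r, lowconf


# ---------------------------------------------------------------------------
# group permutation test and within/among summaries

@dataclass
class GroupRelTest:
    groups: list[str]
    observed: dict[str, float]
    p_high: dict[str, float]
    p_low: dict[str, float]
    n_shuffles: int


def _within_means(r: np.ndarray, labels: np.ndarray,
                  groups: list[str]) -> dict[str, float]:
    out = {}
    for gname in groups:
        idx = np.flatnonzero(labels == gname)
        sub = r[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(len(idx), k=1)]
        out[gname] = float(np.nanmean(vals))
    return out


def group_relatedness_test(r: np.ndarray, labels, n_shuffles: int = 1000,
                           rng: np.random.Generator | None = None,
                           ) -> GroupRelTest:
    """Observed within-group mean r against a label-shuffling null.

    Group sizes are held constant in every shuffle; one-sided p-values are
    (#null >= obs + 1)/(n_shuffles + 1) and the mirror.
    """
    rng = np.random.default_rng() if rng is None else rng
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any((labels == gname).sum() < 2 for gname in groups):
        raise ValueError("every group needs at least two members")
    observed = _within_means(r, labels, groups)
    ge = {gname: 0 for gname in groups}
    le = {gname: 0 for gname in groups}
    for _ in range(n_shuffles):
        perm = rng.permutation(labels)
        null = _within_means(r, perm, groups)
        for gname in groups:
            if null[gname] >= observed[gname]:
                ge[gname] += 1
            if null[gname] <= observed[gname]:
                le[gname] += 1
    p_high = {gname: (ge[gname] + 1) / (n_shuffles + 1) for gname in groups}
    p_low = {gname: (le[gname] + 1) / (n_shuffles + 1) for gname in groups}
    return GroupRelTest(groups, observed, p_high, p_low, n_shuffles)


def within_among_summaries(r: np.ndarray, sample_sites, sample_regimes,
                           ) -> "pd.DataFrame":
    """Site-level r_W (within site) and r_A (other sites, same regime).

    Per-sample means first, then site-level means of those; single-sample
    sites yield NaN r_W.
    """
    import pandas as pd

    sites = np.asarray(sample_sites)
    regimes = np.asarray(sample_regimes)
    n = r.shape[0]
    rw = np.full(n, np.nan)
    ra = np.full(n, np.nan)
    off = ~np.eye(n, dtype=bool)
    for i in range(n):
        same_site = (sites == sites[i]) & off[i]
        if same_site.any():
            rw[i] = np.nanmean(r[i, same_site])
        among = (sites != sites[i]) & (regimes == regimes[i])
        if among.any():
            ra[i] = np.nanmean(r[i, among])
    df = pd.DataFrame({"site_id": sites, "regime": regimes,
                       "r_w": rw, "r_a": ra})
    return (df.groupby(["site_id", "regime"], as_index=False)
              .mean(numeric_only=True))
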