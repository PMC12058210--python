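"""Genotypic diversity: richness, effective numbers, Pareto beta, rarefaction,
and clone spatial extents.

The central quantities follow standard clonal-plant usage: genotypic richness
R = (G - 1)/(N - 1) for G lineages among N shoots, effective numbers of
lineages from Shannon (exp H) and Simpson (1 / sum p_i^2) indices (Hill
numbers of order 1 and 2), and the Pareto beta describing the unevenness of
the clone-size spectrum.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np


@dataclass
class EffectiveNumbers:
    shannon_h: float
    simpson_lambda: float
    eff_shannon: float
    eff_simpson: float


@dataclass
class GenotypicStats:
    scope: str
    n: int
    g: int
    richness: float | None
    eff: EffectiveNumbers
    r_shannon: float | None
    r_simpson: float | None
    pareto_beta: float | None
    pareto_defined: bool


@dataclass
class CloneExtent:
    mll_id: str
    n_samples: int
    n_sites: int
    max_extent: float


def genotypic_richness(g: float, n: int) -> float:
    """R = (G - 1)/(N - 1); G may be an effective (non-integer) number."""
    if n < 2:
        raise ValueError("richness undefined for fewer than two samples")
    if g > n:
        raise ValueError("more lineages than samples")
    return (g - 1.0) / (n - 1.0)


def effective_numbers(counts, unbiased_simpson: bool = False) -> EffectiveNumbers:
    """Shannon/Simpson indices and their effective-number transforms.

    ``unbiased_simpson`` switches lambda to the small-sample variant
    sum n_i (n_i - 1) / (N (N - 1)); the default is the plug-in sum p_i^2 so
    the Hill ordering G >= exp(H) >= 1/lambda holds exactly.
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0:
        raise ValueError("empty abundance vector")
    if (counts <= 0).any():
        raise ValueError("abundances must be positive")
    n = counts.sum()
    p = counts / n
    h = float(-(p * np.log(p)).sum())
    if unbiased_simpson:
        if n < 2:
            raise ValueError("unbiased Simpson needs N >= 2")
        lam = float((counts * (counts - 1)).sum() / (n * (n - 1)))
    else:
        lam = float((p ** 2).sum())
    eff_simpson = np.inf if lam == 0 else 1.0 / lam
    return EffectiveNumbers(h, lam, float(np.exp(h)), float(eff_simpson))


def pareto_beta(counts) -> tuple[float | None, bool]:
    """Pareto beta of the clone-size spectrum.

    OLS slope of log N_{>=x} against log x over the observed clone sizes x
    (reverse cumulative distribution); beta = -slope.  Undefined (None,
    False) when there is a single size class -- all samples unique or all one
    clone.
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.size == 0:
        raise ValueError("empty abundance vector")
    sizes = np.unique(counts)
    if sizes.size < 2:
        return None, False
    n_geq = np.array([(counts >= x).sum() for x in sizes], dtype=float)
    slope = np.polyfit(np.log(sizes), np.log(n_geq), 1)[0]
    return float(-slope), True


def genotypic_stats(mll_labels, scope: str = "",
                    unbiased_simpson: bool = False) -> GenotypicStats:
    """All genotypic diversity measures for one scope (site/regime/river)."""
    labels = list(mll_labels)
    n = len(labels)
    counts = np.array(sorted(Counter(labels).values()), dtype=float)
    g = counts.size
    eff = effective_numbers(counts, unbiased_simpson)
    if n >= 2:
        r = genotypic_richness(g, n)
        r_sh = genotypic_richness(min(eff.eff_shannon, n), n)
        r_si = genotypic_richness(min(eff.eff_simpson, n), n)
    else:
        r = r_sh = r_si = None
    beta, defined = pareto_beta(counts)
    return GenotypicStats(scope, n, int(g), r, eff, r_sh, r_si, beta, defined)


def rarefy_genotypic(mll_labels, n_raref: int, n_reps: int = 1000,
                     rng: np.random.Generator | None = None,
                     exhaustive: bool = False) -> dict[str, float]:
    """Mean genotypic statistics over subsamples of size ``n_raref``.

    Subsampling is without replacement; with ``exhaustive`` every
    C(N, n_raref) subset is enumerated (small N only).  Statistics undefined
    on a subsample (e.g. Pareto beta with one size class) are averaged over
    the subsamples where they are defined.
    """
    labels = np.asarray(list(mll_labels))
    n = labels.size
    if n_raref > n:
        raise ValueError("cannot rarefy beyond the sample size")
    if n_raref < 2:
        raise ValueError("rarefied richness needs n_raref >= 2")
    if exhaustive:
        subsets = itertools.combinations(range(n), n_raref)
        draws = (labels[list(c)] for c in subsets)
    else:
        rng = np.random.default_rng() if rng is None else rng
        draws = (labels[rng.choice(n, size=n_raref, replace=False)]
                 for _ in range(n_reps))
    acc: dict[str, list[float]] = {k: [] for k in
                                   ("g", "richness", "eff_shannon",
                                    "eff_simpson", "r_shannon", "r_simpson",
                                    "pareto_beta")}
    for lab in draws:
        st = genotypic_stats(lab)
        acc["g"].append(st.g)
        acc["richness"].append(st.richness)
        acc["eff_shannon"].append(st.eff.eff_shannon)
        acc["eff_simpson"].append(st.eff.eff_simpson)
        acc["r_shannon"].append(st.r_shannon)
        acc["r_simpson"].append(st.r_simpson)
        if st.pareto_defined:
            acc["pareto_beta"].append(st.pareto_beta)
    return {k: (float(np.mean(v)) if v else float("nan"))
            for k, v in acc.items()}


def clone_extents(mll_of_sample: dict[str, str], site_of_sample: dict[str, str],
                  sample_ids: list[str], distance_matrix: np.ndarray,
                  ) -> list[CloneExtent]:
    """Per-MLL occurrence count, site count and maximum pairwise distance.

    ``distance_matrix`` is indexed by ``sample_ids`` order (typically the
    combined water/Euclidean sample distances); singletons get extent 0.
    """
    idx = {s: i for i, s in enumerate(sample_ids)}
    members: dict[str, list[str]] = {}
    for s, m in mll_of_sample.items():
        members.setdefault(m, []).append(s)
    out = []
    for mll, mem in sorted(members.items()):
        sites = {site_of_sample[s] for s in mem}
        if len(mem) == 1:
            ext = 0.0
        else:
            ii = [idx[s] for s in mem]
            ext = float(np.max(distance_matrix[np.ix_(ii, ii)]))
        out.append(CloneExtent(mll, len(mem), len(sites), ext))
    return out


def multisample_summary(mll_of_sample: dict[str, str]) -> dict[str, float]:
    """Share of MLLs sampled more than once and of shoots in such MLLs."""
    counts = Counter(mll_of_sample.values())
    n_mll = len(counts)
    n_samples = sum(counts.values())
    multi = {m: c for m, c in counts.items() if c > 1}
    shoots_multi = sum(multi.values())
    return {
        "n_mll": n_mll,
        "n_samples": n_samples,
        "n_multisample_mll": len(multi),
        "pct_mll_multisample": 100.0 * len(multi) / n_mll if n_mll else float("nan"),
        "pct_shoots_in_multisample": (100.0 * shoots_multi / n_samples
                                      if n_samples else float("nan")),
    }
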