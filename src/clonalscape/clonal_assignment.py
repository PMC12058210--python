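"""Clone discrimination: MLGs, MLLs, pgen/psex and genotype accumulation.

Samples are grouped into multilocus genotypes (MLGs) by complete multilocus
matches.  Samples with missing data are merged into an existing MLG only when
their resolved loci match exactly one MLG; matching several leaves them
unassigned-ambiguous (reported and excluded downstream), matching none founds
a new MLG.  MLGs differing by a single allele at a single locus are collapsed
into multilocus lineages (MLLs) when the rarer MLG is a singleton, iterated to
a fixed point -- the usual guard against calling a scoring error or somatic
mutation a distinct genet.  psex quantifies the probability that repeated
encounters of an MLL arose from distinct sexual events.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotype_io import MISSING_ALLELE, GenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class ClonalAssignment:
    """Sample -> MLG -> MLL maps plus exclusions and psex bookkeeping."""

    sample_ids: list[str]
    mlg_of_sample: dict[str, str]          # excludes ambiguous/empty samples
    mlg_profiles: dict[str, np.ndarray]    # MLG id -> (L, 2) consensus calls
    mll_of_mlg: dict[str, str]
    ambiguous_samples: list[str] = field(default_factory=list)
    empty_samples: list[str] = field(default_factory=list)
    missing_flagged: list[str] = field(default_factory=list)  # assigned despite gaps
    psex_series: dict[str, np.ndarray] = field(default_factory=dict)
    psex_clonal: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assigned = set(self.mlg_of_sample)
        if assigned - set(self.sample_ids):
            raise ValueError("assignment references unknown samples")
        if set(self.mlg_of_sample.values()) != set(self.mlg_profiles):
            raise ValueError("MLG map and profiles disagree")
        if self.mll_of_mlg and set(self.mll_of_mlg) != set(self.mlg_profiles):
            raise ValueError("MLL map must cover every MLG")

    @property
    def n_assigned(self) -> int:
        return len(self.mlg_of_sample)

    @property
    def mlg_ids(self) -> list[str]:
        return sorted(self.mlg_profiles)

    @property
    def mll_ids(self) -> list[str]:
        return sorted(set(self.mll_of_mlg.values()))

    def mll_of_sample(self) -> dict[str, str]:
        return {s: self.mll_of_mlg[g] for s, g in self.mlg_of_sample.items()}

    def mll_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {m: [] for m in self.mll_ids}
        for s, g in self.mlg_of_sample.items():
            out[self.mll_of_mlg[g]].append(s)
        return out

    def mlg_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {g: [] for g in self.mlg_profiles}
        for s, g in self.mlg_of_sample.items():
            out[g].append(s)
        return out


def _profile_key(calls_row: np.ndarray) -> tuple:
    return tuple(map(tuple, calls_row))


def assign_mlgs(gt: GenotypeTable) -> ClonalAssignment:
    """Group samples into MLGs by complete multilocus matches.

    Complete-data samples are grouped first; missing-data samples are then
    merged, in order of increasing missingness, into the unique MLG that
    agrees at every mutually resolved locus.  Samples compatible with several
    MLGs stay unassigned-ambiguous; samples missing at every locus are
    excluded with a warning.
    """
    miss = gt.missing_mask
    order = sorted(range(gt.n_samples), key=lambda i: (int(miss[i].sum()), i))
    mlg_of_sample: dict[str, str] = {}
    profiles: dict[str, np.ndarray] = {}
    ambiguous: list[str] = []
    empty: list[str] = []
    flagged: list[str] = []
    complete_index: dict[tuple, str] = {}  # fast path for complete profiles
    counter = itertools.count(1)

    for i in order:
        sid = gt.sample_ids[i]
        row = gt.calls[i]
        n_miss = int(miss[i].sum())
        if n_miss == gt.n_loci:
            logger.warning("sample %s missing at all loci; excluded", sid)
            empty.append(sid)
            continue
        if n_miss == 0:
            key = _profile_key(row)
            mlg = complete_index.get(key)
            if mlg is None:
                mlg = f"MLG{next(counter):04d}"
                complete_index[key] = mlg
                profiles[mlg] = row.copy()
            mlg_of_sample[sid] = mlg
            continue
        # missing-data sample: compare at mutually resolved loci
        resolved = ~miss[i]
        matches = []
        for mlg, prof in profiles.items():
            both = resolved & (prof[:, 0] != MISSING_ALLELE)
            if both.any() and (prof[both] == row[both]).all():
                matches.append(mlg)
        if len(matches) == 1:
            mlg_of_sample[sid] = matches[0]
            flagged.append(sid)
        elif len(matches) > 1:
            logger.info("sample %s ambiguous among MLGs %s; excluded",
                        sid, matches)
            ambiguous.append(sid)
        else:
            mlg = f"MLG{next(counter):04d}"
            profiles[mlg] = row.copy()
            mlg_of_sample[sid] = mlg
            flagged.append(sid)

    mll = {g: g.replace("MLG", "MLL") for g in profiles}
    return ClonalAssignment(list(gt.sample_ids), mlg_of_sample, profiles, mll,
                            ambiguous, empty, flagged)


def mlg_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Allele-difference count between two (L, 2) profiles.

    Per locus the diploid multiset difference is 0, 1 or 2; loci missing in
    either profile are skipped.  With no comparable locus the distance is
    undefined.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    both = (a[:, 0] != MISSING_ALLELE) & (b[:, 0] != MISSING_ALLELE)
    if not both.any():
        raise ValueError("no comparable loci between profiles")
    d = 0
    for x, y in zip(a[both], b[both]):
        # profiles are order-normalised, so multiset overlap is direct
        sx, sy = list(x), list(y)
        shared = 0
        for allele in sx:
            if allele in sy:
                sy.remove(allele)
                shared += 1
        d += 2 - shared
    return d


def pairwise_mlg_distances(assignment: ClonalAssignment) -> dict[tuple[str, str], int]:
    ids = assignment.mlg_ids
    out = {}
    for g1, g2 in itertools.combinations(ids, 2):
        try:
            out[(g1, g2)] = mlg_distance(
                assignment.mlg_profiles[g1], assignment.mlg_profiles[g2])
        except ValueError:
            continue
    return out


def collapse_to_mlls(assignment: ClonalAssignment,
                     distances: dict[tuple[str, str], int] | None = None,
                     threshold: int = 1) -> ClonalAssignment:
    """Collapse MLGs into MLLs.

    An MLG pair at distance <= ``threshold`` (default one allele at one locus)
    is merged iff the less common MLG has exactly one member sample.  Merging
    is the transitive closure of eligible pairs, so the result is a fixed
    point independent of processing order.  The MLL representative is the
    most abundant member MLG (ties broken lexicographically).
    """
    if distances is None:
        distances = pairwise_mlg_distances(assignment)
    members = assignment.mlg_members()
    counts = {g: len(m) for g, m in members.items()}

    parent = {g: g for g in assignment.mlg_profiles}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for (g1, g2), d in distances.items():
        if d > threshold:
            continue
        rarer = min((counts[g1], g1), (counts[g2], g2))
        if rarer[0] == 1:
            r1, r2 = find(g1), find(g2)
            if r1 != r2:
                parent[max(r1, r2)] = min(r1, r2)

    clusters: dict[str, list[str]] = {}
    for g in assignment.mlg_profiles:
        clusters.setdefault(find(g), []).append(g)
    mll_of_mlg: dict[str, str] = {}
    for group in clusters.values():
        rep = max(group, key=lambda g: (counts[g], [-ord(c) for c in g]))
        name = rep.replace("MLG", "MLL")
        for g in group:
            mll_of_mlg[g] = name
    return ClonalAssignment(
        assignment.sample_ids, dict(assignment.mlg_of_sample),
        dict(assignment.mlg_profiles), mll_of_mlg,
        list(assignment.ambiguous_samples), list(assignment.empty_samples),
        list(assignment.missing_flagged),
        dict(assignment.psex_series), dict(assignment.psex_clonal))


# ---------------------------------------------------------------------------
# pgen / psex

def allele_frequencies(gt: GenotypeTable, sample_idx=None) -> list[dict[int, float]]:
    """Per-locus allele frequencies from non-missing calls.

    ``sample_idx`` restricts the reference set (e.g. one representative per
    MLL for clone-corrected frequencies).
    """
    if sample_idx is None:
        calls = gt.calls
    else:
        calls = gt.calls[np.asarray(sample_idx)]
    freqs: list[dict[int, float]] = []
    for j in range(gt.n_loci):
        flat = calls[:, j, :].ravel()
        flat = flat[flat != MISSING_ALLELE]
        if flat.size == 0:
            freqs.append({})
            continue
        vals, cnt = np.unique(flat, return_counts=True)
        total = cnt.sum()
        freqs.append({int(v): c / total for v, c in zip(vals, cnt)})
    return freqs


def pgen(profile: np.ndarray, allele_freqs: list[dict[int, float]]) -> float:
    """HWE probability of a multilocus genotype; missing loci contribute 1."""
    profile = np.asarray(profile)
    p = 1.0
    for (a, b), freqs in zip(profile, allele_freqs):
        if a == MISSING_ALLELE:
            continue
        if a not in freqs or b not in freqs:
            raise KeyError(f"allele {a if a not in freqs else b} absent from "
                           "frequency table")
        p *= freqs[a] ** 2 if a == b else 2.0 * freqs[a] * freqs[b]
    return p


def psex(pgen_value: float, n_encounters: int, n_total: int,
         threshold: float = 0.001) -> tuple[np.ndarray, bool]:
    """psex for the 2nd..n-th encounter of an MLL ("multiple" method).

    psex_i = P(X >= i-1) with X ~ Binomial(N-1, pgen): the probability of
    seeing at least i-1 further independent sexual copies of the genotype in
    the remaining N-1 samples.  The MLL is flagged clonal when the final
    value falls below ``threshold``.
    """
    if not (0.0 < pgen_value <= 1.0):
        raise ValueError("pgen must be in (0, 1]")
    if n_encounters < 2:
        raise ValueError("psex is defined for 2 or more encounters")
    i = np.arange(2, n_encounters + 1)
    series = stats.binom.sf(i - 2, n_total - 1, pgen_value)
    return series, bool(series[-1] < threshold)


def attach_psex(assignment: ClonalAssignment, gt: GenotypeTable,
                threshold: float = 0.001) -> ClonalAssignment:
    """Compute psex for every multi-sample MLL.

    Allele frequencies are clone-corrected: one representative sample per MLL
    (the member with fewest missing loci, then lexicographic id), pooled over
    the whole dataset.
    """
    members = assignment.mll_members()
    idx_of = {s: i for i, s in enumerate(gt.sample_ids)}
    miss = gt.missing_mask.sum(axis=1)
    reps = [min(m, key=lambda s: (miss[idx_of[s]], s)) for m in members.values()]
    freqs = allele_frequencies(gt, [idx_of[s] for s in reps])
    n_total = assignment.n_assigned
    series: dict[str, np.ndarray] = {}
    clonal: dict[str, bool] = {}
    rep_mlg = {m: min((g for g, l in assignment.mll_of_mlg.items() if l == m))
               for m in members}
    for mll, mem in members.items():
        if len(mem) < 2:
            continue
        prof = assignment.mlg_profiles[rep_mlg[mll]]
        s, flag = psex(pgen(prof, freqs), len(mem), n_total, threshold)
        series[mll] = s
        clonal[mll] = flag
    assignment.psex_series = series
    assignment.psex_clonal = clonal
    return assignment


# ---------------------------------------------------------------------------
# genotype accumulation

@dataclass
class AccumulationCurve:
    """Distinct-genotype counts over random locus subsets of size 1..L."""

    m: np.ndarray          # loci counts 1..L
    mean: np.ndarray
    q025: np.ndarray
    q975: np.ndarray


def _count_distinct(gt: GenotypeTable, loci: tuple[int, ...]) -> int:
    keys = {
        tuple(map(tuple, gt.calls[i][list(loci)])) for i in range(gt.n_samples)}
    return len(keys)


def genotype_accumulation(gt: GenotypeTable, n_reps: int = 100,
                          rng: np.random.Generator | None = None,
                          exhaustive: bool = False) -> AccumulationCurve:
    """Power of locus subsets to discriminate genotypes.

    For each subset size m the number of distinct complete-match genotypes is
    averaged over ``n_reps`` random m-subsets (or all subsets when
    ``exhaustive``); m = L is computed exactly.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if gt.n_loci < 2:
        raise ValueError("need at least two loci")
    rng = np.random.default_rng() if rng is None else rng
    L = gt.n_loci
    means, lo, hi = [], [], []
    for m in range(1, L + 1):
        if m == L:
            vals = np.array([_count_distinct(gt, tuple(range(L)))], float)
        elif exhaustive:
            vals = np.array([_count_distinct(gt, c)
                             for c in itertools.combinations(range(L), m)], float)
        else:
            vals = np.array([
                _count_distinct(gt, tuple(rng.choice(L, size=m, replace=False)))
                for _ in range(n_reps)], float)
        means.append(vals.mean())
        lo.append(np.quantile(vals, 0.025))
        hi.append(np.quantile(vals, 0.975))
    return AccumulationCurve(np.arange(1, L + 1), np.array(means),
                             np.array(lo), np.array(hi))
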