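"""Synthetic riverscape genotype data with the structure the analyses assume.

The generator emulates a partially clonal dioecious aquatic plant sampled at
sites strung along a single river channel that spans a free-flowing
(nontidal) upper reach and a tidal lower reach:

* a raster river corridor (water = 1) meandering through land, with an
  optional impassable barrier band between the regimes (fall-line analog);
* per-locus ancestral allele frequencies, with site frequencies drifting
  along the river by a logistic-normal random walk whose variance grows with
  river distance -- a simple, reproducible isolation-by-distance engine;
* within each site, new genets drawn by Hardy-Weinberg sampling from the
  site frequencies; each additional shoot is, with regime-dependent
  probability c, a ramet of an existing local genet chosen
  rich-get-richer-style (preferential copying produces uneven,
  Pareto-like clone-size spectra);
* a configurable number of widespread clones seeded across many nontidal
  sites, mimicking river-spanning lineages;
* missing genotype calls injected at regime-specific rates.

The true genet label of every sample is returned so clone discrimination can
be scored against truth.  A separate pedigree-pair generator provides
labelled clone / parent-offspring / full-sib / half-sib / unrelated dyads
for validating relatedness estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable, SiteMeta, WaterGrid


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic riverscape.

    Defaults follow the emulated study design: 24 nontidal + 12 tidal sites
    along ~370 km of river, ~26 shoots per site, 10 microsatellite loci with
    5-13 alleles, strong clonality in the nontidal regime (c = 0.75) and
    almost none in the tidal (c = 0.05), two widespread nontidal clones, and
    regime-specific missing-call rates of 0.1% / 1.4%.
    """

    seed: int = 0
    n_sites_nontidal: int = 24
    n_sites_tidal: int = 12
    river_km_min: float = 89.0
    river_km_max: float = 462.0
    tidal_boundary_km: float = 188.0
    n_loci: int = 10
    alleles_min: int = 5
    alleles_max: int = 13
    clonal_fraction: dict = field(
        default_factory=lambda: {"nontidal": 0.75, "tidal": 0.05})
    local_mating: dict = field(
        default_factory=lambda: {"nontidal": 0.0, "tidal": 0.0})
    clonal_het_advantage: float = 6.0
    n_widespread_clones: int = 2
    widespread_span_sites: int = 15
    samples_per_site: int = 26
    missing_rate: dict = field(
        default_factory=lambda: {"nontidal": 0.001, "tidal": 0.014})
    drift_sigma_per_sqrt_km: float = 0.3
    ancestral_dirichlet_alpha: float = 0.25
    fallline_drift_jump: float = 3.0
    cell_size_m: float = 500.0
    corridor_halfwidth_cells: int = 2
    land_margin_cells: int = 4
    barrier: bool = False
    year: dict = field(
        default_factory=lambda: {"nontidal": 2011, "tidal": 2013})


def tiny_config(seed: int = 0) -> SimulationConfig:
    """4-site preset for fast smoke tests."""
    return SimulationConfig(
        seed=seed, n_sites_nontidal=2, n_sites_tidal=2,
        river_km_min=10.0, river_km_max=40.0, tidal_boundary_km=25.0,
        n_widespread_clones=0, samples_per_site=8, cell_size_m=500.0)


def paper_like_config(seed: int = 0) -> SimulationConfig:
    """The full emulated study design (36 sites, ~940 shoots)."""
    return SimulationConfig(seed=seed)


# ---------------------------------------------------------------------------
# riverscape geometry

def simulate_riverscape(cfg: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[SiteMeta, WaterGrid]:
    """Meandering water corridor plus in-channel site positions.

    The channel runs west-east; river km decreases downstream (eastward) so
    the highest river km is the most upstream site.  With ``cfg.barrier`` a
    one-column land band severs the corridor at the tidal boundary.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.corridor_halfwidth_cells < 0:
        raise ValueError("corridor width must be at least one cell")
    total_km = cfg.river_km_max - cfg.river_km_min
    ncols = int(np.ceil(total_km * 1000.0 / cfg.cell_size_m)) + 1
    amp_cells = 6
    nrows = 2 * (amp_cells + cfg.corridor_halfwidth_cells
                 + cfg.land_margin_cells) + 1
    cond = np.zeros((nrows, ncols), dtype=np.uint8)
    mid = nrows // 2
    xs = np.arange(ncols)
    centre_rows = (mid + amp_cells * np.sin(2 * np.pi * xs / (ncols / 3.0))
                   ).round().astype(int)
    for cx, cr in zip(xs, centre_rows):
        lo = cr - cfg.corridor_halfwidth_cells
        hi = cr + cfg.corridor_halfwidth_cells + 1
        cond[lo:hi, cx] = 1
    grid = WaterGrid(0.0, 0.0, cfg.cell_size_m, cond)

    n_sites = cfg.n_sites_nontidal + cfg.n_sites_tidal
    km_tidal = np.linspace(cfg.river_km_min, cfg.tidal_boundary_km * 0.95,
                           cfg.n_sites_tidal)
    km_nontidal = np.linspace(cfg.tidal_boundary_km * 1.25, cfg.river_km_max,
                              cfg.n_sites_nontidal)
    river_km = np.concatenate([km_nontidal[::-1], km_tidal[::-1]])
    regimes = (["nontidal"] * cfg.n_sites_nontidal
               + ["tidal"] * cfg.n_sites_tidal)

    if cfg.barrier:
        bcol = int((cfg.river_km_max - cfg.tidal_boundary_km)
                   * 1000.0 / cfg.cell_size_m)
        bcol = min(max(bcol, 1), ncols - 2)
        cond[:, bcol] = 0
        grid = WaterGrid(0.0, 0.0, cfg.cell_size_m, cond)

    rows = []
    for i, (km, regime) in enumerate(zip(river_km, regimes)):
        col = int((cfg.river_km_max - km) * 1000.0 / cfg.cell_size_m)
        col = min(col, ncols - 1)
        row = centre_rows[col]
        x, y = grid.center_of(row, col)
        rows.append({"site_id": f"S{i+1:02d}", "x": x, "y": y,
                     "river_km": float(km), "regime": regime,
                     "year": cfg.year[regime]})
    meta = SiteMeta(pd.DataFrame(rows))
    # all sites must sit on water cells
    for r in rows:
        rr, cc = grid.cell_of(r["x"], r["y"])
        assert grid.conductance[rr, cc] == 1
    return meta, grid


# ---------------------------------------------------------------------------
# genotypes

def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def simulate_genotypes(cfg: SimulationConfig, sites: SiteMeta,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[GenotypeTable, dict[str, str]]:
    """Genotype table plus the true genet id of every sample."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    for regime, c in cfg.clonal_fraction.items():
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"clonal fraction for {regime} outside [0, 1]")
    L = cfg.n_loci
    n_alleles = rng.integers(cfg.alleles_min, cfg.alleles_max + 1, size=L)
    # alpha < 1 gives the skewed frequency spectra typical of microsatellites
    ancestral = [rng.dirichlet(np.full(k, cfg.ancestral_dirichlet_alpha))
                 for k in n_alleles]
    # allele "sizes": distinct even integers per locus, microsatellite-style
    allele_codes = [100 + 20 * j + 2 * np.arange(k)
                    for j, k in enumerate(n_alleles)]

    # drift walk starts at the river mouth: upstream sites accumulate drift,
    # so allelic diversity is lowest upstream and accumulates downstream
    order = np.argsort(sites.table["river_km"].to_numpy())
    site_rows = sites.table.iloc[order].reset_index(drop=True)
    site_freqs: dict[str, list[np.ndarray]] = {}
    prev = [np.log(np.maximum(f, 1e-12)) for f in ancestral]
    prev_km = float(site_rows["river_km"].iloc[0])
    prev_regime = str(site_rows["regime"].iloc[0])
    for _, row in site_rows.iterrows():
        d_km = abs(prev_km - float(row["river_km"]))
        sigma = cfg.drift_sigma_per_sqrt_km * np.sqrt(max(d_km, 0.0))
        cur = [z + rng.normal(0.0, sigma, size=z.size) for z in prev]
        if str(row["regime"]) != prev_regime:
            # the fall line is an abrupt disjunction, not a smooth gradient:
            # one extra drift jump when the walk crosses regimes
            cur = [z + rng.normal(0.0, cfg.fallline_drift_jump, size=z.size)
                   for z in cur]
        site_freqs[row["site_id"]] = [_softmax(z) for z in cur]
        prev, prev_km = cur, float(row["river_km"])
        prev_regime = str(row["regime"])

    def draw_genet(freqs: list[np.ndarray], het_bias: bool = False,
                   ) -> np.ndarray:
        """HWE genotype; with het_bias the two alleles are drawn without
        replacement, emulating the heterozygosity enrichment of established
        clone-dominant genets (fixed heterozygosity of clonal lineages)."""
        prof = np.empty((L, 2), dtype=np.int64)
        for j in range(L):
            p = freqs[j]
            first = rng.choice(allele_codes[j], p=p)
            if het_bias and (p > 0).sum() >= 2:
                q = p.copy()
                q[allele_codes[j] == first] = 0.0
                q = q / q.sum()
                second = rng.choice(allele_codes[j], p=q)
            else:
                second = rng.choice(allele_codes[j], p=p)
            prof[j] = sorted((first, second))
        return prof

    genet_profiles: dict[str, np.ndarray] = {}
    seen_profiles: set[tuple] = set()
    genet_counter = [0]

    def _register(prof: np.ndarray) -> str:
        genet_counter[0] += 1
        gid = f"G{genet_counter[0]:05d}"
        genet_profiles[gid] = prof
        seen_profiles.add(tuple(prof.ravel()))
        return gid

    def new_genet(freqs, het_bias: bool = False) -> str:
        # distinct genets must be distinguishable at the scored loci (the
        # premise of complete-match clone discrimination): reject duplicates
        for _ in range(1000):
            prof = draw_genet(freqs, het_bias)
            if tuple(prof.ravel()) not in seen_profiles:
                return _register(prof)
        raise RuntimeError("cannot draw a distinct genotype; loci too uniform")

    def mate_genets(p1: np.ndarray, p2: np.ndarray, freqs) -> str:
        """Mendelian cross of two local genets (within-site relatedness)."""
        for _ in range(100):
            pick1 = rng.integers(0, 2, size=L)
            pick2 = rng.integers(0, 2, size=L)
            child = np.sort(np.stack(
                [p1[np.arange(L), pick1], p2[np.arange(L), pick2]], axis=1),
                axis=1)
            if tuple(child.ravel()) not in seen_profiles:
                return _register(child)
        return new_genet(freqs)

    # widespread clones seeded across upstream nontidal sites
    nontidal_ids = list(site_rows.loc[site_rows["regime"] == "nontidal",
                                      "site_id"])
    widespread: list[tuple[str, list[str]]] = []
    for w in range(cfg.n_widespread_clones):
        if not nontidal_ids:
            break
        span = min(cfg.widespread_span_sites, len(nontidal_ids))
        start = int(rng.integers(0, len(nontidal_ids) - span + 1))
        span_sites = nontidal_ids[start:start + span]
        gid = new_genet(site_freqs[span_sites[0]], het_bias=True)
        widespread.append((gid, span_sites))

    sample_ids, calls = [], []
    site_of: dict[str, str] = {}
    genet_of: dict[str, str] = {}
    counter = 0
    for _, row in site_rows.iterrows():
        sid_site = row["site_id"]
        regime = row["regime"]
        c = cfg.clonal_fraction[regime]
        lm = cfg.local_mating.get(regime, 0.0)
        freqs = site_freqs[sid_site]
        # local genet pool with multiplicities; widespread clones enter with
        # a head start so preferential copying makes them dominant
        pool: list[str] = []
        for gid, span_sites in widespread:
            if sid_site in span_sites:
                pool.extend([gid] * 3)
        for _ in range(cfg.samples_per_site):
            counter += 1
            sample = f"V{counter:04d}"
            if pool and rng.random() < c:
                # size-biased copy, tilted toward heterozygous genets: the
                # genotypes that proliferate clonally are het-enriched
                # (heterosis), which is what makes clone-corrected gene
                # diversity drop below the all-shoot value
                cand = list(dict.fromkeys(pool))
                counts = np.array([pool.count(g) for g in cand], float)
                hets = np.array([
                    (genet_profiles[g][:, 0] != genet_profiles[g][:, 1]).mean()
                    for g in cand])
                wgt = counts * np.exp(cfg.clonal_het_advantage * (hets - 0.5))
                gid = cand[int(rng.choice(len(cand), p=wgt / wgt.sum()))]
            elif len(set(pool)) >= 2 and rng.random() < lm:
                # local mating: new genet is the offspring of two resident
                # genets (size-biased parent choice), building the
                # within-site relatedness structure of partially clonal beds
                p1 = pool[int(rng.integers(0, len(pool)))]
                p2 = p1
                while p2 == p1:
                    p2 = pool[int(rng.integers(0, len(pool)))]
                gid = mate_genets(genet_profiles[p1], genet_profiles[p2],
                                  freqs)
            else:
                # the site's first founder carries the het bias: it is the
                # genet preferential copying will usually make dominant
                gid = new_genet(freqs, het_bias=(not pool and c > 0.5))
            pool.append(gid)
            sample_ids.append(sample)
            site_of[sample] = sid_site
            genet_of[sample] = gid
            calls.append(genet_profiles[gid].copy())
    calls = np.stack(calls)

    regime_of = dict(zip(site_rows["site_id"], site_rows["regime"]))
    miss_p = np.array([cfg.missing_rate[regime_of[site_of[s]]]
                       for s in sample_ids])
    miss = rng.random((len(sample_ids), L)) < miss_p[:, None]
    calls[miss] = 0

    gt = GenotypeTable(sample_ids, [site_of[s] for s in sample_ids],
                       [f"loc{j+1:02d}" for j in range(L)], calls)
    return gt, genet_of


# ---------------------------------------------------------------------------
# pedigree pairs for relatedness validation

PEDIGREE_LABELS = ("unrelated", "half-sib", "full-sib", "parent-offspring",
                   "clone")


def simulate_pedigree_pairs(n_pairs: int, relationship: str, n_loci: int = 10,
                            n_alleles: int = 8,
                            freqs: list[np.ndarray] | None = None,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Labelled genotype dyads generated by Mendelian sampling.

    Returns two (n_pairs, L, 2) call arrays.  Allele codes are 1..k per
    locus; frequencies default to equifrequent.
    """
    if relationship not in PEDIGREE_LABELS:
        raise ValueError(f"unknown relationship {relationship!r}")
    rng = np.random.default_rng() if rng is None else rng
    if freqs is None:
        freqs = [np.full(n_alleles, 1.0 / n_alleles)] * n_loci
    L = len(freqs)

    def hwe(n: int, j: int) -> np.ndarray:
        k = freqs[j].size
        return rng.choice(np.arange(1, k + 1), size=(n, 2), p=freqs[j])

    def child(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
        g1 = p1[np.arange(p1.shape[0]), rng.integers(0, 2, p1.shape[0])]
        g2 = p2[np.arange(p2.shape[0]), rng.integers(0, 2, p2.shape[0])]
        return np.stack([g1, g2], axis=1)

    a = np.empty((n_pairs, L, 2), dtype=np.int64)
    b = np.empty((n_pairs, L, 2), dtype=np.int64)
    for j in range(L):
        pa, pb = hwe(n_pairs, j), hwe(n_pairs, j)
        if relationship == "unrelated":
            x, y = pa, pb
        elif relationship == "clone":
            x = pa
            y = pa.copy()
        elif relationship == "parent-offspring":
            x = pa
            y = child(pa, pb)
        elif relationship == "full-sib":
            x = child(pa, pb)
            y = child(pa, pb)
        else:  # half-sib: shared mother pa, fathers pb / pc
            pc = hwe(n_pairs, j)
            x = child(pa, pb)
            y = child(pa, pc)
        a[:, j, :] = np.sort(x, axis=1)
        b[:, j, :] = np.sort(y, axis=1)
    return a, b
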