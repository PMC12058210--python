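"""End-to-end orchestration: distances -> clones -> diversity -> structure.

``run_full_analysis`` sequences every stage on validated inputs and returns
a :class:`StatsReport`; ``write_reports`` serialises it to deterministic CSV
tables plus a JSON run summary carrying the seed and all thresholds.  Each
stage is pure with respect to upstream artifacts and every random stage
consumes a child of the single run seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import (GenotypeTable, SiteMeta, WaterGrid,
                          write_matrix_csv, write_run_summary)
from . import clonal_assignment as ca
from . import genotypic_diversity as gd
from . import locus_diversity as ld
from . import differentiation as diff
from . import geodistance as geo
from . import structure_stats as ss
from . import regime_tests as rt
from . import relatedness as rel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All analysis thresholds, with the emulated study's defaults."""

    seed: int = 0
    psex_threshold: float = 0.001
    mll_collapse_distance: int = 1
    n_perm_mantel: int = 999
    n_shuffles_grouprel: int = 1000
    n_boot: int = 1000
    n_perm_regime: int = 10_000
    rarefaction_n: int = 5
    rarefaction_reps: int = 1000
    richness_gene_copies: int = 15
    compute_sample_relatedness: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StatsReport:
    """All tables produced by one run."""

    assignment: ca.ClonalAssignment
    mll_registry: pd.DataFrame
    site_stats: pd.DataFrame           # per-site genotypic + locus diversity
    scope_stats: pd.DataFrame          # river / per-regime summaries
    clone_extent_table: pd.DataFrame
    relatedness_sites: pd.DataFrame
    global_differentiation: dict
    pairwise_fst: pd.DataFrame
    pairwise_gst: pd.DataFrame
    pairwise_d: pd.DataFrame
    mantel: list[ss.MantelResult]
    ca_coords: pd.DataFrame
    ca_inertia: np.ndarray
    spearman: pd.DataFrame
    regime_tests: pd.DataFrame
    site_distances: pd.DataFrame
    provenance: dict


def _site_distance_matrices(sites: SiteMeta, grid: WaterGrid | None,
                            gt: GenotypeTable):
    """Euclidean / cost / combined distances between site centroids.

    Centroids are sample-coordinate means when sample coordinates exist; here
    sites carry one coordinate each, used directly (snapped to water for the
    cost computation).  Without a raster the combined matrix equals the
    Euclidean one, with a warning.
    """
    pts = sites.coords()
    eu = geo.euclidean_distance(pts)
    if grid is None:
        logger.warning("no water raster supplied; combined = Euclidean")
        return eu, None, eu
    cost = geo.cost_distance(grid, pts)
    return eu, cost, geo.combined_distance(eu, cost)


def run_full_analysis(gt: GenotypeTable, sites: SiteMeta,
                      grid: WaterGrid | None = None,
                      config: RunConfig | None = None) -> StatsReport:
    config = RunConfig() if config is None else config
    sites.validate_against(gt)
    root = np.random.default_rng(config.seed)
    child = {name: np.random.default_rng(s) for name, s in zip(
        ("rarefy", "grouprel", "boot", "mantel", "regime"),
        root.integers(0, 2 ** 31 - 1, size=5))}

    # --- distances ---------------------------------------------------------
    eu, cost, combined = _site_distance_matrices(sites, grid, gt)
    site_ids = sites.site_ids
    dist_df = pd.DataFrame(combined, index=site_ids, columns=site_ids)

    # --- clone discrimination ---------------------------------------------
    assignment = ca.assign_mlgs(gt)
    assignment = ca.collapse_to_mlls(
        assignment, threshold=config.mll_collapse_distance)
    assignment = ca.attach_psex(assignment, gt,
                                threshold=config.psex_threshold)
    mll_of_sample = assignment.mll_of_sample()
    analysed = gt.subset([i for i, s in enumerate(gt.sample_ids)
                          if s in mll_of_sample])
    labels = np.array([mll_of_sample[s] for s in analysed.sample_ids])
    regime_of = sites.regime_of()
    site_of_sample = dict(zip(analysed.sample_ids, analysed.site_ids))
    sample_regime = np.array([regime_of[s] for s in analysed.site_ids])

    # clone extents on the site-level combined matrix (samples carry no
    # coordinates of their own here; extent = max distance among member sites)
    sdx = {s: i for i, s in enumerate(site_ids)}
    site_dist_of_samples = combined[
        np.ix_([sdx[s] for s in analysed.site_ids],
               [sdx[s] for s in analysed.site_ids])]
    extents = gd.clone_extents(mll_of_sample, site_of_sample,
                               list(analysed.sample_ids),
                               site_dist_of_samples)
    extent_df = pd.DataFrame([vars(e) for e in extents])

    registry_rows = []
    members = assignment.mll_members()
    for mll in assignment.mll_ids:
        mem = members[mll]
        psx = assignment.psex_series.get(mll)
        registry_rows.append({
            "mll_id": mll,
            "mlg_ids": ";".join(sorted(g for g, m in
                                       assignment.mll_of_mlg.items()
                                       if m == mll)),
            "n_samples": len(mem),
            "sites": ";".join(sorted({site_of_sample[s] for s in mem
                                      if s in site_of_sample})),
            "max_extent_m": float(extent_df.loc[
                extent_df["mll_id"] == mll, "max_extent"].iloc[0])
            if len(extent_df) else 0.0,
            "psex_final": float(psx[-1]) if psx is not None else np.nan,
            "clonal": assignment.psex_clonal.get(mll, False),
        })
    registry = pd.DataFrame(registry_rows)

    # --- genotypic + locus diversity per site ------------------------------
    by_site = analysed.by_site()
    cc_gt = ld.clone_correct(analysed, mll_of_sample)
    cc_by_site = cc_gt.by_site()
    site_rows = []
    for site in site_ids:
        idx = by_site.get(site)
        if idx is None or idx.size == 0:
            continue
        lab = labels[idx]
        gstats = gd.genotypic_stats(lab, scope=site)
        p_poly, a_mean = ld.allele_stats(analysed, idx)
        het = ld.heterozygosity_stats(analysed, idx)
        a_r = ld.rarefied_richness(analysed, idx,
                                   g=config.richness_gene_copies)
        row = {
            "site_id": site, "regime": regime_of[site],
            "river_km": sites.river_km_of()[site],
            "n": gstats.n, "g_mll": gstats.g,
            "richness": gstats.richness,
            "eff_shannon": gstats.eff.eff_shannon,
            "eff_simpson": gstats.eff.eff_simpson,
            "r_shannon": gstats.r_shannon,
            "r_simpson": gstats.r_simpson,
            "pareto_beta": gstats.pareto_beta if gstats.pareto_defined
            else np.nan,
            "p_poly": p_poly, "a_mean": a_mean, "a_rarefied": a_r,
            "ho": het.mean_ho, "hs": het.mean_hs, "fis": het.mean_fis,
            "fis_variance": het.fis_variance,
        }
        if idx.size >= config.rarefaction_n >= 2:
            rar = gd.rarefy_genotypic(lab, config.rarefaction_n,
                                      n_reps=config.rarefaction_reps,
                                      rng=child["rarefy"])
            row["richness_rarefied"] = rar["richness"]
        else:
            row["richness_rarefied"] = np.nan
        cc_idx = cc_by_site.get(site)
        if cc_idx is not None and cc_idx.size >= 2:
            cc_het = ld.heterozygosity_stats(cc_gt, cc_idx)
            row.update({"ho_cc": cc_het.mean_ho, "hs_cc": cc_het.mean_hs,
                        "fis_cc": cc_het.mean_fis})
            row.update({"delta_ho": row["ho"] - cc_het.mean_ho,
                        "delta_hs": row["hs"] - cc_het.mean_hs,
                        "delta_fis": row["fis"] - cc_het.mean_fis})
        site_rows.append(row)
    site_stats = pd.DataFrame(site_rows)

    # --- scope (river / regime) summaries ----------------------------------
    scope_rows = []
    scopes = [("river", np.arange(analysed.n_samples))]
    for regime in ("nontidal", "tidal"):
        scopes.append((regime, np.flatnonzero(sample_regime == regime)))
    for scope, idx in scopes:
        if idx.size < 2:
            continue
        gstats = gd.genotypic_stats(labels[idx], scope=scope)
        het = ld.heterozygosity_stats(analysed, idx)
        ci = ld.fis_bootstrap_ci(het, n_boot=config.n_boot, rng=child["boot"])
        p_poly, a_mean = ld.allele_stats(analysed, idx)
        scope_rows.append({
            "scope": scope, "n": gstats.n, "g_mll": gstats.g,
            "richness": gstats.richness,
            "eff_shannon": gstats.eff.eff_shannon,
            "eff_simpson": gstats.eff.eff_simpson,
            "r_shannon": gstats.r_shannon, "r_simpson": gstats.r_simpson,
            "pareto_beta": gstats.pareto_beta if gstats.pareto_defined
            else np.nan,
            "p_poly": p_poly, "a_mean": a_mean,
            "ho": het.mean_ho, "hs": het.mean_hs, "fis": het.mean_fis,
            "fis_ci_low": ci[0], "fis_ci_high": ci[1],
        })
    scope_stats = pd.DataFrame(scope_rows)

    # --- relatedness --------------------------------------------------------
    if config.compute_sample_relatedness:
        rmat, _ = rel.wang_r_matrix(analysed)
        rel_sites = rel.within_among_summaries(
            rmat, analysed.site_ids, sample_regime)
        cc_regime = np.array([regime_of[s] for s in cc_gt.site_ids])
        cc_rmat, _ = rel.wang_r_matrix(cc_gt)
        rel_cc = rel.within_among_summaries(cc_rmat, cc_gt.site_ids,
                                            cc_regime)
        rel_sites = rel_sites.merge(
            rel_cc, on=["site_id", "regime"], how="left",
            suffixes=("", "_mll"))
        grouprel = rel.group_relatedness_test(
            rmat, sample_regime, n_shuffles=config.n_shuffles_grouprel,
            rng=child["grouprel"])
    else:
        rel_sites = pd.DataFrame(columns=["site_id", "regime", "r_w", "r_a"])
        grouprel = None

    # --- differentiation ----------------------------------------------------
    multi_site = [s for s in site_ids
                  if s in by_site and by_site[s].size >= 2]
    keep = np.isin(analysed.site_ids, multi_site)
    diff_gt = analysed.subset(keep)
    global_diff = diff.global_differentiation(diff_gt, diff_gt.site_ids)
    ci_fst = diff.differentiation_bootstrap(
        diff_gt, diff_gt.site_ids, "fst", "loci", config.n_boot,
        child["boot"])
    global_diff["fst_ci"] = ci_fst
    pw = diff.pairwise_matrices(diff_gt, diff_gt.site_ids)

    # mean pairwise differentiation per site (within its regime), fed to the
    # regime battery
    pwf = pw["fst"]
    mean_pairwise = {}
    for site in pwf.index:
        same = [s for s in pwf.index
                if s != site and regime_of[s] == regime_of[site]]
        mean_pairwise[site] = float(pwf.loc[site, same].mean()) if same else np.nan
    site_stats["mean_pairwise_fst"] = site_stats["site_id"].map(mean_pairwise)

    # --- IBD / ordination ---------------------------------------------------
    chord = ss.edwards_chord_matrix(analysed)
    mantel_results = []
    chord_sites = [s for s in site_ids if s in chord.index]
    for scope in ("all", "nontidal", "tidal"):
        if scope == "all":
            sel = chord_sites
        else:
            sel = [s for s in chord_sites if regime_of[s] == scope]
        if len(sel) < 4:
            continue
        gsub = chord.loc[sel, sel].to_numpy()
        dsub = dist_df.loc[sel, sel].to_numpy()
        if np.isinf(dsub).any():
            logger.warning("Mantel scope %s skipped: disconnected sites", scope)
            continue
        mantel_results.append(
            ss.mantel_test(gsub, dsub, n_perm=config.n_perm_mantel,
                           rng=child["mantel"], scope=scope))

    counts = ss.site_allele_counts(analysed)
    ca_res = ss.correspondence_analysis(counts)

    # --- Spearman vs river km and the regime battery ------------------------
    battery_cols = [c for c in (
        "richness", "eff_shannon", "eff_simpson", "r_shannon", "r_simpson",
        "pareto_beta", "p_poly", "a_mean", "a_rarefied", "ho", "hs", "fis",
        "fis_variance", "r_w", "r_a", "mean_pairwise_fst")
        if c in site_stats.columns or c in rel_sites.columns]
    merged = site_stats.merge(rel_sites, on=["site_id", "regime"], how="left")
    sp_rows = []
    for col in battery_cols:
        try:
            rho, p = ss.spearman_vs_riverkm(merged[col], merged["river_km"])
        except ValueError:
            rho, p = np.nan, np.nan
        sp_rows.append({"statistic": col, "rho": rho, "p": p})
    spearman = pd.DataFrame(sp_rows)

    usable = [c for c in battery_cols
              if merged.groupby("regime")[c].count().ge(2).all()]
    regime_table = rt.regime_test_battery(
        merged, usable, "regime", n_perm=config.n_perm_regime,
        rng=child["regime"])

    provenance = {
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_samples_input": gt.n_samples,
        "n_samples_analysed": analysed.n_samples,
        "n_mlg": len(assignment.mlg_ids),
        "n_mll": len(assignment.mll_ids),
        "excluded_ambiguous": sorted(assignment.ambiguous_samples),
        "excluded_empty": sorted(assignment.empty_samples),
    }
    if grouprel is not None:
        provenance["grouprel"] = {
            "observed": grouprel.observed, "p_high": grouprel.p_high,
            "p_low": grouprel.p_low, "n_shuffles": grouprel.n_shuffles}
    return StatsReport(assignment, registry, site_stats, scope_stats,
                       extent_df, rel_sites, global_diff,
                       pw["fst"], pw["gst_hedrick"], pw["d_est"],
                       mantel_results, ca_res.row_coords, ca_res.inertia_pct,
                       spearman, regime_table, dist_df, provenance)


def write_reports(report: StatsReport, outdir) -> list[Path]:
    """Serialise a StatsReport to CSV tables + one JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str, **kw):
        path = outdir / name
        df.to_csv(path, index=False, **kw)
        written.append(path)

    save(report.mll_registry, "mll_registry.csv")
    save(report.site_stats, "site_stats.csv")
    save(report.scope_stats, "scope_stats.csv")
    save(report.clone_extent_table, "clone_extents.csv")
    save(report.relatedness_sites, "relatedness_sites.csv")
    save(report.spearman, "spearman_river_km.csv")
    save(report.regime_tests, "regime_tests.csv")
    for name, df in (("pairwise_fst", report.pairwise_fst),
                     ("pairwise_gst", report.pairwise_gst),
                     ("pairwise_dest", report.pairwise_d),
                     ("site_distances", report.site_distances)):
        path = outdir / f"{name}.csv"
        df.to_csv(path, index_label="id")
        written.append(path)
    ca_path = outdir / "ca_coords.csv"
    report.ca_coords.to_csv(ca_path, index_label="site_id")
    written.append(ca_path)

    summary = {
        "provenance": report.provenance,
        "global_differentiation": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in report.global_differentiation.items()},
        "mantel": [{"scope": m.scope, "r": m.r, "p": m.p,
                    "n_permutations": m.n_permutations}
                   for m in report.mantel],
        "ca_inertia_pct": list(report.ca_inertia[:5]),
    }
    spath = outdir / "run_summary.json"
    write_run_summary(summary, spath)
    written.append(spath)
    return written
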