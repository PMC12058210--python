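#!/usr/bin/env python
"""Among-site differentiation (Weir-Cockerham theta, Hedrick G''ST, Jost
D_est with bootstrap CIs), water-constrained isolation by distance (Mantel
tests on Edwards chord vs combined water distance), and correspondence
analysis of the site x allele table.
"""

import argparse
from pathlib import Path

import numpy as np

from clonalscape import differentiation as diff
from clonalscape import genotype_io as gio
from clonalscape import geodistance as geo
from clonalscape import structure_stats as ss
from clonalscape.clonal_assignment import assign_mlgs, collapse_to_mlls

def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    gt = gio.read_genotype_table(args.data / "genotypes.csv")
    sites = gio.read_site_meta(args.data / "sites.csv")
    grid = gio.read_water_grid(args.data / "water.asc")
    assignment = collapse_to_mlls(assign_mlgs(gt))
    analysed = gt.subset([i for i, s in enumerate(gt.sample_ids)
                          if s in assignment.mlg_of_sample])
    regime_of = sites.regime_of()

    for scope, sel in (("all", np.ones(analysed.n_samples, bool)),
                       ("nontidal", np.array([regime_of[s] == "nontidal"
                                              for s in analysed.site_ids])),
                       ("tidal", np.array([regime_of[s] == "tidal"
                                           for s in analysed.site_ids])),
                       ("regime-vs-regime", np.ones(analysed.n_samples, bool))):
        sub = analysed.subset(sel)
        pops = (np.array([regime_of[s] for s in sub.site_ids])
                if scope == "regime-vs-regime" else np.array(sub.site_ids))
        res = diff.global_differentiation(sub, pops)
        lo, hi = diff.differentiation_bootstrap(sub, pops, "fst", "loci",
                                                1000, rng)
        print(f"{scope:17s} F_ST={res['fst']:.3f} [{lo:.3f}, {hi:.3f}]  "
              f"G''ST={res['gst_hedrick']:.3f}  D_est={res['d_est']:.3f}")

    chord = ss.edwards_chord_matrix(analysed)
    eu = geo.euclidean_distance(sites.coords())
    cost = geo.cost_distance(grid, sites.coords())
    combined = geo.combined_distance(eu, cost)
    import pandas as pd
    dist = pd.DataFrame(combined, index=sites.site_ids,
                        columns=sites.site_ids)
    for scope in ("all", "nontidal", "tidal"):
        sel = (list(chord.index) if scope == "all" else
               [s for s in chord.index if regime_of[s] == scope])
        res = ss.mantel_test(chord.loc[sel, sel].to_numpy(),
                             dist.loc[sel, sel].to_numpy(),
                             n_perm=999, rng=rng, scope=scope)
        print(f"Mantel IBD [{scope:8s}] r={res.r:.2f} p={res.p:.3f}")

    counts = ss.site_allele_counts(analysed)
    ca_res = ss.correspondence_analysis(counts)
    ca_res.row_coords.to_csv(args.out / "ca_coords.csv",
                             index_label="site_id")
    print(f"CA: axis1 {ca_res.inertia_pct[0]:.1f}% of inertia, "
          f"axis2 {ca_res.inertia_pct[1]:.1f}%")


if __name__ == "__main__":
    main()
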