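# Methods

This note documents the statistical methods implemented in `clonalscape`,
the design choices made where conventions diverge, what the synthetic
riverscape generator does and does not emulate, and the package's known
limitations.

## Clone discrimination

Shoots are grouped into multilocus genotypes (MLGs) by complete multilocus
matches over order-normalised diploid calls. Samples with missing loci are
handled conservatively: a missing-data shoot is merged into an existing MLG
only when its resolved loci agree with exactly one MLG; if several MLGs are
compatible it is left unassigned-ambiguous and excluded downstream, and if
none is compatible it founds a new MLG. Missing-data samples are processed
in order of increasing missingness so complete profiles anchor the
comparison set. A shoot missing at every locus is excluded with a warning.

MLGs are collapsed into multilocus lineages (MLLs) — the unit treated as a
genet — when a pair differs by one allele copy at one locus (the multiset
distance equals 1) *and* the less common MLG is a singleton; this is the
standard guard against promoting a scoring error or somatic mutation to a
distinct genet. Merging is the transitive closure of eligible pairs
(union–find), so the partition is a fixed point independent of processing
order; the MLL representative is the most abundant member MLG with a
lexicographic tie-break. The distance threshold (1) is configurable.

For every MLL observed n ≥ 2 times, `psex` is the binomial tail
P(X ≥ i−1), X ~ Binomial(N−1, pgen), evaluated at each encounter i = 2..n
("multiple" method); `pgen` is the Hardy–Weinberg product over resolved
loci (p² or 2pq), and an MLL is flagged clonal when the final psex falls
below 0.001 (configurable). Allele frequencies for `pgen` are
clone-corrected — one representative per MLL, pooled river-wide — to avoid
clone-inflated frequencies; no F_IS adjustment is applied (the simplest
published variant; the choice matters little at the thresholds used).

The genotype-accumulation curve resamples m-subsets of loci (m = 1..L−1,
exact at m = L) and counts distinct complete-match genotypes, reporting
mean and 2.5/97.5% quantiles. In this count a missing call is its own
token, matching the raw complete-match behaviour before manual missing-data
resolution; the curve is a power diagnostic, not an assignment.

## Genotypic diversity

Richness R = (G−1)/(N−1) with G the number (or effective number) of MLLs
among N shoots. Effective numbers are exp(Shannon H) and the reciprocal of
Simpson's λ = Σp²; λ is deliberately the plug-in form (not Gini–Simpson
1−λ, which has no reciprocal interpretation as an effective number; an
unbiased-λ option exists but is off by default so the Hill ordering
G ≥ exp H ≥ 1/λ holds exactly). Pareto β is minus the OLS slope of
log N(≥x) on log x over observed clone sizes (reverse cumulative
convention); it is undefined — flagged, not imputed — when there is a
single size class. Rarefaction draws subsamples without replacement
(default 1000 replicates, study default n = 5) and averages each statistic
over the subsamples where it is defined. Clone extents are the maximum
pairwise distance among an MLL's members on the combined water/Euclidean
matrix.

## Relatedness (Wang's moment estimator)

At one locus a dyad falls in one of four observable allele-sharing
categories; their expected frequencies are linear in the IBD-pattern
probabilities k1 and k2 with coefficients that are polynomials in the
allele-frequency power sums a2, a3, a4 (the b..g constants in
`relatedness.py`; the three moment identities were verified analytically
and are re-derived independently in the test suite). The power sums are
bias-corrected for the reference sample size by inverting the multinomial
moment identities. Loci are combined by weighted averages of the observed
category indicators and of the constants with locus weight w = 1/u,
u = 2a2 − a3 (more polymorphic loci weigh more), renormalised over the loci
resolved in both members; the overdetermined 3×2 system is then solved by
least squares and r = k2 + k1/2. This reproduces the moment structure and
informativeness weighting of the published estimator; the solver is plain
least squares, which preserves unbiasedness (pedigree recovery: unrelated
≈ 0, half-sib ≈ 0.25, full-sib/parent–offspring ≈ 0.5, clones ≈ 1.0,
within ±0.03 at 500–1000 dyads in the suite). Reference allele frequencies
default to the full analysed sample set (configurable to clone-corrected);
pairs sharing fewer than 5 resolved loci are flagged low-confidence.
Estimates are not clipped to [−1, 1].

Group tests shuffle labels holding group sizes fixed (default 1000
shuffles) and report both one-sided p-values with the +1 correction.
Site summaries compute per-sample means first (r_W to same-site samples,
r_A to other-site samples in the same regime), then average per site; they
are produced both for all shoots and for one representative per MLL per
site.

## Locus diversity

P is the fraction of loci with ≥ 2 observed alleles and A the mean observed
allele count; loci with zero calls in a scope are excluded from the
denominators. Allelic richness is rarefied to g gene copies by the exact
hypergeometric expectation Σ_a [1 − C(N−N_a, g)/C(N, g)]; the study-level
default g = 15 follows the reading of "rarefied to the smallest number of
alleles (n = 15)" as gene copies (the hierfstat convention); g is
configurable because the alternative reading (individuals) cannot be ruled
out from the text. H_s is Nei's unbiased gene diversity
(n/(n−1))(1 − Σp̂² − H_o/2n); F_IS = 1 − H_o/H_s per locus, with the
across-locus summary computed as a ratio of means (hierfstat convention)
and the across-locus variance of the per-locus values also reported. The
F_IS confidence interval resamples loci with replacement (percentile
2.5/97.5, default 1000 replicates). Clone correction keeps one shoot per
MLL per site (fewest missing loci, then lexicographic id) and reports
Δ = stat(all) − stat(clone-corrected).

## Differentiation

Weir–Cockerham θ accumulates the per-allele, per-locus variance components
a, b, c and combines them as Σa/Σ(a+b+c); loci monomorphic overall
contribute nothing, and populations without calls at a locus are dropped
for that locus. H_S and H_T follow Nei & Chesser's unbiased estimators with
the harmonic mean sample size. G″ST = k(H_T−H_S)/((kH_T−H_S)(1−H_S)) and
D_est = (k/(k−1))(H_T−H_S)/(1−H_S); the multi-locus D_est defaults to the
harmonic mean of per-locus values (falling back to the arithmetic mean when
any per-locus value is non-positive, where the harmonic mean is
ill-defined), with the arithmetic across-locus H_S/H_T combination
available. Pairwise matrices re-estimate components per pair. Negative
estimates are reported as-is; truncation would bias the bootstrap CIs.

Bootstraps: θ resamples loci (precomputed per-locus components, percentile
CI); G″ST/D_est can resample loci or individuals within populations. A
calibration note: percentile CIs from loci resampling undercover when the
number of resampling units is small (~84% at 10 loci in our null runs,
because the bootstrap spread is itself noisy at 10 units); the suite's
coverage calibration therefore runs at 40 loci, where the percentile
method's asymptotics in the resampling unit apply (~92% observed). This is
a property of the percentile bootstrap, not of the estimator; with ~10
loci the CIs should be read as approximate.

## Riverscape distances

The water mask is a binary conductance raster (ESRI ASCII; NODATA = land).
Cost distances are Dijkstra shortest paths on the 8-neighbour graph of
water cells with orthogonal steps costing one cell size and diagonal steps
√2 times that — the standard corner-connection correction; land is
impassable and unreachable pairs are +inf. Points are snapped to their
containing cell (nearest water cell, row-major tie-break, when on land),
and distances are between cell centers, so short-range values are
discretisation-limited; the working distance is therefore the entrywise
maximum of Euclidean and cost distances. Site centroids are sample-mean
coordinates, snapped to water when they fall on land. River km is consumed
as input metadata; the package does not project points to a channel
midline.

## Structure statistics

Edwards chord distance uses the angular form
D = √(1 − (1/L) Σ_l Σ_a √(p_A p_B)) — several "chord distance" formulas
coexist; this is the `dist.genpop` convention. The Mantel test correlates
off-diagonal pairs, permutes row/column labels of one matrix jointly, and
is one-sided for positive association (the IBD convention; the source
analyses do not state sidedness). Correspondence analysis decomposes the
standardised residuals of the site × allele count table (counts, not
frequencies, so rows are mass-weighted) and reports site principal
coordinates and axis inertias. Spearman correlations use midranks with the
t-approximation p-value (two-sided).

## Regime permutation contrasts

Site values are permuted across regime labels 10,000 times (group sizes
fixed); the statistic is |Δ mean|, and p is the proportion of permuted
values at least as extreme as the observed one. Ties count as extreme, so
constant data give p = 1; for continuous statistics this coincides with the
strictly-larger convention almost surely, and the minimum Monte-Carlo p is
0, reported together with an `exceeds_all_permutations` flag. An exact
enumeration mode exists for small site counts and is used to validate the
Monte-Carlo path. No multiple-testing correction is applied across the
battery (deliberately, matching standard practice for this battery; treat
the table as descriptive).

## Synthetic riverscape generator

The generator produces the inputs the pipeline reads, with known truth:

* **Geometry** — a sinusoidal water corridor through land on a configurable
  cell size (default 500 m; fine rasters are unnecessary for site-level
  distances), sites placed in-channel at configured river-km positions, and
  an optional one-column land barrier at the tidal boundary for
  disconnection tests.
* **Allele frequencies** — ancestral spectra are skewed
  (Dirichlet α = 0.25, the uneven frequency profiles typical of
  microsatellites), and site frequencies follow a logistic-normal random
  walk from the river mouth upstream with standard deviation
  0.3·√(Δkm) per step, plus one extra jump (σ = 3.0) at the
  nontidal/tidal boundary. Walking upstream makes allelic diversity
  accumulate downstream, and the boundary jump makes the regime transition
  an abrupt disjunction rather than a smooth gradient — the two qualitative
  features of the emulated system. These defaults were calibrated once
  against the study-level summary magnitudes (site A ≈ 2.6 vs 4.3 between
  regimes, within-site gene diversity ≈ 0.4–0.5, global θ ≈ 0.15–0.25).
* **Clonality** — within a site each new shoot is, with regime-dependent
  probability c (defaults 0.75 nontidal / 0.05 tidal), a ramet of a
  resident genet chosen size-biased (rich-get-richer, yielding Pareto-like
  clone-size spectra) and tilted toward heterozygous genets
  (`clonal_het_advantage`, logistic weight on the het fraction). The tilt
  encodes the empirical signature of established clones — heterozygote
  excess (H_o > H_s, negative F_IS) and the drop of clone-corrected H_s
  below the all-shoot value. The first founder of a high-clonality site is
  drawn heterozygous (alleles sampled without replacement) for the same
  reason. Configured widespread clones are seeded across a span of nontidal
  sites with a copy-weight head start.
* **Distinguishability** — new genets are rejection-sampled to be unique at
  the scored loci, mirroring the premise of complete-match clone
  discrimination; without it, concentrated upstream frequencies produce
  genotype collisions that no assignment procedure could resolve.
* **Relatedness structure** — genets within a site share drift history, so
  relative to river-wide reference frequencies they are genuinely related
  (r_W > r_A, nontidal ≫ tidal) without any explicit pedigree; an optional
  `local_mating` step (Mendelian crosses of residents) adds family
  structure but defaults to 0 because sib families flatten local allele
  frequencies and thereby inflate clone-corrected gene diversity, the
  opposite of the emulated pattern. Labelled pedigree dyads (clone,
  parent–offspring, full-sib, half-sib, unrelated) come from a separate
  Mendelian generator used to validate the relatedness estimator.
* **Missing data** — whole-call missingness injected per regime (defaults
  0.1% / 1.4%).

What the generator does **not** emulate: temporal structure (collection
years are metadata only), within-site spatial coordinates of individual
shoots (clone extents are exercised at site resolution), genotyping error
and null alleles, sex, selection, and any mechanistic dispersal model
(drift is a statistical surrogate for gene flow, not a simulation of
propagule transport). Tests passing on these data therefore demonstrate
correctness of the estimators and the pipeline's inferential machinery on
data with the assumed structure — not robustness to the artefacts of real
genotyping.

## Numerical and procedural conventions

* All randomness flows from one seed; the pipeline derives independent
  child generators per stage, and every report carries the seed and a
  config hash.
* Undefined statistics (Pareto β with one size class, F_IS at monomorphic
  loci, r_W at single-sample sites, Mantel on constant matrices) are
  flagged or NaN, never imputed; exclusions are logged.
* Two diagnostic conventions used by the end-to-end checks: a site counts
  as *clonal* for the clone-correction comparison when ≥ 30% of its shoots
  belong to multi-sample MLLs and it retains ≥ 5 clone-corrected genets —
  below that, Nei's n/(n−1) factor (1.5 at G = 3) dominates the comparison
  and the delta is noise, not clonality signal. And a missing-data merge
  counts as a *misassignment* only when the shoot's own genet was otherwise
  present in the data: a singleton genet whose resolved loci coincide with
  another genet's profile is unidentifiable for any complete-match
  procedure (the real-data analogue being a distance-1 MLG pair, which MLL
  collapse absorbs).
* Problem sizes in the test suite: the full emulated design (36 sites,
  ~940 shoots) runs end to end once; calibration loops (null coverage,
  p-uniformity) use 200 replicates at reduced dimensions chosen to keep
  each statistical check's Monte-Carlo error well below its tolerance.

## Limitations

* Wang's estimator is re-derived from the category moments and solved by
  least squares; it matches the published estimator in expectation but not
  necessarily replicate-for-replicate against the original Fortran
  implementation's WLS weighting (no such implementation was available to
  diff against).
* D_est's multi-locus combination across heterogeneous loci is
  convention-sensitive; both combinations are exposed and the harmonic
  default falls back to arithmetic for non-positive loci.
* The least-cost engine assumes an isotropic binary conductance; no
  flow-weighted or resistance (circuit-theory) distances.
* Exact HWE tests, null-allele handling, linkage disequilibrium, AMOVA and
  Bayesian clustering are out of scope.
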